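#!/usr/bin/env python
"""Generate the synthetic study cohort and write it as standard files.

Produces, for 20 participants: continuous and discrete arterial blood CSVs,
the noise-free true input function, a dynamic 4-D NIfTI with its frame-timing
sidecar, plus the shared ROI phantom and participant metadata. Everything
downstream reads these files, so the whole analysis runs off disk exactly as
it would for real acquisitions.
"""
import json
from pathlib import Path

import numpy as np

from petquant import (CohortSpec, default_schedule, make_cohort,
                      make_roi_phantom, simulate_blood, simulate_dynamic,
                      write_blood_tables, write_dynamic_pet,
                      write_input_function, write_participants, write_roi_map)
from petquant.pipeline import _participant_seed
from petquant.synthetic import participant_roi_params, true_wholeblood_curve
from petquant.spectral import vt_closed_form

HERE = Path(__file__).resolve().parent.parent
cfg = json.loads((HERE / "analysis" / "study_config.json").read_text())

cohort_dir = HERE / cfg["cohort_dir"]
cohort_dir.mkdir(parents=True, exist_ok=True)

spec = CohortSpec(n_participants=cfg["n_participants"], seed=cfg["seed"])
metas = make_cohort(spec)
write_participants(metas, cohort_dir / "participants.csv")

roi_map = make_roi_phantom(tuple(cfg["phantom_shape"]))
write_roi_map(roi_map, cohort_dir / "roi_map.nii.gz", cohort_dir / "roi_labels.csv")

schedule = default_schedule()
truth_rows = []
for i, meta in enumerate(metas):
    s_blood = _participant_seed(spec.seed, i, 1)
    s_dyn = _participant_seed(spec.seed, i, 2)
    continuous, discrete, true_if = simulate_blood(meta, spec, s_blood)
    wb = true_wholeblood_curve(meta, spec, s_blood)
    write_blood_tables(continuous, discrete,
                       cohort_dir / f"{meta.id}_blood_continuous.csv",
                       cohort_dir / f"{meta.id}_blood_discrete.csv")
    write_input_function(true_if, cohort_dir / f"{meta.id}_true_if.csv")
    params = participant_roi_params(meta, spec, s_dyn)
    dyn = simulate_dynamic(meta, roi_map, params, true_if, schedule,
                           spec.dynamic_noise, s_dyn, wholeblood=wb)
    write_dynamic_pet(dyn, cohort_dir / f"{meta.id}_dynamic.nii.gz",
                      cohort_dir / f"{meta.id}_timing.json")
    for region, pr in params.items():
        truth_rows.append(f"{meta.id},{region},{vt_closed_form(pr):.6f}")

(cohort_dir / "roi_vt_truth.csv").write_text(
    "participant,region,vt_true\n" + "\n".join(truth_rows) + "\n")

doses = np.array([m.injected_dose_mbq for m in metas])
ages = np.array([m.age_years for m in metas])
print(f"wrote cohort of {len(metas)} participants to {cohort_dir}")
print(f"  injected dose {doses.mean():.1f} +/- {doses.std(ddof=1):.1f} MBq; "
      f"ages {ages.min():.0f}-{ages.max():.0f} y")
print(f"  ROI phantom: {len(roi_map.label_table)} regions, "
      f"{int(np.sum(roi_map.labels > 0))} labelled voxels")
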