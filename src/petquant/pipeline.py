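"""End-to-end seeded study: simulate a cohort, build input functions, fit
every requested quantification variant, and write the per-ROI tables and
agreement reports.

The pipeline is a thin composition of the module operations - running it is
equivalent to calling them directly - and is deterministic for a given
configuration (identical runs produce byte-identical CSV output).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as ag
from . import io as pio
from . import pbif as pb
from .curves import InputFunction
from .errors import ConfigError
from .input_function import build_ppif
from .spectral import BasisGrid, vt_closed_form, vt_image
from .suv import suv_epoch
from .synthetic import (CohortSpec, make_cohort, make_roi_phantom,
                        participant_roi_params, simulate_blood, simulate_dynamic,
                        true_wholeblood_curve)
from .timing import default_schedule
from .truncation import DURATION_SLOW_BOUNDARIES, slow_boundary_for, truncate_frames

REQUIRED_KEYS = ("seed", "n_participants", "out_dir", "variants")
REFERENCE_VARIANT = "ppif-90"


@dataclass
class Variant:
    label: str
    kind: str                  # 'ppif' | 'pbif' | 'suv'
    duration_min: int = 90
    epoch: tuple[float, float] | None = None  # seconds, for 'suv'


def parse_variant(label: str) -> Variant:
    parts = label.split("-")
    if parts[0] == "ppif" and len(parts) == 2:
        dur = int(parts[1])
        if dur not in DURATION_SLOW_BOUNDARIES:
            raise ConfigError(
                f"variant {label!r}: no slow boundary defined for {dur}-min scans; "
                f"supported durations are {sorted(DURATION_SLOW_BOUNDARIES)}")
        return Variant(label, "ppif", duration_min=dur)
    if parts[0] == "pbif" and len(parts) == 2:
        dur = int(parts[1])
        if dur != 90:
            raise ConfigError(f"variant {label!r}: PBIF fits use the full 90-min data")
        return Variant(label, "pbif", duration_min=90)
    if parts[0] == "suv" and len(parts) == 3:
        t0, t1 = 60.0 * int(parts[1]), 60.0 * int(parts[2])
        if not 0 <= t0 < t1:
            raise ConfigError(f"variant {label!r}: bad epoch")
        return Variant(label, "suv", epoch=(t0, t1))
    raise ConfigError(f"unrecognised variant {label!r}")


def load_config(config) -> dict:
    """Accept a dict or a JSON file path; check required keys."""
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    missing = [k for k in REQUIRED_KEYS if k not in config]
    if missing:
        raise ConfigError(f"config is missing required keys: {missing}")
    for label in config["variants"]:
        parse_variant(label)
    return config


@dataclass
class ReportBundle:
    """Everything a pipeline run produced, in memory and on disk."""

    out_dir: Path
    metas: list
    roi_tables: dict[str, pd.DataFrame]
    agreement: dict[str, ag.AgreementReport]
    truth_table: pd.DataFrame
    table_paths: dict[str, Path] = field(default_factory=dict)
    report_paths: dict[str, Path] = field(default_factory=dict)


def _participant_seed(base_seed: int, index: int, stream: int = 0) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(index), int(stream)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config) -> ReportBundle:
    """Run the full synthetic study described by ``config``.

    Required keys: ``seed``, ``n_participants``, ``out_dir``, ``variants``
    (labels like ``ppif-90``, ``ppif-60``, ``pbif-90``, ``suv-80-90``).
    Optional: ``phantom_shape``, ``blood_noise``, ``parent_fraction_noise``,
    ``dynamic_noise``, ``n_basis``, ``include_vascular``, ``weights_mode``,
    ``leave_one_out``, ``use_age``, ``write_images``, ``reference_variant``.
    """
    cfg = load_config(config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    variants = [parse_variant(v) for v in cfg["variants"]]
    reference = cfg.get("reference_variant", REFERENCE_VARIANT)

    spec = CohortSpec(
        n_participants=int(cfg["n_participants"]), seed=int(cfg["seed"]),
        blood_noise=float(cfg.get("blood_noise", CohortSpec.blood_noise)),
        parent_fraction_noise=float(cfg.get("parent_fraction_noise",
                                            CohortSpec.parent_fraction_noise)),
        dynamic_noise=float(cfg.get("dynamic_noise", CohortSpec.dynamic_noise)),
    )
    metas = make_cohort(spec)
    roi_map = make_roi_phantom(tuple(cfg.get("phantom_shape", (12, 12, 12))))
    schedule = default_schedule()
    scan_end = schedule.scan_end_pi
    weights_mode = cfg.get("weights_mode", "duration")
    grid_kwargs = {"n_basis": int(cfg.get("n_basis", 100)),
                   "include_vascular": bool(cfg.get("include_vascular", True))}

    # --- per-participant simulation and ppIF reconstruction -----------------
    ppifs: list[InputFunction] = []
    dyns, truth_rows = [], []
    for i, meta in enumerate(metas):
        s_blood = _participant_seed(spec.seed, i, 1)
        s_dyn = _participant_seed(spec.seed, i, 2)
        continuous, discrete, true_if = simulate_blood(meta, spec, s_blood)
        wb = true_wholeblood_curve(meta, spec, s_blood)
        ppif, _ = build_ppif(continuous, discrete, scan_end, meta.id)
        ppifs.append(ppif)
        params = participant_roi_params(meta, spec, s_dyn)
        dyns.append(simulate_dynamic(meta, roi_map, params, true_if, schedule,
                                     spec.dynamic_noise, s_dyn, wholeblood=wb))
        for region, pr in params.items():
            truth_rows.append({"participant": meta.id, "region": region,
                               "value": vt_closed_form(pr), "variant": "truth",
                               "subgroup": meta.subgroup, "age_years": meta.age_years})
    truth_table = pd.DataFrame(truth_rows)

    # --- PBIF models (leave-one-out by default) -----------------------------
    pbif_curves: dict[str, InputFunction] = {}
    if any(v.kind == "pbif" for v in variants):
        loo = bool(cfg.get("leave_one_out", True))
        use_age = bool(cfg.get("use_age", True))
        for meta, ppif in zip(metas, ppifs):
            model = pb.build_pbif_model(
                ppifs, metas, exclude_id=meta.id if loo else None, use_age=use_age)
            anchor = pb.anchor_value(ppif)
            pbif_curves[meta.id] = pb.scale_pbif(model, anchor, meta.id)

    # --- fit every variant ---------------------------------------------------
    roi_tables: dict[str, pd.DataFrame] = {}
    for var in variants:
        rows = []
        for meta, dyn, ppif in zip(metas, dyns, ppifs):
            if var.kind == "suv":
                res = suv_epoch(dyn, meta, *var.epoch, roi_map=roi_map)
                for r in res.roi_means.itertuples():
                    rows.append({"participant": meta.id, "region": r.region,
                                 "value": r.suv})
            else:
                input_fn = pbif_curves[meta.id] if var.kind == "pbif" else ppif
                grid = BasisGrid(slow_boundary=slow_boundary_for(var.duration_min),
                                 **grid_kwargs)
                dyn_fit = dyn if var.duration_min == 90 else \
                    truncate_frames(dyn, var.duration_min * 60.0)
                vt_vol, roi_df = vt_image(dyn_fit, roi_map, input_fn, grid, weights_mode)
                if cfg.get("write_images", False):
                    pio.write_vt_volume(vt_vol, roi_map.voxel_size_mm,
                                        out_dir / f"vt_{var.label}_{meta.id}.nii.gz")
                for r in roi_df.itertuples():
                    rows.append({"participant": meta.id, "region": r.region,
                                 "value": r.vt})
        roi_tables[var.label] = ag.make_roi_table(rows, var.label)

    # --- persist tables and agreement reports -------------------------------
    bundle = ReportBundle(out_dir=out_dir, metas=metas, roi_tables=roi_tables,
                          agreement={}, truth_table=truth_table)
    for label, table in roi_tables.items():
        path = out_dir / f"roi_{label}.csv"
        table.to_csv(path, index=False, float_format="%.10g")
        bundle.table_paths[label] = path
    truth_path = out_dir / "roi_truth.csv"
    truth_table.to_csv(truth_path, index=False, float_format="%.10g")
    bundle.table_paths["truth"] = truth_path

    if reference in roi_tables:
        for label, table in roi_tables.items():
            if label == reference:
                continue
            report = ag.compare_variants(roi_tables[reference], table)
            bundle.agreement[label] = report
            jpath = out_dir / f"agreement_{label}_vs_{reference}.json"
            jpath.write_text(json.dumps(report.to_dict(), indent=1))
            cpath = out_dir / f"blandaltman_{label}_vs_{reference}.csv"
            report.scatter.to_csv(cpath, index=False, float_format="%.10g")
            bundle.report_paths[label] = jpath

        # tidy export for external subgroup statistics (e.g. MANOVA with age)
        subgroup = roi_tables[reference].merge(
            pd.DataFrame([{"participant": m.id, "subgroup": m.subgroup,
                           "age_years": m.age_years} for m in metas]),
            on="participant")
        subgroup.to_csv(out_dir / "subgroup_export.csv", index=False,
                        float_format="%.10g")
    return bundle
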