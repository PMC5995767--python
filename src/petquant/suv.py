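"""Standardised uptake values over post-injection epochs.

SUV = mean activity concentration (Bq/mL, decay-corrected) x body weight (g)
/ injected dose (Bq): a unitless, blood-free uptake index. The default epoch
set is the seven 10-min epochs from 20-30 to 80-90 min plus 30-60 and
60-90 min.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import DynamicImage, ParticipantMeta, ROIMap

#: (t0, t1) seconds post-injection
DEFAULT_EPOCHS = [(1200 + 600 * i, 1800 + 600 * i) for i in range(7)] \
    + [(1800, 3600), (3600, 5400)]


@dataclass
class SUVResult:
    epoch: tuple[float, float]
    suv_image: np.ndarray
    roi_means: pd.DataFrame  # columns: region, suv, n_voxels

    @property
    def label(self) -> str:
        return f"suv-{int(self.epoch[0] // 60)}-{int(self.epoch[1] // 60)}"


def suv_epoch(dyn: DynamicImage, meta: ParticipantMeta, t0: float, t1: float,
              roi_map: ROIMap | None = None) -> SUVResult:
    """SUV image over [t0, t1] seconds post-injection (frame-aligned).

    The epoch mean is the duration-weighted mean of the decay-corrected
    frames it covers; splitting a frame is refused rather than interpolated.
    """
    sched = dyn.schedule
    if t1 <= t0:
        raise ValidationError("epoch must have positive length")
    if t0 < sched.start_pi[0] - 1e-6 or t1 > sched.scan_end_pi + 1e-6:
        raise ValidationError("epoch lies outside the scan")
    for edge in (t0, t1):
        if not sched.is_frame_boundary(edge):
            raise ValidationError(f"epoch edge {edge} s does not coincide with a frame boundary")
    inside = (sched.start_pi >= t0 - 1e-6) & (sched.end_pi <= t1 + 1e-6)
    if not np.any(inside):
        raise ValidationError("epoch covers no whole frame")
    durs = sched.duration[inside]
    mean_img = np.tensordot(dyn.data[..., inside], durs, axes=([3], [0])) / durs.sum()
    suv_img = mean_img * (meta.weight_kg * 1000.0) / (meta.injected_dose_mbq * 1e6)

    rows = []
    if roi_map is not None:
        for label_id, region in roi_map.label_table.items():
            sel = roi_map.labels == label_id
            val = float(suv_img[sel].mean()) if np.any(sel) else np.nan
            rows.append({"region": region, "suv": val, "n_voxels": int(np.sum(sel))})
    return SUVResult((t0, t1), suv_img, pd.DataFrame(rows))


def suv_epoch_series(dyn: DynamicImage, meta: ParticipantMeta,
                     epochs: list[tuple[float, float]] | None = None,
                     roi_map: ROIMap | None = None) -> list[SUVResult]:
    """One SUVResult per epoch; defaults to the nine standard epochs."""
    if epochs is None:
        epochs = DEFAULT_EPOCHS
    return [suv_epoch(dyn, meta, t0, t1, roi_map) for t0, t1 in epochs]
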