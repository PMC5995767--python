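"""Scan-shortening: truncate dynamic data and refit with duration-matched
slow boundaries.

Shorter acquisitions cannot distinguish the slowest kinetic components, so
each supported duration carries its own slow boundary for the spectral
basis; the full-length input function is used for every fit. The boundary
values follow no derivable formula, so they live in a lookup table with an
explicit-override escape hatch.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .curves import InputFunction
from .errors import ValidationError
from .io import DynamicImage, ROIMap
from .spectral import BasisGrid, vt_image
from .timing import FrameSchedule

#: scan duration (min) -> slow boundary (s^-1)
DURATION_SLOW_BOUNDARIES = {60: 0.000290, 70: 0.000256, 80: 0.000222, 90: 0.000196}


def slow_boundary_for(duration_min: int) -> float:
    try:
        return DURATION_SLOW_BOUNDARIES[int(duration_min)]
    except KeyError:
        raise ValidationError(
            f"no slow boundary defined for {duration_min} min; supported durations are "
            f"{sorted(DURATION_SLOW_BOUNDARIES)} - supply a boundary explicitly") from None


def truncate_frames(dyn: DynamicImage, t_end_pi: float) -> DynamicImage:
    """Keep the frames ending at or before ``t_end_pi`` (s post-injection).

    ``t_end_pi`` must coincide with a frame boundary; truncating mid-frame
    would silently change the last frame's statistics.
    """
    sched = dyn.schedule
    if t_end_pi > sched.scan_end_pi + 1e-6:
        raise ValidationError("truncation time lies beyond the scan")
    if not sched.is_frame_boundary(t_end_pi):
        raise ValidationError(f"truncation time {t_end_pi} s falls inside a frame")
    keep = sched.end_pi <= t_end_pi + 1e-6
    if not np.any(keep):
        raise ValidationError("truncation removes every frame")
    new_sched = FrameSchedule(sched.start[keep], sched.duration[keep],
                              sched.injection_offset)
    return DynamicImage(dyn.data[..., keep], new_sched, dyn.voxel_size_mm)


def truncation_study(dyn: DynamicImage, input_fn: InputFunction, roi_map: ROIMap,
                     durations_min: list[int] = (60, 70, 80, 90),
                     reference_min: int = 90,
                     grid_kwargs: dict | None = None,
                     weights_mode: str = "duration",
                     vascular_curve: np.ndarray | None = None,
                     boundaries: dict | None = None) -> pd.DataFrame:
    """Refit V_T for each duration and report percent difference vs reference.

    Returns a tidy frame with one row per (duration, region):
    ``duration_min, region, vt, pct_diff_vs_ref``.
    """
    grid_kwargs = dict(grid_kwargs or {})
    durations = sorted(set(durations_min) | {reference_min})
    results = {}
    for dur in durations:
        boundary = (boundaries or {}).get(dur, None)
        if boundary is None:
            boundary = slow_boundary_for(dur)
        grid = BasisGrid(slow_boundary=boundary, **grid_kwargs)
        short = truncate_frames(dyn, dur * 60.0)
        _, roi_df = vt_image(short, roi_map, input_fn, grid, weights_mode, vascular_curve)
        results[dur] = roi_df.set_index("region")["vt"]
    ref = results[reference_min]
    rows = []
    for dur in sorted(set(durations_min)):
        for region, vt in results[dur].items():
            rows.append({
                "duration_min": dur, "region": region, "vt": vt,
                "pct_diff_vs_ref": 100.0 * (vt - ref[region]) / ref[region],
            })
    return pd.DataFrame(rows)
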