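"""Population-based input functions anchored on a single late plasma sample.

Standardisation: each training ppIF is magnitude-normalised by cohort-median
/ participant ratios of weight, injected dose and age (in that order), its
peak is aligned to 80 s, and the pointwise median across the cohort becomes
the standardised curve. Individualisation: the AUC of the training ppIFs is
regressed on their parent-plasma activity at 90 min, and the standardised
curve is rescaled by predicted-AUC / standardised-AUC for the target
participant's anchor sample. The protocol is leave-one-out by default: the
target participant contributes neither to the median nor to the regression.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

from .curves import InputFunction
from .errors import ValidationError
from .io import ParticipantMeta

PEAK_TARGET_S = 80.0
PEAK_SMOOTH_S = 5.0


@dataclass
class PBIFModel:
    """Standardised median curve plus the AUC-vs-anchor regression."""

    standardised_curve: InputFunction
    slope: float
    intercept: float
    training_ids: list[str]

    def predicted_auc(self, anchor_bq_per_ml: float) -> float:
        return self.slope * anchor_bq_per_ml + self.intercept


def normalise_magnitude(ppifs: list[InputFunction],
                        metas: list[ParticipantMeta],
                        use_age: bool = True) -> list[InputFunction]:
    """Scale each ppIF by (median weight / weight) x (median dose / dose)
    x (median age / age). The factors commute, so the cohort medians are
    computed once from the raw covariates; the age factor can be disabled."""
    if len(ppifs) != len(metas):
        raise ValidationError("one meta per input function required")
    weights = np.array([m.weight_kg for m in metas])
    doses = np.array([m.injected_dose_mbq for m in metas])
    ages = np.array([m.age_years for m in metas])
    if np.any(weights <= 0) or np.any(doses <= 0) or np.any(ages <= 0):
        raise ValidationError("weight, dose and age must all be positive")
    med_w, med_d, med_a = np.median(weights), np.median(doses), np.median(ages)
    out = []
    for curve, w, d, a in zip(ppifs, weights, doses, ages):
        factor = (med_w / w) * (med_d / d)
        if use_age:
            factor *= med_a / a
        out.append(curve.scaled(factor))
    return out


def align_peaks(curves: list[InputFunction],
                target_peak_s: float = PEAK_TARGET_S) -> list[InputFunction]:
    """Time-shift each curve so its (lightly smoothed) maximum sits at the
    target, then truncate all curves to their common support and re-grid.

    Right shifts pad the pre-bolus head with zeros; left shifts discard the
    pre-zero head and shorten the tail (no last-value padding), so the
    common support ends where the earliest-ending shifted curve does.
    """
    if not curves:
        raise ValidationError("no curves to align")
    dt = curves[0].dt
    n = curves[0].values.size
    if any(c.dt != dt or c.values.size != n for c in curves):
        raise ValidationError("curves must share one grid")
    shifts = []
    margin = max(dt, PEAK_SMOOTH_S)
    for c in curves:
        tp = c.peak_time(PEAK_SMOOTH_S)
        if tp <= margin or tp >= c.t_end - margin:
            raise ValidationError(
                f"curve {c.participant_id or '?'} has its maximum at the grid edge "
                "(no identifiable interior peak)")
        shifts.append(int(round((target_peak_s - tp) / dt)))
    # common support after shifting: left-shifted curves lose |shift| tail samples
    n_common = n + min(min(shifts), 0)
    out = []
    for c, s in zip(curves, shifts):
        vals = np.zeros(n_common)
        if s >= 0:
            m = min(n - s, n_common - s) if s < n_common else 0
            if m > 0:
                vals[s:s + m] = c.values[:m]
        else:
            vals[:] = c.values[-s:-s + n_common]
        out.append(InputFunction(np.clip(vals, 0, None), dt, c.participant_id, c.provenance))
    return out


def median_curve(aligned: list[InputFunction]) -> InputFunction:
    """Pointwise median across >= 3 curves sharing one grid."""
    if len(aligned) < 3:
        raise ValidationError("need >= 3 curves for a median")
    dt = aligned[0].dt
    n = aligned[0].values.size
    if any(c.dt != dt or c.values.size != n for c in aligned):
        raise ValidationError("curves must share one grid")
    med = np.median(np.stack([c.values for c in aligned]), axis=0)
    return InputFunction(med, dt, "", "pbif")


def _extend_to(curve: InputFunction, t_end: float) -> InputFunction:
    """Extend a standardised curve to scan end with a log-linear tail fit
    over its last 300 s (peak alignment can shave a few tens of seconds)."""
    if curve.t_end >= t_end - 1e-9:
        return curve
    n_extra = int(round((t_end - curve.t_end) / curve.dt))
    t = curve.time
    tail = t >= t[-1] - 300.0
    v = np.clip(curve.values[tail], 1e-12, None)
    b, a = np.polyfit(t[tail], np.log(v), 1)
    t_new = t[-1] + curve.dt * np.arange(1, n_extra + 1)
    ext = np.exp(a + b * t_new)
    return InputFunction(np.concatenate([curve.values, ext]), curve.dt,
                         curve.participant_id, curve.provenance)


def anchor_value(ppif: InputFunction, t_anchor_s: float = 5400.0) -> float:
    """Parent-plasma activity at the anchor time (90 min by default)."""
    return float(ppif.value_at(min(t_anchor_s, ppif.t_end)))


def fit_auc_regression(ppifs: list[InputFunction],
                       anchors: np.ndarray) -> tuple[float, float]:
    """OLS of ppIF AUC (trapezoid over the full grid) on the anchor activity."""
    if len(ppifs) < 3:
        raise ValidationError("need >= 3 (AUC, anchor) pairs")
    anchors = np.asarray(anchors, dtype=float)
    if anchors.size != len(ppifs):
        raise ValidationError("one anchor per input function required")
    if np.ptp(anchors) == 0:
        raise ValidationError("anchor samples have zero variance")
    aucs = np.array([c.auc() for c in ppifs])
    res = linregress(anchors, aucs)
    return float(res.slope), float(res.intercept)


def build_pbif_model(ppifs: list[InputFunction], metas: list[ParticipantMeta],
                     exclude_id: str | None = None, use_age: bool = True,
                     t_anchor_s: float = 5400.0) -> PBIFModel:
    """Standardise the (optionally leave-one-out) training cohort and fit the
    anchor regression."""
    if exclude_id is not None:
        keep = [i for i, m in enumerate(metas) if m.id != exclude_id]
        if len(keep) == len(metas):
            raise ValidationError(f"participant {exclude_id!r} not in the cohort")
        ppifs = [ppifs[i] for i in keep]
        metas = [metas[i] for i in keep]
    scan_end = ppifs[0].t_end
    normalised = normalise_magnitude(ppifs, metas, use_age=use_age)
    aligned = align_peaks(normalised)
    med = _extend_to(median_curve(aligned), scan_end)
    slope, intercept = fit_auc_regression(
        ppifs, np.array([anchor_value(c, t_anchor_s) for c in ppifs]))
    return PBIFModel(med, slope, intercept, [m.id for m in metas])


def scale_pbif(model: PBIFModel, anchor_bq_per_ml: float,
               participant_id: str = "") -> InputFunction:
    """Rescale the standardised curve to the individual's anchor sample."""
    if anchor_bq_per_ml <= 0:
        raise ValidationError("anchor activity must be positive")
    predicted = model.predicted_auc(anchor_bq_per_ml)
    if predicted <= 0:
        raise ValidationError("predicted AUC is nonpositive; cannot anchor the PBIF")
    factor = predicted / model.standardised_curve.auc()
    return InputFunction(model.standardised_curve.values * factor,
                         model.standardised_curve.dt, participant_id, "pbif")
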