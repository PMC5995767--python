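"""Construction of the continuous parent-plasma input function (ppIF).

The arterial chain has four stages:

1. cross-calibrate the continuous detector against the discrete whole-blood
   samples (a single multiplicative scalar, least squares over all matches);
2. convert whole blood to plasma with the plasma-over-blood (POB) ratio
   interpolated between paired discrete samples;
3. extend the continuous plasma curve past the continuous sampling window
   with a shape-preserving cubic through the later discrete plasma samples;
4. multiply by the fitted parent fraction, a decreasing sigmoid fixed to 1
   at injection.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import curve_fit

from .curves import DiscreteSampleTable, InputFunction, SampledCurve
from .errors import FitError, ValidationError

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Stage 1: cross-calibration
# --------------------------------------------------------------------------

def cross_calibrate(continuous: SampledCurve, discrete: DiscreteSampleTable,
                    match_window_s: float = 5.0) -> tuple[SampledCurve, float]:
    """Scale the continuous detector onto the discrete whole-blood samples.

    The scalar c minimises sum_i (d_i - c * cont(t_i))^2 over every discrete
    whole-blood sample whose time lies inside the continuous window (with a
    small tolerance); the continuous curve is evaluated at the sample times
    by linear interpolation. Negative detector readings (electronic noise)
    are clamped to zero first, with a count logged.

    Returns the calibrated curve and the scalar.
    """
    values = continuous.value.copy()
    n_neg = int(np.sum(values < 0))
    if n_neg:
        log.info("clamped %d negative continuous detector samples to 0", n_neg)
        values = np.clip(values, 0.0, None)
    cont = SampledCurve(continuous.time, values)

    mask = (np.isfinite(discrete.wholeblood)
            & (discrete.time >= cont.time[0] - match_window_s)
            & (discrete.time <= cont.time[-1] + match_window_s))
    if not np.any(mask):
        raise ValidationError("no discrete whole-blood samples inside the continuous window")
    t_match = discrete.time[mask]
    d = discrete.wholeblood[mask]
    c_at = cont.interp(t_match)
    denom = float(np.dot(c_at, c_at))
    if denom == 0.0:
        raise ValidationError("continuous activity is zero at every matched sample")
    scalar = float(np.dot(d, c_at) / denom)
    return cont.scaled(scalar), scalar


# --------------------------------------------------------------------------
# Stage 2: plasma-over-blood ratio
# --------------------------------------------------------------------------

def apply_plasma_over_blood(calibrated: SampledCurve,
                            discrete: DiscreteSampleTable) -> SampledCurve:
    """Multiply the whole-blood curve pointwise by the interpolated POB ratio.

    The ratio is linear between paired samples and held constant beyond the
    first and last pair.
    """
    paired = discrete.with_both_blood_measures()
    if paired.n < 2:
        raise ValidationError("need >= 2 samples with both plasma and whole blood")
    if np.any((paired.wholeblood == 0) & (paired.plasma > 0)):
        raise ValidationError("whole-blood activity is zero where plasma is positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(paired.wholeblood > 0, paired.plasma / paired.wholeblood, 1.0)
    pob = np.interp(calibrated.time, paired.time, ratio)
    return SampledCurve(calibrated.time, calibrated.value * pob)


def pob_curve(discrete: DiscreteSampleTable, t: np.ndarray) -> np.ndarray:
    """The interpolated POB ratio itself, on an arbitrary time grid."""
    paired = discrete.with_both_blood_measures()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(paired.wholeblood > 0, paired.plasma / paired.wholeblood, 1.0)
    return np.interp(np.asarray(t, float), paired.time, ratio)


# --------------------------------------------------------------------------
# Stage 3: tail extension
# --------------------------------------------------------------------------

def merge_continuous_discrete(plasma_cont: SampledCurve,
                              discrete: DiscreteSampleTable) -> SampledCurve:
    """Join the continuous plasma curve with the discrete plasma tail.

    Inside the continuous window the curve is kept verbatim. Beyond it, a
    shape-preserving piecewise cubic (monotone-safe, so no negative
    undershoot) runs through the later discrete plasma samples, anchored at
    the continuous curve's final point, and is sampled at 1-s resolution.
    """
    t_break = plasma_cont.time[-1]
    mask_tail = np.isfinite(discrete.plasma) & (discrete.time > t_break + 1e-9)
    if not np.any(mask_tail):
        raise ValidationError("no discrete plasma sample beyond the continuous window")
    knots_t = np.concatenate([[t_break], discrete.time[mask_tail]])
    knots_v = np.concatenate([[plasma_cont.value[-1]], discrete.plasma[mask_tail]])
    t_tail = np.arange(np.ceil(t_break) + 1.0, np.floor(knots_t[-1]) + 1.0)
    if knots_t.size == 2:
        tail_vals = np.interp(t_tail, knots_t, knots_v)
    else:
        tail_vals = PchipInterpolator(knots_t, knots_v)(t_tail)
    tail_vals = np.clip(tail_vals, 0.0, None)
    return SampledCurve(np.concatenate([plasma_cont.time, t_tail]),
                        np.concatenate([plasma_cont.value, tail_vals]))


# --------------------------------------------------------------------------
# Stage 4: parent fraction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParentFractionFit:
    """Hill-type decreasing sigmoid f(t) = 1 - A t^h / (t^h + T50^h).

    f(0) = 1 holds by construction; A in [0, 1] is the asymptotic drop, T50
    the half-drop time (s) and h the steepness.
    """

    A: float
    T50: float
    h: float
    residual_rss: float = 0.0

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        th = np.power(np.clip(t, 0.0, None), self.h)
        return 1.0 - self.A * th / (th + self.T50 ** self.h)


def fit_parent_fraction(discrete: DiscreteSampleTable) -> ParentFractionFit:
    """Weighted (uniform) least-squares fit of the parent-fraction sigmoid."""
    mask = np.isfinite(discrete.parent_fraction) & (discrete.time > 0)
    t = discrete.time[mask]
    f = discrete.parent_fraction[mask]
    if t.size < 3:
        raise ValidationError("need >= 3 parent-fraction measurements at positive times")

    def model(tt, A, T50, h):
        th = np.power(tt, h)
        return 1.0 - A * th / (th + T50 ** h)

    # moment-style start: half-drop time from the sample closest to 1 - A/2
    a0 = float(np.clip(1.0 - f.min(), 1e-3, 1.0))
    t50_0 = float(t[np.argmin(np.abs(f - (1 - 0.5 * a0)))])
    p0 = (a0, max(t50_0, 1.0), 1.5)
    try:
        popt, _ = curve_fit(model, t, f, p0=p0,
                            bounds=([0.0, 1e-6, 0.05], [1.0, 1e7, 10.0]),
                            maxfev=20000)
    except RuntimeError as e:
        raise FitError(f"parent-fraction fit did not converge (start {p0}): {e}") from e
    resid = f - model(t, *popt)
    return ParentFractionFit(float(popt[0]), float(popt[1]), float(popt[2]),
                             float(np.sum(resid**2)))


# --------------------------------------------------------------------------
# Composition
# --------------------------------------------------------------------------

def build_ppif(continuous: SampledCurve, discrete: DiscreteSampleTable,
               scan_end_s: float, participant_id: str = "",
               dt: float = 1.0) -> tuple[InputFunction, dict]:
    """Full ppIF chain: calibrate, POB-convert, merge the tail, apply the
    fitted parent fraction, and resample to a uniform grid [0, scan_end].

    Returns the input function and a fit report (calibration scalar,
    parent-fraction parameters, clamp count).
    """
    calibrated, scalar = cross_calibrate(continuous, discrete)
    plasma_cont = apply_plasma_over_blood(calibrated, discrete)
    merged = merge_continuous_discrete(plasma_cont, discrete)
    if merged.time[-1] < scan_end_s:
        raise ValidationError("blood data end before the requested scan end")
    pf = fit_parent_fraction(discrete)
    grid = np.arange(0.0, scan_end_s + 0.5 * dt, dt)
    plasma = np.interp(grid, merged.time, merged.value)
    values = plasma * pf(grid)
    n_clamped = int(np.sum(values < 0))
    if n_clamped:
        log.info("clamped %d negative ppIF values to 0", n_clamped)
    values = np.clip(values, 0.0, None)
    report = {
        "calibration_scalar": scalar,
        "parent_fraction": {"A": pf.A, "T50_s": pf.T50, "h": pf.h,
                            "residual_rss": pf.residual_rss},
        "n_clamped": n_clamped,
    }
    return InputFunction(values, dt, participant_id, "ppif"), report
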