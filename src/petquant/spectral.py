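"""Classic spectral analysis of dynamic PET data, plus compartmental oracles.

A tissue time-activity curve C(t) is decomposed against the parent-plasma
input function Cp as a nonnegative sum of convolved exponentials,

    C(t) = sum_j alpha_j * [Cp (*) exp(-beta_j t)](t),    alpha_j >= 0,

with the rates beta_j fixed on a log-spaced grid between a fast and a slow
boundary and the amplitudes found by nonnegative least squares. The total
volume of distribution follows as V_T = sum_j alpha_j / beta_j over the
tissue bases (an optional vascular column is excluded).

The same module houses the one- and two-tissue compartment forward models
and the closed-form V_T they imply, which serve as simulation ground truth
and as independent oracles for the spectral estimates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.signal import lfilter

from .curves import InputFunction
from .errors import ValidationError
from .timing import FrameSchedule, frame_average

SEC_PER_MIN = 60.0

#: Classic-SA basis boundaries: time constants of 5 s and 5100 s.
FAST_BOUNDARY = 0.2        # s^-1
SLOW_BOUNDARY_90MIN = 0.000196  # s^-1


def beta_from_time_constant(tc_s: float) -> float:
    """Convert a time constant (s) to its exponential rate (s^-1)."""
    if tc_s <= 0:
        raise ValidationError("time constant must be positive")
    return 1.0 / tc_s


# --------------------------------------------------------------------------
# Compartment models (ground truth / oracles)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticParams:
    """Two-tissue compartment rate constants with a fractional blood volume.

    ``K1`` is in mL·cm^-3·min^-1 and the k's in min^-1 (the conventional
    reporting units); they are converted to s^-1 internally. ``k3 = k4 = 0``
    reduces the model to one tissue compartment.
    """

    K1: float
    k2: float
    k3: float = 0.0
    k4: float = 0.0
    vb: float = 0.0

    def __post_init__(self) -> None:
        if min(self.K1, self.k2, self.k3, self.k4) < 0:
            raise ValidationError("rate constants must be nonnegative")
        if self.k2 <= 0:
            raise ValidationError("k2 must be positive")
        if not 0 <= self.vb < 1:
            raise ValidationError("vb must be in [0, 1)")


def vt_closed_form(params: KineticParams) -> float:
    """V_T = K1/k2 for 1TC and (K1/k2)(1 + k3/k4) for 2TC kinetics."""
    if params.k3 > 0 and params.k4 == 0:
        raise ValidationError("k3 > 0 with k4 = 0: irreversible trapping, V_T unbounded")
    vt = params.K1 / params.k2
    if params.k3 > 0:
        vt *= 1.0 + params.k3 / params.k4
    return vt


def tissue_impulse_response(params: KineticParams):
    """Exponential decomposition of the tissue impulse response.

    Returns ``(amplitudes, rates)`` in s^-1 such that
    ``h(t) = sum_i amplitudes[i] * exp(-rates[i] * t)`` and
    ``C_tissue = h (*) Cp``.
    """
    K1 = params.K1 / SEC_PER_MIN
    k2 = params.k2 / SEC_PER_MIN
    k3 = params.k3 / SEC_PER_MIN
    k4 = params.k4 / SEC_PER_MIN
    if k3 == 0 and k4 == 0:
        return np.array([K1]), np.array([k2])
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    root = np.sqrt(max(disc, 0.0))
    a1 = 0.5 * (s - root)
    a2 = 0.5 * (s + root)
    if a2 - a1 < 1e-15:
        raise ValidationError("degenerate 2TC eigenvalues; perturb the rate constants")
    c1 = K1 * (k3 + k4 - a1) / (a2 - a1)
    c2 = K1 * (a2 - k3 - k4) / (a2 - a1)
    return np.array([c1, c2]), np.array([a1, a2])


def exp_conv(values: np.ndarray, dt: float, beta: float) -> np.ndarray:
    """Convolve a uniformly sampled curve with exp(-beta t), exactly for a
    piecewise-linear integrand.

    Uses the recursion y[n] = a*y[n-1] + c0*f[n-1] + c1*f[n] with
    a = exp(-beta dt), evaluated as a single IIR filter pass.
    """
    f = np.asarray(values, dtype=float)
    if beta < 0:
        raise ValidationError("rate must be nonnegative")
    if beta * dt < 1e-12:  # degenerate: plain running integral
        out = np.concatenate([[0.0], np.cumsum((f[1:] + f[:-1]) * 0.5 * dt)])
        return out
    u = beta * dt
    a = np.exp(-u)
    em = -np.expm1(-u) / u          # (1 - e^-u)/u
    c1 = dt * (1.0 - em) / u        # weight of f[n]
    c0 = dt * (em - (1.0 - em) / u)  # weight of f[n-1]
    y = lfilter([c1, c0], [1.0, -a], f)
    # lfilter starts from y[0] = c1*f[0]; remove that homogeneous mode so y[0] = 0
    y -= c1 * f[0] * a ** np.arange(f.size)
    y[0] = 0.0
    return y


def simulate_tissue_tac(params: KineticParams, input_fn: InputFunction) -> np.ndarray:
    """Noise-free tissue concentration C_T(t) on the input function's grid."""
    amps, rates = tissue_impulse_response(params)
    out = np.zeros_like(input_fn.values)
    for amp, rate in zip(amps, rates):
        out += amp * exp_conv(input_fn.values, input_fn.dt, rate)
    return out


# --------------------------------------------------------------------------
# Basis construction and NNLS fit
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BasisGrid:
    """Log-spaced exponential rate grid between the slow and fast boundaries."""

    fast_boundary: float = FAST_BOUNDARY
    slow_boundary: float = SLOW_BOUNDARY_90MIN
    n_basis: int = 100
    include_vascular: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.slow_boundary < self.fast_boundary:
            raise ValidationError("need 0 < slow_boundary < fast_boundary")
        if self.n_basis < 2:
            raise ValidationError("need at least 2 basis rates")

    @property
    def betas(self) -> np.ndarray:
        return np.geomspace(self.slow_boundary, self.fast_boundary, self.n_basis)


@dataclass
class SpectralResult:
    """NNLS amplitudes on the rate grid and the V_T they imply."""

    alpha: np.ndarray
    beta: np.ndarray
    vt: float
    vascular_coeff: float
    residual_rss: float

    @property
    def n_components(self) -> int:
        return int(np.count_nonzero(self.alpha))


def make_basis(input_fn: InputFunction, grid: BasisGrid, schedule: FrameSchedule,
               vascular_curve: np.ndarray | None = None) -> np.ndarray:
    """Frame-averaged basis matrix, one column per grid rate.

    Column j holds the frame averages of ``Cp (*) exp(-beta_j t)``. When the
    grid requests a vascular component, a final column holds the frame
    averages of ``vascular_curve`` (the whole-blood curve when available;
    defaults to Cp itself).
    """
    if input_fn.t_end < schedule.scan_end_pi - 1e-6:
        raise ValidationError("input function does not cover the frame schedule")
    cols = []
    for beta in grid.betas:
        conv = exp_conv(input_fn.values, input_fn.dt, beta)
        cols.append(frame_average(conv, input_fn.dt, schedule))
    if grid.include_vascular:
        vc = input_fn.values if vascular_curve is None else np.asarray(vascular_curve, float)
        if vc.size != input_fn.values.size:
            raise ValidationError("vascular curve must share the input-function grid")
        cols.append(frame_average(vc, input_fn.dt, schedule))
    return np.column_stack(cols)


def spectral_fit(tac: np.ndarray, basis: np.ndarray, grid: BasisGrid,
                 weights: np.ndarray | None = None) -> SpectralResult:
    """Weighted NNLS fit of one time-activity curve against the basis."""
    tac = np.asarray(tac, dtype=float)
    if tac.ndim != 1 or tac.size != basis.shape[0]:
        raise ValidationError("TAC length must equal the basis row count")
    n_tissue = grid.n_basis
    if basis.shape[1] != n_tissue + int(grid.include_vascular):
        raise ValidationError("basis column count does not match the grid")
    if not np.any(basis):
        raise ValidationError("all-zero basis")
    if weights is None:
        weights = np.ones_like(tac)
    else:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights < 0):
            raise ValidationError("weights must be nonnegative")
    sw = np.sqrt(weights)
    coef, rnorm = nnls(basis * sw[:, None], tac * sw)
    alpha = coef[:n_tissue]
    vasc = float(coef[n_tissue]) if grid.include_vascular else 0.0
    vt = float(np.sum(alpha / grid.betas))
    return SpectralResult(alpha=alpha, beta=grid.betas.copy(), vt=vt,
                          vascular_coeff=vasc, residual_rss=float(rnorm**2))


def frame_weights(schedule: FrameSchedule, mode: str = "duration",
                  tac: np.ndarray | None = None) -> np.ndarray:
    """Fit weights per frame: 'uniform', 'duration', or 'duration_activity'
    (duration / max(activity, small), the count-statistics proxy)."""
    if mode == "uniform":
        return np.ones(schedule.n_frames)
    if mode == "duration":
        return schedule.duration.copy()
    if mode == "duration_activity":
        if tac is None:
            raise ValidationError("duration_activity weighting needs the TAC")
        floor = max(float(np.max(tac)) * 1e-3, 1e-12)
        return schedule.duration / np.maximum(np.asarray(tac, float), floor)
    raise ValidationError(f"unknown weights mode: {mode!r}")


def vt_image(dyn, roi_map, input_fn: InputFunction, grid: BasisGrid,
             weights_mode: str = "duration",
             vascular_curve: np.ndarray | None = None):
    """Voxelwise spectral analysis over a dynamic image.

    Fits every voxel inside the ROI map (label > 0), returning the 3-D V_T
    volume (NaN outside) and a per-ROI table of mean voxel V_T. ROIs with no
    voxels are reported with a NaN mean, never silently as zero. Only frames
    fully post-injection enter the fit.
    """
    schedule = dyn.schedule
    mask_frames = schedule.post_injection_mask()
    fit_sched = FrameSchedule(schedule.start[mask_frames], schedule.duration[mask_frames],
                              schedule.injection_offset)
    basis = make_basis(input_fn, grid, fit_sched, vascular_curve)
    w = frame_weights(fit_sched, weights_mode)

    labels = roi_map.labels
    if labels.shape != dyn.data.shape[:3]:
        raise ValidationError("ROI map shape does not match the dynamic image")
    vt_vol = np.full(labels.shape, np.nan)
    for ijk in np.argwhere(labels > 0):
        tac = dyn.data[tuple(ijk)][mask_frames]
        res = spectral_fit(tac, basis, grid, w)
        vt_vol[tuple(ijk)] = res.vt

    rows = []
    for label_id, region in roi_map.label_table.items():
        sel = labels == label_id
        mean_vt = float(np.nanmean(vt_vol[sel])) if np.any(sel) else np.nan
        rows.append({"region": region, "vt": mean_vt, "n_voxels": int(np.sum(sel))})
    return vt_vol, pd.DataFrame(rows)
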