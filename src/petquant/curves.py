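"""Core curve containers: sampled blood/plasma curves and uniform-grid input functions.

All times are seconds post-injection unless a loader states otherwise; all
activity concentrations are Bq/mL and decay-corrected to injection time.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


@dataclass
class SampledCurve:
    """An (irregularly) sampled activity curve: (time s, activity Bq/mL) pairs."""

    time: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.value.shape:
            raise ValidationError("time and value must be 1-D arrays of equal length")
        if self.time.size == 0:
            raise ValidationError("empty curve")
        if np.any(np.diff(self.time) <= 0):
            raise ValidationError("times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.time.size

    def interp(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation with constant extrapolation at both ends."""
        return np.interp(np.asarray(t, dtype=float), self.time, self.value)

    def auc(self) -> float:
        """Trapezoidal area under the curve over its sampled support (Bq·s/mL)."""
        return float(np.trapezoid(self.value, self.time))

    def scaled(self, c: float) -> "SampledCurve":
        return SampledCurve(self.time.copy(), self.value * c)


@dataclass
class InputFunction:
    """A parent-plasma input function on a uniform grid from 0 to scan end.

    ``provenance`` records how the curve was obtained: ``"ppif"`` (measured
    arterial chain), ``"pbif"`` (population curve scaled to the individual) or
    ``"true"`` (noise-free generator output).
    """

    values: np.ndarray
    dt: float = 1.0
    participant_id: str = ""
    provenance: str = "ppif"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValidationError("input function needs >= 2 grid values")
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if np.any(self.values < 0):
            raise ValidationError("input-function values must be nonnegative")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt

    @property
    def t_end(self) -> float:
        return (self.values.size - 1) * self.dt

    def value_at(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.time, self.values)

    def auc(self, t_end: float | None = None) -> float:
        """Trapezoidal AUC from 0 to ``t_end`` (defaults to the full grid)."""
        if t_end is None:
            return float(np.trapezoid(self.values, dx=self.dt))
        t = self.time
        mask = t <= t_end + 1e-9
        return float(np.trapezoid(self.values[mask], t[mask]))

    def peak_time(self, smooth_window_s: float = 0.0) -> float:
        """Time of the curve maximum, optionally after a moving-average smooth."""
        v = self.values
        if smooth_window_s > self.dt:
            w = max(1, int(round(smooth_window_s / self.dt)))
            kernel = np.ones(w) / w
            v = np.convolve(v, kernel, mode="same")
        return float(np.argmax(v) * self.dt)

    def scaled(self, c: float, provenance: str | None = None) -> "InputFunction":
        return InputFunction(self.values * c, self.dt, self.participant_id,
                             provenance or self.provenance)

    def as_sampled(self) -> SampledCurve:
        return SampledCurve(self.time, self.values.copy())


@dataclass
class DiscreteSampleTable:
    """Discrete arterial samples: whole blood, plasma and parent fraction.

    A NaN entry means the quantity was not measured for that sample; times are
    strictly increasing seconds post-injection.
    """

    time: np.ndarray
    wholeblood: np.ndarray
    plasma: np.ndarray
    parent_fraction: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("time", "wholeblood", "plasma", "parent_fraction"):
            arrays[name] = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arrays[name])
        n = arrays["time"].size
        if n == 0:
            raise ValidationError("empty discrete sample table")
        if any(a.shape != (n,) for a in arrays.values()):
            raise ValidationError("all columns must share one length")
        if np.any(arrays["time"] < 0):
            raise ValidationError("negative sample time")
        if np.any(np.diff(arrays["time"]) <= 0):
            raise ValidationError("sample times must be strictly increasing")
        for name in ("wholeblood", "plasma"):
            a = arrays[name]
            if np.any(a[np.isfinite(a)] < 0):
                raise ValidationError(f"negative {name} activity")
        pf = arrays["parent_fraction"]
        finite = pf[np.isfinite(pf)]
        if np.any((finite < 0) | (finite > 1)):
            raise ValidationError("parent_fraction outside [0, 1]")

    @property
    def n(self) -> int:
        return self.time.size

    def with_both_blood_measures(self) -> "DiscreteSampleTable":
        """Sub-table of samples where both whole blood and plasma were measured."""
        mask = np.isfinite(self.wholeblood) & np.isfinite(self.plasma)
        if not np.any(mask):
            raise ValidationError("no samples with both whole-blood and plasma values")
        return DiscreteSampleTable(self.time[mask], self.wholeblood[mask],
                                   self.plasma[mask], self.parent_fraction[mask])
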