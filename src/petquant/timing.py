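"""Frame schedules, decay correction and frame-averaging utilities.

Scanner sidecars give frame starts relative to acquisition start; the tracer
bolus is injected ``injection_offset`` seconds into the acquisition (30 s for
the emulated protocol). All kinetic computation uses seconds post-injection,
so the offset is subtracted once here and nowhere else.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

F18_HALF_LIFE_S = 109.77 * 60.0  # fluorine-18


@dataclass
class FrameSchedule:
    """Per-frame (start, duration) in seconds from acquisition start."""

    start: np.ndarray
    duration: np.ndarray
    injection_offset: float = 30.0

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.duration = np.asarray(self.duration, dtype=float)
        if self.start.ndim != 1 or self.start.shape != self.duration.shape:
            raise ValidationError("start and duration must be 1-D arrays of equal length")
        if self.start.size == 0:
            raise ValidationError("empty frame schedule")
        if np.any(np.diff(self.start) <= 0):
            raise ValidationError("frame starts must be strictly increasing")
        if np.any(self.duration <= 0):
            raise ValidationError("frame durations must be positive")
        ends = self.start + self.duration
        if np.any(self.start[1:] < ends[:-1] - 1e-9):
            raise ValidationError("frames overlap")
        if self.injection_offset < 0:
            raise ValidationError("injection offset must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.start.size

    # --- post-injection views -------------------------------------------------
    @property
    def start_pi(self) -> np.ndarray:
        return self.start - self.injection_offset

    @property
    def end_pi(self) -> np.ndarray:
        return self.start_pi + self.duration

    @property
    def mid_pi(self) -> np.ndarray:
        return self.start_pi + 0.5 * self.duration

    @property
    def scan_end_pi(self) -> float:
        return float(self.end_pi[-1])

    def post_injection_mask(self) -> np.ndarray:
        """Frames that lie entirely after the injection."""
        return self.start_pi >= -1e-9

    def is_frame_boundary(self, t_pi: float, tol: float = 1e-6) -> bool:
        edges = np.concatenate([self.start_pi, self.end_pi])
        return bool(np.any(np.abs(edges - t_pi) <= tol))

    def to_dict(self) -> dict:
        return {
            "FrameTimesStart": self.start.tolist(),
            "FrameDuration": self.duration.tolist(),
            "InjectionStart": self.injection_offset,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrameSchedule":
        try:
            return cls(np.asarray(d["FrameTimesStart"], dtype=float),
                       np.asarray(d["FrameDuration"], dtype=float),
                       float(d.get("InjectionStart", 30.0)))
        except KeyError as e:  # pragma: no cover - trivial
            raise ValidationError(f"timing sidecar missing key {e}") from e


def default_schedule(injection_offset: float = 30.0) -> FrameSchedule:
    """90-min variable-frame schedule: one pre-injection background frame, then
    short early frames lengthening to 600 s (27 frames total, ending 90 min
    post-injection). Frame edges land on every 10-min boundary from 15 min on,
    so the SUV epochs and the 60/70/80-min truncation points are frame-aligned.
    """
    durations = ([injection_offset] + [15.0] * 6 + [30.0] * 3 + [60.0] * 2
                 + [120.0] * 5 + [300.0] * 5 + [600.0] * 5)
    durations = np.asarray(durations)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(starts, durations, injection_offset)


def decay_factor(t_s: np.ndarray, half_life_s: float = F18_HALF_LIFE_S) -> np.ndarray:
    """exp(-lambda t): fraction of activity remaining t seconds after reference."""
    lam = np.log(2.0) / half_life_s
    return np.exp(-lam * np.asarray(t_s, dtype=float))


def decay_correct(values: np.ndarray, t_s: np.ndarray,
                  half_life_s: float = F18_HALF_LIFE_S) -> np.ndarray:
    """Correct measured activity at times ``t_s`` back to the reference time."""
    return np.asarray(values, dtype=float) / decay_factor(t_s, half_life_s)


def frame_average(fine_values: np.ndarray, dt: float,
                  schedule: FrameSchedule) -> np.ndarray:
    """Average a fine-grid curve (defined on t_pi = 0, dt, 2dt, ...) over each frame.

    Activity before injection (t_pi < 0) is zero, but a frame straddling the
    injection still divides by its full duration. Uses the cumulative
    trapezoidal integral, so the result is exact for piecewise-linear curves.
    """
    fine_values = np.asarray(fine_values, dtype=float)
    t_grid = np.arange(fine_values.size) * dt
    cum = np.concatenate([[0.0], np.cumsum((fine_values[1:] + fine_values[:-1]) * 0.5 * dt)])

    def integral_to(t):
        t = np.clip(t, 0.0, t_grid[-1])
        return np.interp(t, t_grid, cum)

    s, e = schedule.start_pi, schedule.end_pi
    if np.any(e > t_grid[-1] + 1e-6):
        raise ValidationError("fine grid does not cover the frame schedule")
    return (integral_to(e) - integral_to(s)) / schedule.duration
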