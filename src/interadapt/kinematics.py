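"""Raw-signal preprocessing: resampling, zero-phase low-pass filtering,
derivative estimation, movement-onset detection and line-crossing lookup.

Position data are linearly interpolated onto a uniform grid (0.008 s steps by
default, matching a 125 Hz tablet), low-pass filtered with a bidirectional
(zero-phase) Butterworth filter, and differentiated with backward differences
spanning the past two grid points (dt = 0.016 s), the convention standard in
tablet-based interception work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import ConfigError, NoCrossingError, NoOnsetError

__all__ = ["FilterSpec", "KinematicSeries", "preprocess", "detect_onset", "crossing_time"]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filter and resampling parameters.

    ``order`` is the order of the one-way Butterworth design; applying it
    forward and backward doubles the effective order while cancelling the
    phase lag.
    """

    cutoff_hz: float = 6.0
    order: int = 2
    sample_rate_hz: float = 125.0
    interp_step_s: float = 0.008

    def __post_init__(self) -> None:
        if not 0 < self.cutoff_hz < self.sample_rate_hz / 2:
            raise ConfigError("cutoff must lie in (0, Nyquist)")
        if self.order < 1:
            raise ConfigError("order must be >= 1")
        if abs(self.interp_step_s * self.sample_rate_hz - 1.0) > 1e-6:
            raise ConfigError("interp_step_s must equal 1/sample_rate_hz")

    def to_dict(self) -> dict:
        return {
            "cutoff_hz": self.cutoff_hz,
            "order": self.order,
            "sample_rate_hz": self.sample_rate_hz,
            "interp_step_s": self.interp_step_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FilterSpec":
        return cls(**d)


@dataclass
class KinematicSeries:
    """Filtered positions and their derivatives on a uniform time grid."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    speed: np.ndarray
    ax: np.ndarray
    ay: np.ndarray


def _backward_diff(values: np.ndarray, step: float) -> np.ndarray:
    """Derivative as change over the past two grid points (dt = 2*step);
    the first two samples are copied from the first computable value."""
    d = np.empty_like(values)
    d[2:] = (values[2:] - values[:-2]) / (2.0 * step)
    d[0] = d[1] = d[2]
    return d


def preprocess(t: np.ndarray, x: np.ndarray, y: np.ndarray, spec: FilterSpec | None = None) -> KinematicSeries:
    """Interpolate, zero-phase filter, and differentiate a sampled 2-D path.

    Gaps in ``t`` are permitted; linear interpolation fills them.  The filter
    is applied forward and backward (`scipy.signal.filtfilt`) so the output
    has no phase lag; reflective padding handles the edges.
    """
    spec = spec or FilterSpec()
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 8:
        raise ConfigError("need at least 8 samples")
    if np.any(np.diff(t) <= 0):
        raise ConfigError("sample times must be strictly increasing")

    step = spec.interp_step_s
    n = int(np.floor((t[-1] - t[0]) / step + 1e-9)) + 1
    tg = t[0] + step * np.arange(n)
    xg = np.interp(tg, t, x)
    yg = np.interp(tg, t, y)

    b, a = butter(spec.order, spec.cutoff_hz, fs=spec.sample_rate_hz)
    # pad with one full settling length so edge transients (and the tiny
    # forward/backward asymmetry they cause) are negligible
    padlen = min(int(np.ceil(8.0 * spec.sample_rate_hz / spec.cutoff_hz)), n - 1)
    xf = filtfilt(b, a, xg, padlen=padlen)
    yf = filtfilt(b, a, yg, padlen=padlen)

    vx = _backward_diff(xf, step)
    vy = _backward_diff(yf, step)
    speed = np.hypot(vx, vy)
    ax = _backward_diff(vx, step)
    ay = _backward_diff(vy, step)
    return KinematicSeries(t=tg, x=xf, y=yf, vx=vx, vy=vy, speed=speed, ax=ax, ay=ay)


def detect_onset(series: KinematicSeries, tolerance: float = 0.10) -> float:
    """Movement onset from the tangential-speed trace.

    The threshold is ``min + tolerance * (max - min)``.  The suprathreshold
    run containing the global speed peak is located, then walked backward to
    the last sample below threshold; onset is the time of the next (first
    suprathreshold) sample, so it is always grid-aligned and never after the
    peak.
    """
    sp = series.speed
    rng = float(np.ptp(sp))
    if rng <= 1e-9:
        raise NoOnsetError("speed trace is flat; no movement to detect")
    thr = float(np.min(sp)) + tolerance * rng
    peak = int(np.argmax(sp))
    i = peak
    while i > 0 and sp[i - 1] > thr:
        i -= 1
    return float(series.t[i])


def crossing_time(series: KinematicSeries, line_y: float) -> tuple[float, float]:
    """Time and x-position of the first upward crossing of ``y = line_y``.

    Linear interpolation between the bracketing grid samples.
    """
    y = series.y
    below = y < line_y
    up = below[:-1] & (y[1:] >= line_y)
    idx = np.nonzero(up)[0]
    if idx.size == 0:
        raise NoCrossingError(f"path never crosses y = {line_y}")
    i = int(idx[0])
    frac = (line_y - y[i]) / (y[i + 1] - y[i])
    t_c = series.t[i] + frac * (series.t[i + 1] - series.t[i])
    x_c = series.x[i] + frac * (series.x[i + 1] - series.x[i])
    return float(t_c), float(x_c)
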