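"""Adaptation-curve quantification.

Each subject's baseline-corrected TE over the adaptation phase is summarized
by a two-state ("hinge") curve ``min(a * trial, b)`` with intercept 0: a
linear rise of slope ``a`` (ms of TE per trial) up to a flat asymptote ``b``
(ms).  The slope and asymptote are z-standardized across subjects and summed
into the Adaptation Score, which rewards both fast and complete adaptation.
A saturating-exponential fit ``b_e * (1 - exp(-trial / tau))`` is provided as
the conventional cross-check; some adapters are genuinely non-exponential and
the fit then fails to converge, which is reported rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .errors import DegenerateDataError, TooFewTrialsError

__all__ = [
    "PiecewiseFit",
    "ExpFit",
    "AdaptationScores",
    "fit_two_state",
    "fit_exponential",
    "adaptation_scores",
    "moving_average",
]


@dataclass
class PiecewiseFit:
    a: float  # slope (ms of TE per trial)
    b: float  # asymptote (ms)
    breakpoint: float  # b / a (trials)
    sse: float  # residual sum of squares (ms^2)
    degenerate: bool = False


@dataclass
class ExpFit:
    tau: float  # time constant (trials)
    b_e: float  # asymptote (ms)
    sse: float
    converged: bool


@dataclass
class AdaptationScores:
    subject_ids: list[str]
    z_a: np.ndarray
    z_b: np.ndarray
    score: np.ndarray


def _hinge_sse_at(c: float, t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Conditional least squares for breakpoint ``c``: with z = min(t, c) the
    model y = a*z is linear in a, and b = a*c.  Returns (sse, a)."""
    z = np.minimum(t, c)
    denom = float(z @ z)
    a = max(float(z @ y) / denom, 0.0) if denom > 0 else 0.0
    r = y - a * z
    return float(r @ r), a


def fit_two_state(
    te_ms: np.ndarray, trials: np.ndarray | None = None, n_grid: int = 512
) -> PiecewiseFit:
    """Least-squares hinge fit of ``min(a * trial, b)`` with a, b >= 0.

    Parametrized by the breakpoint c = b/a: for each candidate c the optimal
    slope has a closed form, so the 2-D problem reduces to a 1-D scan over c
    (a dense grid over [~0, max trial] plus every observed trial index),
    refined by bounded continuum minimization around the grid optimum.
    """
    y = np.asarray(te_ms, dtype=float)
    t = np.arange(1, y.size + 1, dtype=float) if trials is None else np.asarray(trials, dtype=float)
    if y.size < 5:
        raise TooFewTrialsError("need at least 5 adaptation trials")
    degenerate = bool(np.ptp(y) < 1e-12)

    t_max = float(t.max())
    grid = np.unique(np.concatenate([np.linspace(t_max / n_grid, t_max, n_grid), t]))
    sses = np.empty_like(grid)
    for i, c in enumerate(grid):
        sses[i], _ = _hinge_sse_at(c, t, y)
    k = int(np.argmin(sses))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    best_c = grid[k]
    if hi > lo:
        res = minimize_scalar(
            lambda c: _hinge_sse_at(c, t, y)[0], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        if res.fun <= sses[k]:
            best_c = float(res.x)
    sse, a = _hinge_sse_at(best_c, t, y)
    return PiecewiseFit(a=a, b=a * best_c, breakpoint=best_c, sse=sse, degenerate=degenerate)


def fit_exponential(
    te_ms: np.ndarray, trials: np.ndarray | None = None, tau_flag_factor: float = 10.0
) -> ExpFit:
    """Multi-start least-squares fit of ``b_e * (1 - exp(-trial / tau))``.

    ``converged`` is False when the optimizer fails or the fitted time
    constant exceeds ``tau_flag_factor`` times the series length (the curve is
    then indistinguishable from a straight line over the observed window).
    """
    y = np.asarray(te_ms, dtype=float)
    t = np.arange(1, y.size + 1, dtype=float) if trials is None else np.asarray(trials, dtype=float)
    if y.size < 5:
        raise TooFewTrialsError("need at least 5 adaptation trials")
    n = float(t.max())

    def resid(p):
        b_e, tau = p
        return b_e * (1.0 - np.exp(-t / tau)) - y

    b0 = float(np.mean(y[t >= 0.75 * n])) if np.any(t >= 0.75 * n) else float(np.mean(y))
    best = None
    for tau0 in (1.0, 2.0, 5.0, 10.0, 20.0, 40.0):
        try:
            res = least_squares(
                resid, x0=[b0 if b0 != 0 else 1.0, tau0],
                bounds=([-np.inf, 1e-6], [np.inf, 50.0 * n]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return ExpFit(tau=float("nan"), b_e=float("nan"), sse=float("nan"), converged=False)
    b_e, tau = best.x
    sse = float(2.0 * best.cost)
    converged = bool(tau <= tau_flag_factor * n)
    return ExpFit(tau=float(tau), b_e=float(b_e), sse=sse, converged=converged)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = float(np.std(v, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateDataError("zero variance across subjects; cannot standardize")
    return (v - float(np.mean(v))) / sd


def adaptation_scores(
    fits: list[PiecewiseFit], subject_ids: list[str] | None = None
) -> AdaptationScores:
    """Cross-subject standardization of slope and asymptote; score = z_a + z_b.

    High scores mean relatively fast and relatively complete adaptation.
    """
    if len(fits) < 3:
        raise TooFewTrialsError("need at least 3 subjects to standardize")
    ids = subject_ids if subject_ids is not None else [f"S{i + 1:02d}" for i in range(len(fits))]
    a = np.array([f.a for f in fits], dtype=float)
    b = np.array([f.b for f in fits], dtype=float)
    z_a = _zscore(a)
    z_b = _zscore(b)
    return AdaptationScores(subject_ids=list(ids), z_a=z_a, z_b=z_b, score=z_a + z_b)


def moving_average(series: np.ndarray, window: int = 4) -> np.ndarray:
    """Trailing moving average, truncated at the start (for display only)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(series, dtype=float)
    out = np.empty_like(x)
    for i in range(x.size):
        j = max(0, i - window + 1)
        out[i] = x[j : i + 1].mean()
    return out
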