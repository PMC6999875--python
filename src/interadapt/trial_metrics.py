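"""Per-trial scalar metrics, exclusion rules, and subject series assembly.

The central quantity is the temporal hand error (TE): the time difference
between the hand and the target reaching the same point on the target's
trajectory line, positive when the hand leads.  From each trial we also
derive the movement time T, the mean tangential speed Mv between onset and
crossing, the absolute initial movement angle Ma, and the tangential speed at
the crossing (used for exclusions).  Per-subject series carry the
baseline-corrected TE (each subject's mean TE over the last 30 baseline
trials subtracted) and the baseline variances of Mv and Ma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import kinematics
from .errors import DegenerateDataError, TargetRangeError, TooFewTrialsError
from .kinematics import FilterSpec, KinematicSeries
from .task_simulator import TrialRecord

__all__ = [
    "TargetPath",
    "TrialMetrics",
    "SubjectSeries",
    "temporal_hand_error",
    "movement_angle",
    "compute_trial_metrics",
    "metrics_to_frame",
    "apply_exclusions",
    "build_subject_series",
    "build_all_series",
]

#: Window over which the initial movement angle is measured (s).
MA_WINDOW_S = 0.200


@dataclass(frozen=True)
class TargetPath:
    """Constant-velocity target motion along the trajectory line.

    Position at time ``t`` is ``x0 + direction * speed * (t - t0)``.
    ``t_end``, when given, bounds the traversed range for validity checks.
    """

    speed_cmps: float
    direction: int
    x0_cm: float
    t0_s: float = 0.0
    t_end_s: float | None = None

    def time_at(self, x: float) -> float:
        return self.t0_s + (x - self.x0_cm) / (self.direction * self.speed_cmps)


def temporal_hand_error(hand_crossing: tuple[float, float], target: TargetPath) -> float:
    """TE in seconds: target's arrival time at the hand's crossing x minus the
    hand's crossing time.  Positive when the hand arrives first (leads)."""
    t_hand, x_cross = hand_crossing
    t_target = target.time_at(x_cross)
    if target.t_end_s is not None and not (target.t0_s <= t_target <= target.t_end_s):
        raise TargetRangeError(
            f"crossing x = {x_cross:.3f} cm is outside the target's traversed range"
        )
    return t_target - t_hand


def movement_angle(series: KinematicSeries, onset_t: float, window_s: float = MA_WINDOW_S) -> float:
    """Absolute initial heading angle from the y-axis (degrees), measured as
    the displacement between onset and onset + ``window_s``.

    If the series ends early the last available sample is used.
    """
    i0 = int(np.searchsorted(series.t, onset_t - 1e-12))
    i1 = int(np.searchsorted(series.t, onset_t + window_s - 1e-12))
    i1 = min(i1, series.t.size - 1)
    dx = series.x[i1] - series.x[i0]
    dy = series.y[i1] - series.y[i0]
    if dx == 0.0 and dy == 0.0:
        raise DegenerateDataError("zero displacement over the angle window")
    return abs(math.degrees(math.atan2(dx, dy)))


@dataclass
class TrialMetrics:
    """Derived per-trial scalars."""

    subject_id: str
    trial_index: int
    phase: str
    onset_t: float
    crossing_t: float
    crossing_x: float
    T: float  # movement time onset -> crossing (s)
    Mv: float  # mean tangential speed onset -> crossing (cm/s)
    Ma: float  # absolute initial movement angle (deg)
    tv: float  # absolute target speed (cm/s)
    TE: float  # temporal hand error (s), + = hand leads
    crossing_speed: float
    valid: bool


def compute_trial_metrics(
    record: TrialRecord,
    spec: FilterSpec | None = None,
    crossing_speed_floor: float = 20.0,
    reach_distance_cm: float = 20.0,
) -> TrialMetrics:
    """Run the kinematic pipeline on one trial's hand trajectory.

    Trials whose hand path never crosses the target line, or that cross it
    below the speed floor, are marked invalid (metrics set to NaN where not
    computable) rather than raising.
    """
    spec = spec or FilterSpec()
    series = kinematics.preprocess(record.t, record.hand_x, record.hand_y, spec)
    nan = float("nan")
    try:
        onset = kinematics.detect_onset(series)
        t_c, x_c = kinematics.crossing_time(series, reach_distance_cm)
    except Exception:
        return TrialMetrics(
            subject_id=record.subject_id,
            trial_index=record.trial_index,
            phase=record.phase,
            onset_t=nan, crossing_t=nan, crossing_x=nan, T=nan, Mv=nan, Ma=nan,
            tv=record.target_speed_cmps, TE=nan, crossing_speed=nan, valid=False,
        )

    mask = (series.t >= onset) & (series.t <= t_c)
    mv = float(np.mean(series.speed[mask])) if mask.any() else nan
    ma = movement_angle(series, onset)
    cross_speed = float(np.interp(t_c, series.t, series.speed))

    target = TargetPath(
        speed_cmps=record.target_speed_cmps,
        direction=record.target_direction,
        x0_cm=float(record.target_x[0]),
        t0_s=float(record.t[0]),
    )
    te = temporal_hand_error((t_c, x_c), target)
    return TrialMetrics(
        subject_id=record.subject_id,
        trial_index=record.trial_index,
        phase=record.phase,
        onset_t=onset,
        crossing_t=t_c,
        crossing_x=x_c,
        T=t_c - onset,
        Mv=mv,
        Ma=ma,
        tv=record.target_speed_cmps,
        TE=te,
        crossing_speed=cross_speed,
        valid=bool(cross_speed >= crossing_speed_floor),
    )


def metrics_to_frame(metrics: list[TrialMetrics]) -> pd.DataFrame:
    return pd.DataFrame([vars(m) for m in metrics])


def apply_exclusions(
    frame: pd.DataFrame, floor_cmps: float = 20.0, subject_frac: float = 0.25
) -> tuple[pd.DataFrame, dict]:
    """Invalidate slow-crossing trials and drop non-complying subjects.

    Trials with crossing speed below ``floor_cmps`` (or no crossing at all)
    are marked invalid; subjects with more than ``subject_frac`` of their
    trials invalid are removed entirely.  Validity depends only on each
    trial's own metrics, so the result is order-independent.
    """
    frame = frame.copy()
    slow = frame["crossing_speed"].isna() | (frame["crossing_speed"] < floor_cmps)
    frame["valid"] = ~slow
    report: dict = {"floor_cmps": floor_cmps, "subject_frac": subject_frac, "subjects": {}}
    removed = []
    for sid, grp in frame.groupby("subject_id", sort=True):
        frac = float((~grp["valid"]).mean())
        report["subjects"][sid] = {
            "n_trials": int(len(grp)),
            "n_invalid": int((~grp["valid"]).sum()),
            "invalid_frac": frac,
            "removed": bool(frac > subject_frac),
        }
        if frac > subject_frac:
            removed.append(sid)
    report["removed_subjects"] = removed
    kept = frame[~frame["subject_id"].isin(removed)].reset_index(drop=True)
    n_kept_trials = int(kept["valid"].sum())
    report["n_trials_kept"] = n_kept_trials
    report["n_trials_discarded_in_kept_subjects"] = int(len(kept)) - n_kept_trials
    return kept, report


@dataclass
class SubjectSeries:
    """Ordered trial metrics for one subject with baseline-corrected TE.

    ``table`` keeps the original trial indices (invalid trials removed, gaps
    allowed) plus a ``te_corrected`` column (seconds) and, for adaptation
    trials, ``adapt_trial`` re-indexed to 1 at the first adaptation trial.
    """

    subject_id: str
    table: pd.DataFrame
    baseline_te_mean: float
    sigma2_Mv: float
    sigma2_Ma: float


def build_subject_series(frame: pd.DataFrame, n_baseline_tail: int = 30) -> SubjectSeries:
    """Assemble one subject's series from their (possibly mixed-validity)
    metrics rows; requires at least ``n_baseline_tail`` valid baseline trials.
    Baseline variances use the unbiased (n-1) estimator over valid baseline
    trials only."""
    sids = frame["subject_id"].unique()
    if len(sids) != 1:
        raise ValueError("build_subject_series expects a single subject's rows")
    sid = sids[0]
    df = frame.sort_values("trial_index").reset_index(drop=True)
    df = df[df["valid"]].reset_index(drop=True)
    base = df[df["phase"] == "baseline"]
    if len(base) < n_baseline_tail:
        raise TooFewTrialsError(
            f"subject {sid}: {len(base)} valid baseline trials < {n_baseline_tail}"
        )
    tail = base.tail(n_baseline_tail)
    te0 = float(tail["TE"].mean())
    df = df.copy()
    df["te_corrected"] = df["TE"] - te0
    adapt = df["phase"] == "adaptation"
    df["adapt_trial"] = np.nan
    if adapt.any():
        first = int(df.loc[adapt, "trial_index"].min())
        df.loc[adapt, "adapt_trial"] = df.loc[adapt, "trial_index"] - first + 1
    return SubjectSeries(
        subject_id=sid,
        table=df,
        baseline_te_mean=te0,
        sigma2_Mv=float(base["Mv"].var(ddof=1)),
        sigma2_Ma=float(base["Ma"].var(ddof=1)),
    )


def build_all_series(frame: pd.DataFrame, n_baseline_tail: int = 30) -> dict[str, SubjectSeries]:
    return {
        sid: build_subject_series(grp, n_baseline_tail)
        for sid, grp in frame.groupby("subject_id", sort=True)
    }
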