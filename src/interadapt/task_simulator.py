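"""Generative model of the delayed-feedback interception task.

Synthetic agents reach from a start position through a target's trajectory
line with a straight minimum-jerk movement while a target traverses that line
at constant speed.  In the adaptation phase the cursor that represents the
hand lags it by a fixed delay (100 ms by default).  Agents sense the temporal
error of the *cursor* relative to the target at the crossing — they cannot see
the hand itself — and correct the planned movement speed of subsequent trials
in proportion to that error.  Inter-agent differences in the correction gain
are the generative analogue of the inter-subject differences in trial-to-trial
error correction that the analysis side of this package measures.

Conventions
-----------
* The hand starts at the origin; the target line is ``y = reach_distance_cm``.
* The target moves along the line at speed ``tv`` in direction ``+1`` (left to
  right) or ``-1``; its motion is timed so that a noise-free agent moving at
  its habitual baseline speed crosses the line exactly when the target passes
  ``x = 0`` (temporal hand error zero by construction).
* Temporal hand error (TE) is positive when the hand leads the target.
* All randomness flows through one seeded :class:`numpy.random.Generator`;
  cohort simulation derives one independent substream per subject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigError

__all__ = [
    "TaskConfig",
    "AgentParams",
    "AgentState",
    "TrialRecord",
    "simulate_trial",
    "simulate_cohort",
    "default_cohort_spec",
]

#: Mean movement-onset time after trial start (s).  Onset noise is added on top.
ONSET_MEAN_S = 0.3

#: The aim point lies this far beyond the target line (cm); the task instructs
#: movements to end "well beyond" the line.
OVERSHOOT_CM = 4.0

#: Recording continues this long after the movement ends (s).
TAIL_S = 0.2


@dataclass(frozen=True)
class TaskConfig:
    """Geometry and schedule of the interception task."""

    reach_distance_cm: float = 20.0
    target_speeds_cmps: tuple[float, ...] = (17.5, 22.5, 27.5)
    n_baseline: int = 80
    n_adaptation: int = 80
    delay_s: float = 0.100
    sample_rate_hz: float = 125.0
    occlusion_window_cm: tuple[float, float] = (0.5, 16.0)
    crossing_speed_floor_cmps: float = 20.0

    def __post_init__(self) -> None:
        lo, hi = self.occlusion_window_cm
        if not (self.reach_distance_cm > hi > lo > 0):
            raise ConfigError(
                "require reach_distance_cm > occlusion upper > occlusion lower > 0"
            )
        if self.delay_s < 0:
            raise ConfigError("delay_s must be >= 0")
        if not all(s > 0 for s in self.target_speeds_cmps):
            raise ConfigError("target speeds must be positive")
        if self.n_baseline <= 0 or self.n_adaptation < 0:
            raise ConfigError("trial counts must be positive")
        if self.sample_rate_hz <= 0:
            raise ConfigError("sample_rate_hz must be positive")


@dataclass(frozen=True)
class AgentParams:
    """Parameters of one synthetic subject.

    ``gain`` is the change in planned speed (cm/s) per second of sensed cursor
    temporal error; ``retention`` is the fraction of a pending correction
    applied on the immediately following trial, the remainder being spread
    geometrically over later trials.
    """

    subject_id: str = "S01"
    gain: float = 20.0
    retention: float = 0.6
    planning_noise_sd: float = 0.5
    execution_noise_sd: float = 1.0
    observation_noise_sd: float = 0.010
    baseline_speed_cmps: float = 35.0
    onset_policy_sd: float = 0.020
    angle_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if not np.isfinite(
            [
                self.gain,
                self.retention,
                self.planning_noise_sd,
                self.execution_noise_sd,
                self.observation_noise_sd,
                self.baseline_speed_cmps,
                self.onset_policy_sd,
                self.angle_noise_sd,
            ]
        ).all():
            raise ConfigError("agent parameters must be finite")
        if self.gain < 0:
            raise ConfigError("gain must be >= 0")
        if not (0.0 <= self.retention <= 1.0):
            raise ConfigError("retention must lie in [0, 1]")
        for sd in (
            self.planning_noise_sd,
            self.execution_noise_sd,
            self.observation_noise_sd,
            self.onset_policy_sd,
            self.angle_noise_sd,
        ):
            if sd < 0:
                raise ConfigError("noise SDs must be >= 0")
        if self.baseline_speed_cmps <= 0:
            raise ConfigError("baseline speed must be positive")


@dataclass
class AgentState:
    """Mutable internal state carried between trials.

    ``planned_offset_cmps`` is the current adjustment of planned speed away
    from the habitual baseline; ``pending_cmps`` is the pool of corrections
    not yet applied (drained at rate ``retention`` per trial).
    """

    planned_offset_cmps: float = 0.0
    pending_cmps: float = 0.0


@dataclass
class TrialRecord:
    """Raw sampled trajectories and metadata for one trial."""

    subject_id: str
    trial_index: int  # 1-based across the whole session
    phase: str  # "baseline" | "adaptation"
    target_speed_cmps: float
    target_direction: int  # +1 (left->right) or -1
    t: np.ndarray
    hand_x: np.ndarray
    hand_y: np.ndarray
    cursor_x: np.ndarray
    cursor_y: np.ndarray
    target_x: np.ndarray
    truth: dict = field(default_factory=dict, repr=False)


# ----------------------------------------------------------------------------
# minimum-jerk machinery
# ----------------------------------------------------------------------------

def minjerk_position_fraction(tau: np.ndarray | float) -> np.ndarray | float:
    """Normalized minimum-jerk position profile s(tau) = 10t^3 - 15t^4 + 6t^5."""
    tau = np.clip(tau, 0.0, 1.0)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def minjerk_time_at_fraction(frac: float) -> float:
    """Normalized time at which the minimum-jerk profile reaches path fraction ``frac``."""
    if not 0.0 < frac < 1.0:
        raise ConfigError("fraction must lie strictly inside (0, 1)")
    return brentq(lambda x: minjerk_position_fraction(x) - frac, 0.0, 1.0, xtol=1e-14)


@dataclass(frozen=True)
class _Reach:
    """Closed-form straight minimum-jerk reach from the origin."""

    aim_x: float
    aim_y: float
    onset: float
    duration: float

    def position(self, t: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
        s = minjerk_position_fraction((np.asarray(t, dtype=float) - self.onset) / self.duration)
        return self.aim_x * s, self.aim_y * s


def _crossing_fraction(cfg: TaskConfig) -> float:
    return cfg.reach_distance_cm / (cfg.reach_distance_cm + OVERSHOOT_CM)


def nominal_crossing_time(cfg: TaskConfig, baseline_speed_cmps: float) -> float:
    """Trial time at which a noise-free, straight-ahead reach at the agent's
    baseline mean speed crosses the target line (the target is timed to pass
    x = 0 at this instant)."""
    length = cfg.reach_distance_cm + OVERSHOOT_CM
    tau_c = minjerk_time_at_fraction(_crossing_fraction(cfg))
    return ONSET_MEAN_S + tau_c * length / baseline_speed_cmps


# ----------------------------------------------------------------------------
# single-trial simulation
# ----------------------------------------------------------------------------

def simulate_trial(
    cfg: TaskConfig,
    agent: AgentParams,
    state: AgentState,
    phase: str,
    rng: np.random.Generator,
    target_speed_cmps: float | None = None,
    target_direction: int | None = None,
    trial_index: int = 1,
) -> tuple[TrialRecord, AgentState]:
    """Simulate one trial and return the record plus the updated agent state.

    Target speed and direction are drawn uniformly from the configured sets
    unless given explicitly.  The sensed error driving the speed update is the
    cursor-vs-target temporal error at the crossing (plus observation noise);
    the cursor lags the hand by ``cfg.delay_s`` in the adaptation phase.
    """
    if phase not in ("baseline", "adaptation"):
        raise ConfigError(f"unknown phase {phase!r}")
    if target_speed_cmps is None:
        target_speed_cmps = float(rng.choice(cfg.target_speeds_cmps))
    if target_direction is None:
        target_direction = int(rng.choice((-1, 1)))

    delay = cfg.delay_s if phase == "adaptation" else 0.0

    # planned speed of this trial: habitual baseline + accumulated corrections
    # + planning noise; execution noise perturbs the realized mean speed.
    planned = (
        agent.baseline_speed_cmps
        + state.planned_offset_cmps
        + rng.normal(0.0, agent.planning_noise_sd)
    )
    realized = planned + rng.normal(0.0, agent.execution_noise_sd)
    realized = max(realized, 5.0)  # guard against non-physical reversals

    onset = max(ONSET_MEAN_S + rng.normal(0.0, agent.onset_policy_sd), 0.05)
    theta = math.radians(rng.normal(0.0, agent.angle_noise_sd))
    aim_y = cfg.reach_distance_cm + OVERSHOOT_CM
    aim_x = aim_y * math.tan(theta)
    length = math.hypot(aim_x, aim_y)
    duration = length / realized
    reach = _Reach(aim_x=aim_x, aim_y=aim_y, onset=onset, duration=duration)

    frac = _crossing_fraction(cfg)
    tau_c = minjerk_time_at_fraction(frac)
    t_hand_cross = onset + tau_c * duration
    x_cross = aim_x * frac

    # target timing calibrated so the unperturbed habitual reach scores TE = 0
    t_star = nominal_crossing_time(cfg, agent.baseline_speed_cmps)
    tv = target_speed_cmps * target_direction  # signed velocity along the line

    t_target_at_cross = t_star + x_cross / tv
    te_hand = t_target_at_cross - t_hand_cross  # + = hand leads
    sensed = te_hand - delay + rng.normal(0.0, agent.observation_noise_sd)

    # sample the trajectories on the nominal grid
    dt = 1.0 / cfg.sample_rate_hz
    n = int(math.floor((onset + duration + TAIL_S) / dt)) + 1
    t = dt * np.arange(n)
    hand_x, hand_y = reach.position(t)
    cursor_x, cursor_y = reach.position(t - delay)
    target_x = tv * (t - t_star)

    record = TrialRecord(
        subject_id=agent.subject_id,
        trial_index=trial_index,
        phase=phase,
        target_speed_cmps=target_speed_cmps,
        target_direction=target_direction,
        t=t,
        hand_x=hand_x,
        hand_y=hand_y,
        cursor_x=cursor_x,
        cursor_y=cursor_y,
        target_x=target_x,
        truth={
            "te_hand_s": te_hand,
            "sensed_error_s": sensed,
            "realized_speed_cmps": realized,
            "planned_speed_cmps": planned,
            "onset_s": onset,
            "hand_cross_t_s": t_hand_cross,
            "hand_cross_x_cm": x_cross,
            "delay_s": delay,
        },
    )

    # first-order correction of planned speed: a late cursor (negative sensed
    # error) speeds the next trial up; corrections drain from a pending pool at
    # rate `retention`.
    pending = state.pending_cmps - agent.gain * sensed
    applied = agent.retention * pending
    new_state = AgentState(
        planned_offset_cmps=state.planned_offset_cmps + applied,
        pending_cmps=pending - applied,
    )
    return record, new_state


# ----------------------------------------------------------------------------
# cohort simulation
# ----------------------------------------------------------------------------

def simulate_session(
    cfg: TaskConfig, agent: AgentParams, rng: np.random.Generator
) -> list[TrialRecord]:
    """One full session (baseline then adaptation) for a single agent."""
    records: list[TrialRecord] = []
    state = AgentState()
    idx = 1
    for phase, count in (("baseline", cfg.n_baseline), ("adaptation", cfg.n_adaptation)):
        for _ in range(count):
            rec, state = simulate_trial(cfg, agent, state, phase, rng, trial_index=idx)
            records.append(rec)
            idx += 1
    return records


def simulate_cohort(
    cfg: TaskConfig, agents: list[AgentParams], seed: int
) -> list[TrialRecord]:
    """Simulate one session per agent; deterministic given ``seed``.

    Each subject draws from an independent substream derived from
    ``(seed, subject position)`` so cohorts are reproducible and subjects
    statistically independent.
    """
    if not agents:
        raise ConfigError("agent list must be non-empty")
    records: list[TrialRecord] = []
    for i, agent in enumerate(agents):
        rng = np.random.default_rng([int(seed), i])
        records.extend(simulate_session(cfg, agent, rng))
    return records


def default_cohort_spec(
    n_subjects: int,
    gain_range: tuple[float, float] = (0.0, 60.0),
    seed: int = 0,
    **overrides,
) -> list[AgentParams]:
    """Agents with correction gains evenly spread across ``gain_range``.

    All other parameters take the documented defaults, except the habitual
    baseline speed which is jittered slightly (SD 1.5 cm/s) across subjects so
    that agents are not clones; the jitter is deterministic given ``seed``.
    Keyword overrides are applied to every agent.
    """
    if n_subjects < 2:
        raise ConfigError("need at least 2 subjects")
    lo, hi = gain_range
    if not lo < hi:
        raise ConfigError("gain_range must satisfy lower < upper")
    rng = np.random.default_rng([int(seed), 997])
    gains = np.linspace(lo, hi, n_subjects)
    agents = []
    for i, g in enumerate(gains):
        base = AgentParams(
            subject_id=f"S{i + 1:02d}",
            gain=float(g),
            baseline_speed_cmps=35.0 + float(rng.normal(0.0, 1.5)),
        )
        if overrides:
            base = replace(base, **overrides)
        agents.append(base)
    return agents
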