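import numpy as np
import pytest

from interadapt.task_simulator import AgentParams, AgentState, TaskConfig, simulate_trial


def noise_free_agent(**kw) -> AgentParams:
    """Agent with every noise source switched off (deterministic reaches)."""
    base = dict(
        gain=0.0,
        planning_noise_sd=0.0,
        execution_noise_sd=0.0,
        observation_noise_sd=0.0,
        onset_policy_sd=0.0,
        angle_noise_sd=0.0,
    )
    base.update(kw)
    return AgentParams(**base)


def run_trials(cfg: TaskConfig, agent: AgentParams, phase: str, n: int, seed: int = 0):
    """Simulate n consecutive trials of one phase, returning the records."""
    rng = np.random.default_rng(seed)
    state = AgentState()
    records = []
    for i in range(n):
        rec, state = simulate_trial(cfg, agent, state, phase, rng, trial_index=i + 1)
        records.append(rec)
    return records


@pytest.fixture(scope="session")
def default_cfg() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def small_cohort_metrics():
    """Metrics table for a small simulated cohort (6 agents, 40+40 trials),
    shared across tests that only need realistic structure."""
    from interadapt.pipeline import PipelineConfig, compute_metrics
    from interadapt.task_simulator import default_cohort_spec, simulate_cohort

    cfg = TaskConfig(n_baseline=40, n_adaptation=40)
    agents = default_cohort_spec(6, (0.0, 60.0), seed=3)
    records = simulate_cohort(cfg, agents, seed=3)
    metrics = compute_metrics(records, cfg)
    pconfig = PipelineConfig(task=cfg, agents=agents, seed=3, n_baseline_tail=30)
    return cfg, agents, metrics, pconfig
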