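"""Volatile reversal-learning task generation.

The task is a two-armed probabilistic choice task with two 90-trial halves.
In the *stable* half one stimulus (the dominant one) carries the feedback
with a fixed probability of 0.75 on every trial. In the *volatile* half the
dominant stimulus carries feedback with probability 0.8, but the identity of
the dominant stimulus reverses every 20 trials. Exactly one of the two
stimuli carries feedback on each trial. Each stimulus additionally displays
a feedback magnitude (reward points or shock intensity) drawn uniformly from
the integers 1-99, independently per stimulus and trial.

A full experiment consists of two such 180-trial runs, one delivering reward
feedback and one aversive (shock) feedback, with the order of the stable and
volatile halves counterbalanced between runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "TaskRun",
    "CohortSpec",
    "generate_run",
    "generate_experiment",
    "synthesize_cohort",
    "runs_to_frame",
]

BlockOrder = Literal["stable_first", "volatile_first"]
FeedbackContext = Literal["reward", "aversive"]

# context code used throughout the package:
# (feedback_context, volatility) -> 0..3
CONTEXT_CODES = {
    ("reward", "stable"): 0,
    ("reward", "volatile"): 1,
    ("aversive", "stable"): 2,
    ("aversive", "volatile"): 3,
}


@dataclass(frozen=True)
class TaskConfig:
    """Design parameters of a single task run."""

    n_stable_trials: int = 90
    n_volatile_trials: int = 90
    p_stable: float = 0.75
    p_volatile: float = 0.8
    reversal_period: int = 20
    magnitude_range: tuple[int, int] = (1, 99)
    block_order: BlockOrder = "stable_first"
    feedback_context: FeedbackContext = "reward"
    # which stimulus is initially dominant in each block; None -> coin flip
    stable_s1_dominant: bool | None = None
    volatile_s1_dominant: bool | None = None

    def __post_init__(self) -> None:
        if not (0.5 < self.p_stable < 1.0):
            raise ValueError(f"p_stable must lie in (0.5, 1), got {self.p_stable}")
        if not (0.5 < self.p_volatile < 1.0):
            raise ValueError(f"p_volatile must lie in (0.5, 1), got {self.p_volatile}")
        if self.n_stable_trials < 0 or self.n_volatile_trials < 0:
            raise ValueError("trial counts must be non-negative")
        if self.reversal_period <= 0:
            raise ValueError("reversal_period must be positive")
        if self.block_order not in ("stable_first", "volatile_first"):
            raise ValueError(f"unknown block_order {self.block_order!r}")
        if self.feedback_context not in ("reward", "aversive"):
            raise ValueError(f"unknown feedback_context {self.feedback_context!r}")
        lo, hi = self.magnitude_range
        if not (0 < lo <= hi):
            raise ValueError("magnitude_range must satisfy 0 < lo <= hi")

    @property
    def n_trials(self) -> int:
        return self.n_stable_trials + self.n_volatile_trials

    def to_dict(self) -> dict:
        return {
            "n_stable_trials": self.n_stable_trials,
            "n_volatile_trials": self.n_volatile_trials,
            "p_stable": self.p_stable,
            "p_volatile": self.p_volatile,
            "reversal_period": self.reversal_period,
            "magnitude_range": list(self.magnitude_range),
            "block_order": self.block_order,
            "feedback_context": self.feedback_context,
            "stable_s1_dominant": self.stable_s1_dominant,
            "volatile_s1_dominant": self.volatile_s1_dominant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        if "magnitude_range" in d:
            d["magnitude_range"] = tuple(d["magnitude_range"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "TaskConfig":
        """Load from a YAML or JSON config file."""
        import json
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@dataclass
class TaskRun:
    """One 180-trial run, stored as flat per-trial arrays.

    ``feedback_stim`` is 1 where stimulus 1 carries the feedback on that
    trial and 2 otherwise. ``psi_true_s1`` is the true feedback probability
    of stimulus 1 (the probability for stimulus 2 is its complement).
    ``choice`` is 0 where no choice has been recorded yet.
    """

    config: TaskConfig
    m1: np.ndarray           # int magnitudes, raw 1..99
    m2: np.ndarray
    psi_true_s1: np.ndarray  # float
    feedback_stim: np.ndarray  # 1 | 2
    volatile: np.ndarray     # bool, per trial
    choice: np.ndarray = field(default=None)  # 1 | 2 | 0 (missing)
    # per-trial probability that each MOS strategy puts on stimulus 1,
    # filled by models.simulate for MOS agents; columns (EU, MO, HA)
    strategy_p1: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.m1)
        if self.choice is None:
            self.choice = np.zeros(n, dtype=np.int64)
        for name in ("m2", "psi_true_s1", "feedback_stim", "volatile", "choice"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} has inconsistent length")

    @property
    def n_trials(self) -> int:
        return len(self.m1)

    @property
    def has_choices(self) -> bool:
        return bool(np.all(self.choice > 0))

    @property
    def context_code(self) -> np.ndarray:
        """Per-trial context code 0..3 (feedback context x volatility)."""
        base = 2 if self.config.feedback_context == "aversive" else 0
        return base + self.volatile.astype(np.int64)

    def with_choices(self, choice: np.ndarray,
                     strategy_p1: np.ndarray | None = None) -> "TaskRun":
        out = replace(self, choice=np.asarray(choice, dtype=np.int64))
        out.strategy_p1 = strategy_p1
        return out

    def to_frame(self) -> pd.DataFrame:
        cfg = self.config
        return pd.DataFrame(
            {
                "trial_index": np.arange(self.n_trials),
                "feedback_context": cfg.feedback_context,
                "block_order": cfg.block_order,
                "volatility_label": np.where(self.volatile, "volatile", "stable"),
                "m1_raw": self.m1,
                "m2_raw": self.m2,
                "psi_true_s1": self.psi_true_s1,
                "feedback_stim": self.feedback_stim,
                "choice": np.where(self.choice > 0, self.choice, pd.NA),
            }
        )


def _block(n_trials: int, p: float, s1_dominant: bool, reversal_period: int | None,
           rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """psi_true_s1 trace and feedback assignment for one block.

    With ``reversal_period`` None the dominant stimulus is fixed; otherwise
    it flips every ``reversal_period`` trials (a final partial segment keeps
    the last dominant assignment).
    """
    t = np.arange(n_trials)
    if reversal_period is None:
        dominant_is_s1 = np.full(n_trials, s1_dominant)
    else:
        segment = t // reversal_period
        dominant_is_s1 = (segment % 2 == 0) == s1_dominant
    psi_s1 = np.where(dominant_is_s1, p, 1.0 - p)
    s1_feedback = rng.random(n_trials) < psi_s1
    feedback_stim = np.where(s1_feedback, 1, 2).astype(np.int64)
    return psi_s1, feedback_stim


def generate_run(config: TaskConfig, rng: np.random.Generator) -> TaskRun:
    """Generate one task run with the configured block structure."""
    stable_dom = config.stable_s1_dominant
    if stable_dom is None:
        stable_dom = bool(rng.random() < 0.5)
    volatile_dom = config.volatile_s1_dominant
    if volatile_dom is None:
        volatile_dom = bool(rng.random() < 0.5)

    psi_st, fb_st = _block(config.n_stable_trials, config.p_stable, stable_dom,
                           None, rng)
    psi_vo, fb_vo = _block(config.n_volatile_trials, config.p_volatile,
                           volatile_dom, config.reversal_period, rng)

    vol_st = np.zeros(config.n_stable_trials, dtype=bool)
    vol_vo = np.ones(config.n_volatile_trials, dtype=bool)
    if config.block_order == "stable_first":
        psi = np.concatenate([psi_st, psi_vo])
        fb = np.concatenate([fb_st, fb_vo])
        vol = np.concatenate([vol_st, vol_vo])
    else:
        psi = np.concatenate([psi_vo, psi_st])
        fb = np.concatenate([fb_vo, fb_st])
        vol = np.concatenate([vol_vo, vol_st])

    lo, hi = config.magnitude_range
    n = config.n_trials
    m1 = rng.integers(lo, hi + 1, size=n)
    m2 = rng.integers(lo, hi + 1, size=n)
    return TaskRun(config=config, m1=m1, m2=m2, psi_true_s1=psi,
                   feedback_stim=fb, volatile=vol)


def generate_experiment(config_pair: tuple[TaskConfig, TaskConfig],
                        rng: np.random.Generator) -> tuple[TaskRun, TaskRun]:
    """Generate the two runs of one experiment (reward and aversive)."""
    a, b = config_pair
    if a.feedback_context == b.feedback_context:
        raise ValueError("the two runs of an experiment must differ in feedback_context")
    return generate_run(a, rng), generate_run(b, rng)


@dataclass
class CohortSpec:
    """A group of simulated agents sharing a generating model.

    ``params`` maps parameter names to either scalars (all agents identical)
    or callables ``f(rng) -> float`` sampled per agent. ``run_configs`` lists
    the task runs each agent performs (default: the two-run counterbalanced
    experiment in the reward and aversive contexts).
    """

    group: str
    model_spec: "object"  # models.ModelSpec; kept loose to avoid an import cycle
    params: dict
    n_agents: int
    run_configs: Sequence[TaskConfig] | None = None
    synthetic_severity: "object" = None  # optional callable rng -> float

    def __post_init__(self) -> None:
        if self.n_agents < 0:
            raise ValueError("n_agents must be non-negative")


def default_experiment_configs(stable_first_reward: bool = True) -> list[TaskConfig]:
    """Reward + aversive run pair with counterbalanced block order."""
    r_order: BlockOrder = "stable_first" if stable_first_reward else "volatile_first"
    a_order: BlockOrder = "volatile_first" if stable_first_reward else "stable_first"
    return [
        TaskConfig(block_order=r_order, feedback_context="reward"),
        TaskConfig(block_order=a_order, feedback_context="aversive"),
    ]


def synthesize_cohort(spec: CohortSpec, rng: np.random.Generator):
    """Simulate a cohort of agents: returns (trial table, parameter table).

    Each agent's parameters are resolved from ``spec.params``, its runs
    generated from ``spec.run_configs`` and its choices simulated with the
    generating model. The trial table is tidy (one row per trial).
    """
    from . import models  # deferred: models imports task types

    run_configs = spec.run_configs or default_experiment_configs()
    trial_frames = []
    param_rows = []
    for i in range(spec.n_agents):
        params = {k: (v(rng) if callable(v) else v) for k, v in spec.params.items()}
        row = {"participant_id": f"{spec.group}-{i:03d}", "group": spec.group, **params}
        if spec.synthetic_severity is not None:
            row["severity"] = spec.synthetic_severity(rng)
        param_rows.append(row)
        for run_id, cfg in enumerate(run_configs):
            run = generate_run(cfg, rng)
            sim = models.simulate(spec.model_spec, params, run, rng)
            df = sim.to_frame()
            df.insert(0, "participant_id", row["participant_id"])
            df.insert(1, "group", spec.group)
            df.insert(2, "run_id", run_id)
            trial_frames.append(df)
    if trial_frames:
        trials = pd.concat(trial_frames, ignore_index=True)
    else:
        trials = pd.DataFrame()
    return trials, pd.DataFrame(param_rows)


def runs_to_frame(runs: Sequence[TaskRun], participant_id: str = "p000",
                  group: str = "NA") -> pd.DataFrame:
    """Tidy CSV-ready table for a list of runs from one participant."""
    frames = []
    for run_id, run in enumerate(runs):
        df = run.to_frame()
        df.insert(0, "participant_id", participant_id)
        df.insert(1, "group", group)
        df.insert(2, "run_id", run_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
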