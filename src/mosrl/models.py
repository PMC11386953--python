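"""The four model families for volatile reversal learning.

All families learn the feedback probability of stimulus 1 with the same
Rescorla-Wagner delta rule (full information: the feedback stimulus is
revealed by the task on every trial) and differ only in their decision
policy:

* **MOS** - mixture of strategies: a convex combination of an
  expected-utility (EU) softmax on psi*u(m), a magnitude-only (MO) softmax
  on u(m), and a habitual (HA) Bernoulli policy that tracks past choices.
  The mixture weights live on the simplex and are parameterized by softmax
  logits.
* **FLR** - flexible-learning-rate model: a logistic policy on a linear
  combination of the probability difference, a power-transformed magnitude
  difference, and the habit difference.
* **RS** - risk-sensitive expected utility: the EU policy applied to a
  linearly distorted (and clipped) probability estimate.
* **PH** - Pearce-Hall: the EU policy with an associability-driven running
  learning rate.

Each family has a context-free variant (one parameter set for all four task
contexts) and a context-dependent variant (some parameters fit separately
per reward/aversive x stable/volatile context, with valence-specific
learning rates for better- vs worse-than-expected outcomes). Free-parameter
counts: MOS 6/22, FLR 6/22, RS 3/13, PH 4/17.

Magnitudes are displayed as integers 1-99; models consume them rescaled to
(0, 1) by dividing by 100. In the aversive context utilities are negated,
u(m) = -m/100, so every policy prefers the lower expected shock.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _kernels
from .task import TaskRun

__all__ = [
    "ModelSpec",
    "ParamDef",
    "AgentState",
    "ParameterError",
    "MODEL_NAMES",
    "CONTEXT_LABELS",
    "init_state",
    "policy_mos",
    "policy_flr",
    "policy_rs",
    "policy_ph",
    "update_state",
    "nll",
    "simulate",
    "count_free_params",
    "softmax_weights",
]

CONTEXT_LABELS = ("rew_stab", "rew_vol", "ave_stab", "ave_vol")
MODEL_NAMES = ("MOS6", "MOS22", "FLR6", "FLR22", "RS3", "RS13", "PH4", "PH17")

LOG_FLOOR = 1e-12  # probability floor inside log


class ParameterError(ValueError):
    """A parameter violates its domain."""


@dataclass(frozen=True)
class ParamDef:
    """One free parameter: its name and the map from the unconstrained
    fitting scale to its native domain."""

    name: str
    transform: str  # "logistic" -> (0,1), "exp" -> (0,inf), "identity" -> R


def _ctx_name(base: str, ctx: int) -> str:
    return f"{base}@{CONTEXT_LABELS[ctx]}"


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus variant (and, for MOS, its strategy subset)."""

    family: str  # MOS | FLR | RS | PH
    context_dependent: bool = False
    strategy_set: tuple[str, ...] = ("eu", "mo", "ha")

    def __post_init__(self) -> None:
        if self.family not in ("MOS", "FLR", "RS", "PH"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.family == "MOS":
            if not self.strategy_set or not set(self.strategy_set) <= {"eu", "mo", "ha"}:
                raise ValueError(f"invalid strategy set {self.strategy_set!r}")

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        table = {
            "MOS6": ("MOS", False), "MOS22": ("MOS", True),
            "FLR6": ("FLR", False), "FLR22": ("FLR", True),
            "RS3": ("RS", False), "RS13": ("RS", True),
            "PH4": ("PH", False), "PH17": ("PH", True),
        }
        if name not in table:
            raise ValueError(f"unknown model name {name!r}; expected one of {MODEL_NAMES}")
        family, cd = table[name]
        return cls(family=family, context_dependent=cd)

    @property
    def name(self) -> str:
        return f"{self.family}{len(self.param_defs)}"

    @property
    def param_defs(self) -> tuple[ParamDef, ...]:
        fam, cd = self.family, self.context_dependent
        defs: list[ParamDef] = []
        if fam == "MOS":
            lams = [ParamDef(f"lam_{s}", "identity") for s in self.strategy_set]
            if not cd:
                defs = [ParamDef("beta", "exp"), ParamDef("alpha_ha", "logistic"),
                        ParamDef("alpha_psi", "logistic")] + lams
            else:
                defs = [ParamDef("beta", "exp"), ParamDef("alpha_ha", "logistic")]
                for c in range(4):
                    defs += [ParamDef(_ctx_name("alpha_psi_pos", c), "logistic"),
                             ParamDef(_ctx_name("alpha_psi_neg", c), "logistic")]
                    defs += [ParamDef(_ctx_name(f"lam_{s}", c), "identity")
                             for s in self.strategy_set]
        elif fam == "FLR":
            if not cd:
                defs = [ParamDef("alpha_ha", "logistic"), ParamDef("r", "exp"),
                        ParamDef("beta_ha", "exp"), ParamDef("alpha_psi", "logistic"),
                        ParamDef("beta", "exp"), ParamDef("lam_mix", "logistic")]
            else:
                defs = [ParamDef("alpha_ha", "logistic"), ParamDef("r", "exp")]
                for c in range(4):
                    defs += [ParamDef(_ctx_name("beta_ha", c), "exp"),
                             ParamDef(_ctx_name("alpha_psi_pos", c), "logistic"),
                             ParamDef(_ctx_name("alpha_psi_neg", c), "logistic"),
                             ParamDef(_ctx_name("beta", c), "exp"),
                             ParamDef(_ctx_name("lam_mix", c), "logistic")]
        elif fam == "RS":
            if not cd:
                defs = [ParamDef("beta", "exp"), ParamDef("alpha_psi", "logistic"),
                        ParamDef("gamma", "exp")]
            else:
                defs = [ParamDef("beta", "exp")]
                for c in range(4):
                    defs += [ParamDef(_ctx_name("alpha_psi_pos", c), "logistic"),
                             ParamDef(_ctx_name("alpha_psi_neg", c), "logistic"),
                             ParamDef(_ctx_name("gamma", c), "exp")]
        else:  # PH
            if not cd:
                defs = [ParamDef("alpha_psi0", "logistic"), ParamDef("k", "exp"),
                        ParamDef("eta", "logistic"), ParamDef("beta", "exp")]
            else:
                defs = [ParamDef("alpha_psi0", "logistic")]
                for c in range(4):
                    defs += [ParamDef(_ctx_name("k_pos", c), "exp"),
                             ParamDef(_ctx_name("k_neg", c), "exp"),
                             ParamDef(_ctx_name("eta", c), "logistic"),
                             ParamDef(_ctx_name("beta", c), "exp")]
        return tuple(defs)

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.param_defs)

    def to_dict(self, params: dict | None = None) -> dict:
        out = {"family": self.family,
               "variant": ("context_dependent" if self.context_dependent
                           else "context_free"),
               "strategy_set": list(self.strategy_set)}
        if params is not None:
            out["params"] = {k: float(v) for k, v in params.items()}
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(family=d["family"],
                   context_dependent=d.get("variant") == "context_dependent",
                   strategy_set=tuple(d.get("strategy_set", ("eu", "mo", "ha"))))


def count_free_params(spec: ModelSpec | str) -> int:
    """Number of free parameters of a model variant."""
    if isinstance(spec, str):
        spec = ModelSpec.from_name(spec)
    return len(spec.param_defs)


def softmax_weights(lams: Sequence[float]) -> np.ndarray:
    z = np.asarray(lams, dtype=float)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


# ---------------------------------------------------------------------------
# parameter resolution: named values -> per-context kernel matrix

_MATRIX_COLS = {
    "MOS": ("beta", "alpha_ha", "alpha_psi_pos", "alpha_psi_neg",
            "w_eu", "w_mo", "w_ha"),
    "FLR": ("beta", "beta_ha", "alpha_ha", "alpha_psi_pos", "alpha_psi_neg",
            "lam_mix", "r"),
    "RS": ("beta", "alpha_psi_pos", "alpha_psi_neg", "gamma"),
    "PH": ("beta", "k_pos", "k_neg", "eta", "alpha_psi0"),
}

# inverse temperatures and scale factors admit the boundary value 0 (the
# uniform-policy limit); the magnitude exponent r must be strictly positive
_NONNEG = {"beta", "beta_ha", "gamma", "k", "k_pos", "k_neg"}
_STRICT_POS = {"r"}
_UNIT = {"alpha_ha", "alpha_psi", "alpha_psi_pos", "alpha_psi_neg",
         "alpha_psi0", "eta"}
_CLOSED_UNIT = {"lam_mix"}


def _check_domain(name: str, value: float) -> float:
    base = name.split("@")[0]
    if base in _NONNEG and not value >= 0:
        raise ParameterError(f"{name} must be non-negative, got {value}")
    if base in _STRICT_POS and not value > 0:
        raise ParameterError(f"{name} must be positive, got {value}")
    if base in _UNIT and not (0.0 < value < 1.0):
        raise ParameterError(f"{name} must lie in (0, 1), got {value}")
    if base in _CLOSED_UNIT and not (0.0 <= value <= 1.0):
        raise ParameterError(f"{name} must lie in [0, 1], got {value}")
    if not math.isfinite(value):
        raise ParameterError(f"{name} is not finite")
    return float(value)


def _lookup(params: dict, base: str, ctx: int, cd: bool):
    """Fetch a parameter, trying the per-context name first for
    context-dependent variants and falling back to the shared name."""
    if cd:
        key = _ctx_name(base, ctx)
        if key in params:
            return params[key]
    return params.get(base)


def _mos_weights(params: dict, strategy_set: tuple[str, ...], ctx: int,
                 cd: bool) -> dict[str, float]:
    """Weights from logits (softmax) or directly from w_* entries."""
    lams = [_lookup(params, f"lam_{s}", ctx, cd) for s in strategy_set]
    if all(v is not None for v in lams):
        w = softmax_weights([float(v) for v in lams])
    else:
        ws = [_lookup(params, f"w_{s}", ctx, cd) for s in strategy_set]
        if any(v is None for v in ws):
            missing = [f"lam_{s}/w_{s}" for s, v in zip(strategy_set, ws) if v is None]
            raise ParameterError(f"missing MOS weight parameters: {missing}")
        w = np.asarray([float(v) for v in ws])
        if abs(w.sum() - 1.0) > 1e-6 or (w < -1e-12).any():
            raise ParameterError(f"MOS weights must lie on the simplex, got {w}")
        w = np.clip(w, 0.0, 1.0)
        w = w / w.sum()
    out = {"w_eu": 0.0, "w_mo": 0.0, "w_ha": 0.0}
    for s, v in zip(strategy_set, w):
        out[f"w_{s}"] = float(v)
    return out


def matrix_from_params(spec: ModelSpec, params: dict) -> np.ndarray:
    """Resolve named parameter values into the (4, p) per-context matrix
    consumed by the trial-loop kernels.

    Context-free variants accept plain names (``alpha_psi`` fills both the
    positive and negative learning-rate slots); context-dependent variants
    use ``name@ctx`` with ctx in rew_stab/rew_vol/ave_stab/ave_vol. MOS
    weights may be given as logits ``lam_*`` or directly as ``w_*``.
    """
    fam, cd = spec.family, spec.context_dependent
    cols = _MATRIX_COLS[fam]
    P = np.empty((4, len(cols)))
    for c in range(4):
        row: dict[str, float] = {}
        if fam == "MOS":
            row.update(_mos_weights(params, spec.strategy_set, c, cd))
        for col in cols:
            if col.startswith("w_"):
                continue
            if col in ("alpha_psi_pos", "alpha_psi_neg"):
                v = _lookup(params, col, c, cd)
                if v is None:
                    v = _lookup(params, "alpha_psi", c, cd)
            elif col in ("k_pos", "k_neg"):
                v = _lookup(params, col, c, cd)
                if v is None:
                    v = _lookup(params, "k", c, cd)
            else:
                v = _lookup(params, col, c, cd)
            if v is None:
                raise ParameterError(f"missing parameter {col!r} for {spec.name}")
            row[col] = _check_domain(col, float(v))
        P[c] = [row[col] for col in cols]
    return P


def params_from_vector(spec: ModelSpec, values: Sequence[float]) -> dict:
    """Named dict from a flat vector ordered like ``spec.param_defs``."""
    names = spec.param_names
    if len(values) != len(names):
        raise ValueError(f"{spec.name} expects {len(names)} values, got {len(values)}")
    return dict(zip(names, map(float, values)))


# ---------------------------------------------------------------------------
# reference scalar implementation (readable single-trial policy/update API)

@dataclass
class AgentState:
    """Latent learner state: psi and pi_HA refer to stimulus 1; the
    complements for stimulus 2 are implicit."""

    psi_s1: float = 0.5
    pi_ha_s1: float = 0.5
    alpha_psi: float | None = None  # Pearce-Hall running rate


def init_state(spec: ModelSpec, params: dict) -> AgentState:
    """Uninformative initial state; PH starts its running learning rate at
    the fitted initial value."""
    alpha = None
    if spec.family == "PH":
        alpha = _check_domain("alpha_psi0", float(params["alpha_psi0"]))
    return AgentState(psi_s1=0.5, pi_ha_s1=0.5, alpha_psi=alpha)


def _utilities(m1: float, m2: float, feedback_context: str) -> tuple[float, float]:
    sign = -1.0 if feedback_context == "aversive" else 1.0
    return sign * m1, sign * m2


def _logistic(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


def policy_mos(state: AgentState, m1: float, m2: float, params: dict,
               feedback_context: str = "reward",
               strategy_set: tuple[str, ...] = ("eu", "mo", "ha")):
    """MOS policy. Returns (mixture, p_eu, p_mo, p_ha) for stimulus 1.

    ``m1``, ``m2`` are magnitudes already rescaled to (0, 1).
    """
    beta = _check_domain("beta", float(params["beta"]))
    w = _mos_weights(params, strategy_set, 0, False)
    u1, u2 = _utilities(m1, m2, feedback_context)
    p_eu = _logistic(beta * (state.psi_s1 * u1 - (1.0 - state.psi_s1) * u2))
    p_mo = _logistic(beta * (u1 - u2))
    p_ha = state.pi_ha_s1
    mix = w["w_eu"] * p_eu + w["w_mo"] * p_mo + w["w_ha"] * p_ha
    return mix, p_eu, p_mo, p_ha


def policy_flr(state: AgentState, m1: float, m2: float, params: dict,
               feedback_context: str = "reward") -> float:
    beta = _check_domain("beta", float(params["beta"]))
    beta_ha = _check_domain("beta_ha", float(params["beta_ha"]))
    lam = _check_domain("lam_mix", float(params["lam_mix"]))
    r = _check_domain("r", float(params["r"]))
    dm = m1 - m2
    mag = math.copysign(abs(dm) ** r, dm) if dm != 0 else 0.0
    v = lam * (2.0 * state.psi_s1 - 1.0) + (1.0 - lam) * mag
    if feedback_context == "aversive":
        v = -v
    return _logistic(beta * v + beta_ha * (2.0 * state.pi_ha_s1 - 1.0))


def policy_rs(state: AgentState, m1: float, m2: float, params: dict,
              feedback_context: str = "reward") -> float:
    beta = _check_domain("beta", float(params["beta"]))
    gamma = _check_domain("gamma", float(params["gamma"]))
    psi_d = min(max(gamma * (state.psi_s1 - 0.5) + 0.5, 0.0), 1.0)
    u1, u2 = _utilities(m1, m2, feedback_context)
    return _logistic(beta * (psi_d * u1 - (1.0 - psi_d) * u2))


def policy_ph(state: AgentState, m1: float, m2: float, params: dict,
              feedback_context: str = "reward") -> float:
    beta = _check_domain("beta", float(params["beta"]))
    u1, u2 = _utilities(m1, m2, feedback_context)
    return _logistic(beta * (state.psi_s1 * u1 - (1.0 - state.psi_s1) * u2))


def _select_rate(pos: float, neg: float, pe: float, feedback_context: str) -> float:
    better = pe > 0 if feedback_context == "reward" else pe < 0
    return pos if better else neg


def update_state(state: AgentState, feedback_stim: int, chosen_stim: int,
                 params: dict, spec: ModelSpec,
                 feedback_context: str = "reward") -> AgentState:
    """One trial's learning step; returns a new state.

    The probability update is full-information (driven by the task-defined
    feedback stimulus); the habit update (MOS/FLR) tracks the chosen
    stimulus; PH updates its running rate from the pre-update prediction
    error before applying the scaled delta step.
    """
    o1 = 1.0 if feedback_stim == 1 else 0.0
    pe = o1 - state.psi_s1

    if spec.family == "PH":
        eta = _check_domain("eta", float(params["eta"]))
        if "k_pos" in params or "k_neg" in params:
            k = _select_rate(float(params["k_pos"]), float(params["k_neg"]),
                             pe, feedback_context)
        else:
            k = float(params["k"])
        _check_domain("k", k)
        alpha = state.alpha_psi + eta * (abs(pe) - state.alpha_psi)
        psi = min(max(state.psi_s1 + k * alpha * pe, 0.0), 1.0)
        return AgentState(psi_s1=psi, pi_ha_s1=state.pi_ha_s1, alpha_psi=alpha)

    if "alpha_psi_pos" in params or "alpha_psi_neg" in params:
        rate = _select_rate(float(params["alpha_psi_pos"]),
                            float(params["alpha_psi_neg"]), pe, feedback_context)
    else:
        rate = float(params["alpha_psi"])
    _check_domain("alpha_psi", rate)
    psi = state.psi_s1 + rate * pe

    pi_ha = state.pi_ha_s1
    if spec.family in ("MOS", "FLR"):
        alpha_ha = _check_domain("alpha_ha", float(params["alpha_ha"]))
        a1 = 1.0 if chosen_stim == 1 else 0.0
        pi_ha = pi_ha + alpha_ha * (a1 - pi_ha)
    return AgentState(psi_s1=psi, pi_ha_s1=pi_ha, alpha_psi=state.alpha_psi)


# ---------------------------------------------------------------------------
# fast sequential likelihood and simulation

_TRACE = {"MOS": _kernels.mos_trace, "FLR": _kernels.flr_trace,
          "RS": _kernels.rs_trace, "PH": _kernels.ph_trace}


def _pack(run: TaskRun):
    m1 = run.m1.astype(np.float64) / 100.0
    m2 = run.m2.astype(np.float64) / 100.0
    o1 = (run.feedback_stim == 1).astype(np.float64)
    ctx = run.context_code.astype(np.int64)
    val = -1.0 if run.config.feedback_context == "aversive" else 1.0
    return m1, m2, o1, ctx, val


def _as_runs(runs) -> list[TaskRun]:
    return [runs] if isinstance(runs, TaskRun) else list(runs)


def choice_probabilities(spec: ModelSpec, P: np.ndarray, run: TaskRun) -> np.ndarray:
    """Per-trial model probability of choosing stimulus 1 given the run's
    recorded choices (state is conditioned on the observed history)."""
    if not run.has_choices:
        raise ValueError("run has missing choices")
    m1, m2, o1, ctx, val = _pack(run)
    c1 = (run.choice == 1).astype(np.float64)
    dummy = np.empty(0)
    out = _TRACE[spec.family](m1, m2, o1, ctx, val, P, c1, dummy, False)
    return out[0]


def nll(spec: ModelSpec, params: dict | np.ndarray, runs) -> float:
    """Negative log-likelihood of recorded choices under the model.

    ``runs`` is a TaskRun or an iterable of TaskRuns; the learner state is
    re-initialized at each run boundary. Probabilities are floored at 1e-12
    inside the log.
    """
    if not isinstance(params, dict):
        params = params_from_vector(spec, params)
    P = matrix_from_params(spec, params)
    total = 0.0
    for run in _as_runs(runs):
        p1 = choice_probabilities(spec, P, run)
        p_chosen = np.where(run.choice == 1, p1, 1.0 - p1)
        total -= float(np.sum(np.log(np.maximum(p_chosen, LOG_FLOOR))))
    if not math.isfinite(total):
        raise FloatingPointError("non-finite negative log-likelihood")
    return total


def simulate(spec: ModelSpec, params: dict, run: TaskRun,
             rng: np.random.Generator) -> TaskRun:
    """Simulate choices on a task run; returns a new run with choices filled.

    For MOS agents the per-trial probabilities each strategy places on
    stimulus 1 are recorded in ``strategy_p1`` (columns EU, MO, HA), so
    per-strategy performance can be scored without running any strategy in
    isolation (the habit strategy only functions inside the mixture).
    """
    if not isinstance(params, dict):
        params = params_from_vector(spec, params)
    P = matrix_from_params(spec, params)
    m1, m2, o1, ctx, val = _pack(run)
    u = rng.random(run.n_trials)
    c_in = np.zeros(run.n_trials)
    out = _TRACE[spec.family](m1, m2, o1, ctx, val, P, c_in, u, True)
    strat = None
    if spec.family == "MOS":
        strat = out[1]
    c1 = out[-1]
    choice = np.where(c1 > 0.5, 1, 2).astype(np.int64)
    return run.with_choices(choice, strategy_p1=strat)


def latent_trace(spec: ModelSpec, params: dict, run: TaskRun):
    """Per-trial latent-state table (psi, pi_HA, running rate, policy and
    per-strategy probabilities) for debugging and figures.

    Steps the scalar reference implementation; the run must have choices.
    """
    import pandas as pd

    if not run.has_choices:
        raise ValueError("run has missing choices")
    fc = run.config.feedback_context
    ctx_params = []
    for label in CONTEXT_LABELS:
        sub = {}
        for d in spec.param_defs:
            base, _, suffix = d.name.partition("@")
            if not suffix or suffix == label:
                sub[base] = params[d.name] if d.name in params else params.get(base)
        ctx_params.append({k: v for k, v in sub.items() if v is not None})
    extra = {k: v for k, v in params.items() if "@" not in k}
    ctx_params = [dict(extra, **cp) for cp in ctx_params]

    state = init_state(spec, ctx_params[run.context_code[0]])
    rows = []
    for t in range(run.n_trials):
        cp = ctx_params[run.context_code[t]]
        m1, m2 = run.m1[t] / 100.0, run.m2[t] / 100.0
        row = {"trial_index": t, "psi_s1": state.psi_s1,
               "pi_ha_s1": state.pi_ha_s1, "alpha_psi": state.alpha_psi}
        if spec.family == "MOS":
            mix, p_eu, p_mo, p_ha = policy_mos(state, m1, m2, cp, fc,
                                               spec.strategy_set)
            row.update(p_choose_s1=mix, p_eu_s1=p_eu, p_mo_s1=p_mo,
                       p_ha_s1=p_ha)
        else:
            policy = {"FLR": policy_flr, "RS": policy_rs, "PH": policy_ph}
            row["p_choose_s1"] = policy[spec.family](state, m1, m2, cp, fc)
        rows.append(row)
        state = update_state(state, run.feedback_stim[t], run.choice[t],
                             cp, spec, fc)
    return pd.DataFrame(rows)
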