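"""Behavioral summaries: hit rates, volatile-minus-stable differences,
exemplar-aligned learning curves, and the routine group statistics.

A *hit* is a choice of the correct stimulus — the one with the higher true
feedback probability in the reward context, or the lower one in the
aversive context (shock avoidance). Correctness is defined from the task
contingency (psi_true), not the realized feedback, so it is well defined on
every trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .task import TaskRun

__all__ = [
    "hit",
    "run_hits",
    "HitRates",
    "hit_rate_and_difference",
    "align_to_exemplar",
    "align_series",
    "smooth_curve",
    "GroupStats",
    "welch_t",
    "paired_t",
    "pearson_r",
    "mixed_anova",
]


def hit(psi_true_s1, choice, feedback_context: str = "reward"):
    """1 where the chosen stimulus is the correct one, elementwise.

    ``choice`` is 1 or 2. Raises on a probability tie, where correctness is
    undefined (cannot occur with the default task design).
    """
    psi = np.asarray(psi_true_s1, dtype=float)
    ch = np.asarray(choice)
    if np.any(psi == 0.5):
        raise ValueError("psi_true = 0.5: correct stimulus undefined")
    s1_correct = psi > 0.5 if feedback_context == "reward" else psi < 0.5
    return np.where(s1_correct == (ch == 1), 1, 0)


def run_hits(run: TaskRun) -> np.ndarray:
    if not run.has_choices:
        raise ValueError("run has missing choices")
    return hit(run.psi_true_s1, run.choice, run.config.feedback_context)


@dataclass
class HitRates:
    overall: float
    stable: float
    volatile: float

    @property
    def difference(self) -> float:
        """Volatile minus stable hit rate."""
        return self.volatile - self.stable


def hit_rate_and_difference(runs) -> HitRates:
    """Block-masked hit rates pooled over one participant's runs."""
    run_list = [runs] if isinstance(runs, TaskRun) else list(runs)
    hits = np.concatenate([run_hits(r) for r in run_list])
    vol = np.concatenate([r.volatile for r in run_list])
    if not vol.any() or vol.all():
        raise ValueError("need trials in both the stable and volatile blocks")
    return HitRates(overall=float(hits.mean()),
                    stable=float(hits[~vol].mean()),
                    volatile=float(hits[vol].mean()))


def _block_flips(run: TaskRun) -> tuple[np.ndarray, np.ndarray]:
    """Reordering (stable half first) and per-trial label-flip mask that map
    a run onto the exemplar: stable-first with stimulus 1 dominant at the
    start of each block."""
    idx = np.arange(run.n_trials)
    order = np.concatenate([idx[~run.volatile], idx[run.volatile]])
    psi = run.psi_true_s1[order]
    n_st = int((~run.volatile).sum())
    flip = np.zeros(run.n_trials, dtype=bool)
    if n_st > 0 and psi[0] < 0.5:
        flip[:n_st] = True
    if n_st < run.n_trials and psi[n_st] < 0.5:
        flip[n_st:] = True
    return order, flip


def align_series(run: TaskRun, series_p1) -> np.ndarray:
    """Remap a per-trial probability-of-stimulus-1 series onto the exemplar
    task: the stable half comes first and stimulus labels are flipped
    blockwise so the true-probability trace matches the exemplar's."""
    p = np.asarray(series_p1, dtype=float)
    if p.shape[0] != run.n_trials:
        raise ValueError("series length does not match the run")
    order, flip = _block_flips(run)
    p = p[order]
    return np.where(flip, 1.0 - p, p)


def align_to_exemplar(run: TaskRun) -> np.ndarray:
    """Per-trial 0/1 indicator of choosing the exemplar reference stimulus."""
    if not run.has_choices:
        raise ValueError("run has missing choices")
    return align_series(run, (run.choice == 1).astype(float))


def aligned_psi_trace(run: TaskRun) -> np.ndarray:
    """The run's true-probability trace after exemplar alignment."""
    return align_series(run, run.psi_true_s1)


def smooth_curve(series, sigma: float = 2.0) -> np.ndarray:
    """Gaussian smoothing (SD in trials, truncated at 4 sigma) with the
    kernel renormalized at the boundaries; preserves length and constants."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite series")
    radius = int(math.ceil(4 * sigma))
    t = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (t / sigma) ** 2)
    kernel /= kernel.sum()
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


# ---------------------------------------------------------------------------
# group statistics

@dataclass
class GroupStats:
    test: str
    statistic: float
    df: float
    p_value: float
    effect_size: float
    effect_name: str


def _pooled_d(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    sp = math.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
                   / (nx + ny - 2))
    return float((x.mean() - y.mean()) / sp)


def welch_t(x, y) -> GroupStats:
    """Welch two-sample t test with Welch-Satterthwaite df and Cohen's d
    (pooled SD)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(x, y, equal_var=False)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    df = (vx + vy) ** 2 / (vx ** 2 / (len(x) - 1) + vy ** 2 / (len(y) - 1))
    return GroupStats("welch_t", float(res.statistic), float(df),
                      float(res.pvalue), _pooled_d(x, y), "cohen_d")


def paired_t(x, y) -> GroupStats:
    """Paired t test; Cohen's d = mean(diff) / sd(diff)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("paired samples must match and have n >= 2")
    diff = x - y
    res = stats.ttest_rel(x, y)
    d = float(diff.mean() / diff.std(ddof=1))
    return GroupStats("paired_t", float(res.statistic), float(len(x) - 1),
                      float(res.pvalue), d, "cohen_d")


def pearson_r(x, y) -> GroupStats:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("correlation needs matched samples with n >= 3")
    res = stats.pearsonr(x, y)
    return GroupStats("pearson_r", float(res.statistic), float(len(x) - 2),
                      float(res.pvalue), float(res.statistic), "pearson_r")


def mixed_anova(data: pd.DataFrame, dv: str, between: str, within: str,
                subject: str) -> pd.DataFrame:
    """Mixed between/within ANOVA with partial eta squared (one between and
    one within factor; collapse additional within factors by averaging
    before calling)."""
    import pingouin as pg

    return pg.mixed_anova(data=data, dv=dv, between=between, within=within,
                          subject=subject, effsize="np2")
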