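"""Model comparison: information criteria and random-effects group-level
Bayesian model selection with protected exceedance probabilities.

The random-effects scheme treats each participant's best model as a draw
from an unknown population frequency vector r with a flat Dirichlet prior.
The posterior over r is estimated by the standard variational iteration on
per-participant log model evidences; exceedance probabilities EP_k = P(r_k
is the largest) are estimated by Dirichlet Monte Carlo; the Bayesian
omnibus risk (BOR) compares the free energy of this model against the null
in which all models are equally frequent, and the protected exceedance
probability blends the two: PXP_k = (1 - BOR) * EP_k + BOR / K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp

from .fitting import FitResult

__all__ = ["aic_bic", "log_evidence", "evidence_table", "group_bms", "BmsResult"]


def aic_bic(fit: FitResult) -> tuple[float, float]:
    """AIC = 2k + 2*NLL and BIC = k*ln(n_trials) + 2*NLL."""
    if fit.n_trials == 0:
        raise ValueError("information criteria undefined for zero trials")
    return fit.aic, fit.bic


def log_evidence(fit: FitResult, method: str = "bic") -> float:
    """Per-participant log model evidence approximation.

    ``bic``: -BIC/2 (the default, robust choice). ``laplace``: Laplace
    approximation at the MAP using the optimizer's inverse-Hessian estimate,
    log p(y) ~ log posterior + (d/2) ln 2*pi + (1/2) ln |H^-1|.
    """
    if method == "bic":
        return -0.5 * fit.bic
    if method == "laplace":
        sign, logdet = np.linalg.slogdet(fit.inv_hessian)
        if sign <= 0:
            warnings.warn("inverse Hessian not positive definite; "
                          "falling back to -BIC/2")
            return -0.5 * fit.bic
        d = fit.n_params
        return fit.log_posterior + 0.5 * d * np.log(2 * np.pi) + 0.5 * logdet
    raise ValueError(f"unknown evidence method {method!r}")


def evidence_table(fits: dict, method: str = "bic") -> pd.DataFrame:
    """Participants x models table of log evidences.

    ``fits`` maps participant id -> {model name -> FitResult}.
    """
    rows = {pid: {m: log_evidence(f, method) for m, f in by_model.items()}
            for pid, by_model in fits.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.attrs["provenance"] = f"{method}_based"
    return df


@dataclass
class BmsResult:
    models: list
    alpha: np.ndarray            # Dirichlet concentrations
    expected_freq: np.ndarray
    ep: np.ndarray               # exceedance probabilities
    bor: float                   # Bayesian omnibus risk
    pxp: np.ndarray              # protected exceedance probabilities

    def to_dict(self) -> dict:
        return {
            "models": list(self.models),
            "alpha": self.alpha.tolist(),
            "expected_freq": self.expected_freq.tolist(),
            "ep": self.ep.tolist(),
            "bor": float(self.bor),
            "pxp": self.pxp.tolist(),
        }


def _dirichlet_kl(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    a_sum, a0_sum = alpha.sum(), alpha0.sum()
    return float(gammaln(a_sum) - gammaln(alpha).sum()
                 - gammaln(a0_sum) + gammaln(alpha0).sum()
                 + np.sum((alpha - alpha0) * (digamma(alpha) - digamma(a_sum))))


def group_bms(evidence, n_samples: int = 1_000_000,
              rng: np.random.Generator | None = None,
              tol: float = 1e-8, max_iter: int = 10_000) -> BmsResult:
    """Random-effects Bayesian model selection on a participants x models
    log-evidence table (DataFrame or array)."""
    if isinstance(evidence, pd.DataFrame):
        model_names = list(evidence.columns)
        L = evidence.to_numpy(dtype=float)
    else:
        L = np.asarray(evidence, dtype=float)
        model_names = list(range(L.shape[1]))
    if L.ndim != 2 or L.shape[0] < 2 or L.shape[1] < 2:
        raise ValueError("need >=2 participants and >=2 models")
    if not np.all(np.isfinite(L)):
        raise ValueError("non-finite log evidence")
    if n_samples < 10_000:
        warnings.warn(f"n_samples={n_samples} is small; exceedance "
                      "probabilities will be noisy")
    rng = rng or np.random.default_rng(0)
    n, K = L.shape

    alpha0 = np.ones(K)
    alpha = alpha0.copy()
    for _ in range(max_iter):
        ln_u = L + digamma(alpha) - digamma(alpha.sum())
        g = np.exp(ln_u - logsumexp(ln_u, axis=1, keepdims=True))
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    ln_u = L + digamma(alpha) - digamma(alpha.sum())
    g = np.exp(ln_u - logsumexp(ln_u, axis=1, keepdims=True))

    expected_freq = alpha / alpha.sum()

    # exceedance probabilities by Dirichlet Monte Carlo
    samples = rng.dirichlet(alpha, size=int(n_samples))
    winners = np.argmax(samples, axis=1)
    ep = np.bincount(winners, minlength=K) / float(n_samples)

    # free energy of the random-effects model vs the equal-frequency null
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = -np.sum(np.where(g > 0, g * np.log(g), 0.0))
    e_lik = float(np.sum(g * L))
    e_assign = float(np.sum(g * (digamma(alpha) - digamma(alpha.sum()))))
    f1 = e_lik + e_assign - _dirichlet_kl(alpha, alpha0) + entropy
    f0 = float(np.sum(logsumexp(L, axis=1) - np.log(K)))
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))

    pxp = (1.0 - bor) * ep + bor / K
    return BmsResult(models=model_names, alpha=alpha,
                     expected_freq=expected_freq, ep=ep, bor=bor, pxp=pxp)
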