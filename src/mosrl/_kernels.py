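"""Sequential trial-loop kernels for the four model families.

Each kernel walks one run trial by trial, maintaining the learner state
(feedback-probability estimate psi for stimulus 1, habit probability pi_HA,
and for Pearce-Hall the running learning rate), and emits the per-trial
probability of choosing stimulus 1. The same kernel serves likelihood
evaluation (choices given) and forward simulation (choices sampled from the
policy via pre-drawn uniforms).

Per-context parameters arrive as a (4, p) matrix, one row per context
(reward-stable, reward-volatile, aversive-stable, aversive-volatile); the
context-free variants simply repeat one row. ``val`` is +1 in the reward
context and -1 in the aversive context: magnitudes enter every policy as
utilities u(m) = val * m, so agents avoid probable shocks. Probability
learning is full-information (the feedback stimulus is defined by the task,
not by the choice); the habit update tracks the chosen stimulus.

Matrix column layouts:
  MOS: beta, alpha_ha, a_pos, a_neg, w_eu, w_mo, w_ha
  FLR: beta, beta_ha, alpha_ha, a_pos, a_neg, lam_mix, r
  RS:  beta, a_pos, a_neg, gamma
  PH:  beta, k_pos, k_neg, eta, alpha0
"""

import numpy as np
from numba import njit

__all__ = ["mos_trace", "flr_trace", "rs_trace", "ph_trace"]


@njit(cache=True, inline="always")
def _sigmoid(z):
    if z >= 0.0:
        return 1.0 / (1.0 + np.exp(-z))
    e = np.exp(z)
    return e / (1.0 + e)


@njit(cache=True, inline="always")
def _rate(a_pos, a_neg, pe, val):
    # valence-specific selection: a_pos applies to better-than-expected
    # outcomes, i.e. pe > 0 under reward and pe < 0 under aversive feedback
    if val > 0.0:
        return a_pos if pe > 0.0 else a_neg
    return a_pos if pe < 0.0 else a_neg


@njit(cache=True)
def mos_trace(m1, m2, o1, ctx, val, P, choice1, u, simulate):
    n = m1.shape[0]
    p1 = np.empty(n)
    strat = np.empty((n, 3))
    c1 = choice1.copy()
    psi = 0.5
    pi_ha = 0.5
    for t in range(n):
        beta, alpha_ha, a_pos, a_neg, w_eu, w_mo, w_ha = (
            P[ctx[t], 0], P[ctx[t], 1], P[ctx[t], 2], P[ctx[t], 3],
            P[ctx[t], 4], P[ctx[t], 5], P[ctx[t], 6])
        u1 = val * m1[t]
        u2 = val * m2[t]
        p_eu = _sigmoid(beta * (psi * u1 - (1.0 - psi) * u2))
        p_mo = _sigmoid(beta * (u1 - u2))
        p = w_eu * p_eu + w_mo * p_mo + w_ha * pi_ha
        p1[t] = p
        strat[t, 0] = p_eu
        strat[t, 1] = p_mo
        strat[t, 2] = pi_ha
        if simulate:
            c1[t] = 1.0 if u[t] < p else 0.0
        pe = o1[t] - psi
        psi += _rate(a_pos, a_neg, pe, val) * pe
        pi_ha += alpha_ha * (c1[t] - pi_ha)
    return p1, strat, c1


@njit(cache=True)
def flr_trace(m1, m2, o1, ctx, val, P, choice1, u, simulate):
    n = m1.shape[0]
    p1 = np.empty(n)
    c1 = choice1.copy()
    psi = 0.5
    pi_ha = 0.5
    for t in range(n):
        beta, beta_ha, alpha_ha, a_pos, a_neg, lam, r = (
            P[ctx[t], 0], P[ctx[t], 1], P[ctx[t], 2], P[ctx[t], 3],
            P[ctx[t], 4], P[ctx[t], 5], P[ctx[t], 6])
        dm = m1[t] - m2[t]
        if dm > 0.0:
            mag = dm ** r
        elif dm < 0.0:
            mag = -((-dm) ** r)
        else:
            mag = 0.0
        v = val * (lam * (2.0 * psi - 1.0) + (1.0 - lam) * mag)
        p = _sigmoid(beta * v + beta_ha * (2.0 * pi_ha - 1.0))
        p1[t] = p
        if simulate:
            c1[t] = 1.0 if u[t] < p else 0.0
        pe = o1[t] - psi
        psi += _rate(a_pos, a_neg, pe, val) * pe
        pi_ha += alpha_ha * (c1[t] - pi_ha)
    return p1, c1


@njit(cache=True)
def rs_trace(m1, m2, o1, ctx, val, P, choice1, u, simulate):
    n = m1.shape[0]
    p1 = np.empty(n)
    c1 = choice1.copy()
    psi = 0.5
    for t in range(n):
        beta, a_pos, a_neg, gamma = (
            P[ctx[t], 0], P[ctx[t], 1], P[ctx[t], 2], P[ctx[t], 3])
        psi_d = gamma * (psi - 0.5) + 0.5
        if psi_d > 1.0:
            psi_d = 1.0
        elif psi_d < 0.0:
            psi_d = 0.0
        u1 = val * m1[t]
        u2 = val * m2[t]
        p = _sigmoid(beta * (psi_d * u1 - (1.0 - psi_d) * u2))
        p1[t] = p
        if simulate:
            c1[t] = 1.0 if u[t] < p else 0.0
        pe = o1[t] - psi
        psi += _rate(a_pos, a_neg, pe, val) * pe
    return p1, c1


@njit(cache=True)
def ph_trace(m1, m2, o1, ctx, val, P, choice1, u, simulate):
    n = m1.shape[0]
    p1 = np.empty(n)
    c1 = choice1.copy()
    psi = 0.5
    alpha = P[ctx[0], 4]
    for t in range(n):
        beta, k_pos, k_neg, eta = (
            P[ctx[t], 0], P[ctx[t], 1], P[ctx[t], 2], P[ctx[t], 3])
        u1 = val * m1[t]
        u2 = val * m2[t]
        p = _sigmoid(beta * (psi * u1 - (1.0 - psi) * u2))
        p1[t] = p
        if simulate:
            c1[t] = 1.0 if u[t] < p else 0.0
        pe = o1[t] - psi
        # associability update first (with the pre-update prediction error),
        # then the scaled delta update; k may push k*alpha past 1, so clip psi
        alpha += eta * (abs(pe) - alpha)
        k = _rate(k_pos, k_neg, pe, val)
        psi += k * alpha * pe
        if psi > 1.0:
            psi = 1.0
        elif psi < 0.0:
            psi = 0.0
    return p1, c1
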