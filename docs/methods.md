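# Methods

## The task

`mosrl.task` simulates a two-armed volatile reversal-learning task. Each run
has 180 trials in two 90-trial halves. In the *stable* half one stimulus (the
dominant one) carries the feedback with probability 0.75 on every trial; in
the *volatile* half the dominant stimulus carries feedback with probability
0.8 and its identity reverses every 20 trials (with 90 trials and period 20
the final 10-trial segment keeps the last assignment). Exactly one stimulus
carries feedback per trial, so observing the chosen stimulus's outcome fully
reveals the feedback stimulus — learning is full-information. Each stimulus
displays a feedback magnitude drawn uniformly and independently from the
integers 1–99 per trial. A full experiment is two runs, one with reward
feedback and one with aversive (shock) feedback, with the stable/volatile
order counterbalanced between them. Which stimulus is initially dominant in
each half is a coin flip unless pinned in the `TaskConfig`.

Magnitudes are consumed by all models rescaled to (0, 1) by dividing by 100;
with utilities of order one, inverse temperatures of order ten are
well-scaled. In the aversive context utilities are negated, u(m) = −m/100, so
every policy prefers the lower expected shock; the generator itself is
valence-blind — the flip lives in the models and in the hit definition.

## The models

All four families learn the feedback probability ψ(s1) of stimulus 1 with
the same Rescorla–Wagner rule,

    ψ(s1) ← ψ(s1) + α_ψ (O(s1) − ψ(s1)),      ψ(s2) = 1 − ψ(s1),

where O(s1) indicates the trial's true feedback stimulus. Context-dependent
variants use valence-specific rates: α⁺ applies to better-than-expected
outcomes (prediction error > 0 under reward, < 0 under aversive feedback),
α⁻ to the rest. The families differ only in the decision policy:

* **MOS** (mixture of strategies): π = w_EU·π_EU + w_MO·π_MO + w_HA·π_HA,
  where π_EU(s1) = σ(β(ψ(s1)u(m1) − ψ(s2)u(m2))) is an expected-utility
  softmax, π_MO(s1) = σ(β(u(m1) − u(m2))) uses magnitude only, and π_HA is a
  habit distribution updated toward the chosen stimulus with rate α_HA. The
  weights live on the simplex and are fit as softmax logits λ.
* **FLR** (flexible learning rate): π(s1) = σ(βv + β_HA(π_HA(s1) − π_HA(s2)))
  with v = λ(ψ(s1) − ψ(s2)) + (1 − λ)·sign(Δm)|Δm|^r; in the aversive
  context the whole value v is negated (negating utilities inside both terms
  is algebraically the same as negating v).
* **RS** (risk-sensitive): the EU policy applied to the distorted estimate
  ψ̃ = clip(γ(ψ − 0.5) + 0.5, 0, 1).
* **PH** (Pearce–Hall): the EU policy with an associability-driven rate,
  α_ψ ← α_ψ + η(|O − ψ| − α_ψ) applied *before* the scaled update
  ψ ← ψ + k·α_ψ·(O − ψ) (the conventional ordering; k·α_ψ may exceed 1, so ψ
  is clipped to [0, 1]).

Free-parameter counts: MOS 6/22, FLR 6/22, RS 3/13, PH 4/17. The
context-dependent variants fit their per-context parameters separately to
each of the four contexts (reward/aversive × stable/volatile) within a
single joint likelihood; β and α_HA (MOS), α_HA and r (FLR), β (RS) and the
initial rate α_ψ0 (PH) are shared. The 17-parameter Pearce–Hall layout is
{α_ψ0 shared; k⁺, k⁻, η, β per context}: the policy has an inverse
temperature and no risk parameter, so the context-dependent inverse
temperature completes the count.

States initialize uninformatively (ψ = π_HA = 0.5; the PH rate at α_ψ0),
carry across the stable↔volatile boundary within a run (the transition is
unsignalled), and reset at run boundaries (separate sessions). Probabilities
are floored at 1e-12 inside the log.

The sequential likelihood and simulation loops are numba-compiled
(`mosrl._kernels`); a scalar reference implementation of every policy and
update lives in `mosrl.models` and the test suite pins the two paths
together to 1e-8.

## Fitting

MAP estimation per participant: rates are reparameterized through a
logistic, positive scales through an exponential, and mixture logits are
left unconstrained; each unconstrained coordinate gets an independent
Normal(0, variance 10) prior (the λ prior as specified; the same weak prior
is the simplest faithful choice for the remaining coordinates, and it has
little influence on fits with a run or more of data). The negative log
posterior is minimized with BFGS (numerical gradients, gradient tolerance
1e-5, 500 iterations) from multiple starts: the first at the prior mode,
the rest standard-normal draws on the unconstrained scale clipped to ±4.
Starts at the prior's own scale (SD ≈ 3.2) frequently land at extreme
inverse temperatures where the floored likelihood is flat and quasi-Newton
steps stall, so the tighter start distribution is used deliberately; it
covers the region where every parameter has behavioral consequences. With a
fixed generator the fit is exactly reproducible, and the best log posterior
is non-decreasing in the number of starts. All three MOS logits are fit;
the likelihood is invariant to their common shift and the prior resolves it
toward centered logits.

AIC = 2k + 2·NLL and BIC = k·ln(n_trials) + 2·NLL come from the fit;
group-level Bayesian model selection uses per-participant log evidences
(−BIC/2 by default, a Laplace approximation from the BFGS inverse Hessian
optionally), the standard variational Dirichlet iteration, Monte-Carlo
exceedance probabilities (10⁶ draws by default, seeded), the Bayesian
omnibus risk from the free-energy comparison against the equal-frequency
null, and PXP = (1 − BOR)·EP + BOR/K.

## Behavioral metrics

A *hit* is a choice of the stimulus with the higher true feedback
probability (reward) or the lower one (aversive); correctness is defined
from the contingency, never the realized feedback, so it exists on every
trial. Learning curves align runs to an exemplar (stable half first,
stimulus 1 dominant at the start of each half) by swapping halves in time
and flipping stimulus labels blockwise, then smooth with a Gaussian kernel
(SD 2 trials, truncated at 4σ, renormalized at the boundaries — no padding
data is fabricated). Group statistics: Welch t with Welch–Satterthwaite
degrees of freedom and pooled-SD Cohen's d, paired t with d =
mean(diff)/SD(diff), Pearson correlations, and a mixed between/within ANOVA
with partial η² (one between and one within factor; collapse extra within
factors by averaging first).

## Simulation studies

**Strategy decomposition.** Two arms of MOS6 agents share β = 10.803,
α_HA = 0.423, α_ψ = 0.473 and differ only in strategy logits
(healthy-control-like λ = (1.138, −1.547, 0.686); patient-like
(0.515, −0.220, 0.094)); each arm runs 100 experiments of two
reward-context runs with counterbalanced block order. Per-strategy
performance is scored as the probability mass the strategy places on the
correct stimulus while the mixture drives the state (the habit strategy
cannot perform the task alone). Under this generator the magnitude-only
strategy sits at chance, the habit strategy is markedly better in the
stable half (volatile-minus-stable difference ≈ −0.09), and the
expected-utility strategy dominates both with a near-zero difference
(≈ −0.005 ± 0.001 at the median learning rate): its tracking lag after each
reversal costs almost exactly what the higher volatile ceiling
(0.80 vs 0.75) gains. A positive expected-utility difference would require
the ceiling gain to dominate, which does not happen at learning rates near
0.5 on 20-trial reversal segments; this is a property of the design, not of
the estimator.

**Learning-rate adaptation.** 20 healthy-control-like (weights
0.60/0.15/0.25) and 20 patient-like (0.15/0.60/0.25) MOS6 datasets of four
runs each (reward/aversive × block order, fresh sequences per dataset) are
fit with FLR22; the per-context log learning rates are averaged over
valence and feedback context and contrasted between volatile and stable.
In this implementation the contrast is essentially null: FLR22 carries a
counterpart for each mixture component (probability term, magnitude term,
habit term), so it decomposes the generating mixture instead of
misattributing it to the learning rate — a single high-precision fit on 40
generated runs recovers α ≈ 0.47 in all four contexts and α_HA ≈ 0.42, and
the paired effect size across datasets scatters around zero. The study is
retained because it is the direct test of the misattribution hypothesis;
its outcome here is a negative result.

**Parameter recovery.** 80 datasets of 10 runs vary α_ψ and the three
logits (drawn from the fitting prior pushed through the transforms and
truncated to rates in [0.05, 0.95] and logits in [−3, 3] — the region
fitted participant populations occupy; outside it weights saturate and the
logit is unidentifiable from any amount of data), with β and α_HA fixed at
their medians. MAP refits use 10 starts at desk scale. Correlations are
reported on the native scale for α_ψ and the logit scale for weights; a
parameter with zero generating variance reports NaN, not 0. Because the
likelihood only identifies logits up to a common shift, per-logit
correlations are bounded near √(2/3) ≈ 0.82 even for a perfect fitter;
observed minima around 0.72–0.77 are close to that bound.

**Model recovery.** Each of the eight variants generates datasets
(default 10 per model, 10 runs cycling the four context × order
configurations); every variant is fit to every dataset; confusion is
summarized by mean AIC and BIC relative to the per-dataset best and by PXP
across datasets. Generating draws come from the truncated prior with the
additional requirement that each family's distinctive mechanism is engaged
(every MOS weight ≥ 0.10; PH η ≥ 0.20): a generating agent at a reduction
point — a mixture with a vanishing weight, an adaptive learner whose rate
never moves — is observationally equivalent to a strictly nested model, and
"which model generated the data" is then ill-posed. Even so, BIC-based
dominance is information-limited at desk scale: a context-free nested model
escapes the 16-parameter BIC penalty (≈ 16·ln n) whenever the generating
context spread earns fewer nats than that, so the context-dependent rows
(most visibly MOS22) and the near-equivalent RS3/PH4 pair can be won by the
nested neighbour at small run counts. The test suite asserts both the
strict all-rows claim and, separately, the robust sub-structure
(context-free dominance and the asymmetric MOS6/RS3 confusion).

## Problem sizes and numerics

The shipped defaults (80 recovery sets × 10 runs × 10 starts; 20 + 20
adaptation datasets; 8 × 5 × 8 × 3 model-recovery profile in the test
suite) were chosen so each study finishes in minutes on a single CPU while
keeping the designs' sample sizes at or near their full values; only the
optimizer restart count is reduced from 40, which measurement shows does
not move the optima on these problems (the first prior-mode start plus a
handful of unit-scale draws reach the same optima as larger start sets).
Exceedance probabilities at 10⁵–10⁶ Dirichlet draws are stable to two
decimals across seeds. Ties and degenerate inputs: equal displayed
magnitudes contribute exactly zero to the FLR magnitude term (sign(0) = 0);
a probability tie (ψ_true = 0.5) makes the hit undefined and raises; a
zero-trial fit returns the prior mode with log posterior equal to the log
prior.

## What the generator does and does not emulate

The synthetic cohorts reproduce the trial economy of the laboratory task
design (180-trial runs, 90/90 block split, 0.75/0.8 contingencies,
20-trial reversals, uniform 1–99 magnitudes, counterbalanced orders, two
feedback contexts) and group differences expressed purely through strategy
weights. They do not emulate: real participants' departures from any of the
eight model families, missing runs, within-session non-stationarity
(fatigue, drift), magnitude–probability correlations in the realized
sequences shown to humans, or clinically measured symptom scores (a
synthetic severity score can be attached per cohort). Passing recovery
tests therefore demonstrates identifiability of the machinery under its own
assumptions, not the validity of any model for human data.
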