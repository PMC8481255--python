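# Methods

## The model

`metadrift` analyses two-choice response-time/accuracy data from a 2×2
within-subject design — metaphor FAMILIARITY (familiar FM vs novel NM)
crossed with CONTEXT (supporting SC vs opposing OC) — with a hierarchical
Bayesian drift–diffusion model (DDM).

A trial is a Wiener process with drift *v* between absorbing boundaries at
0 and *a*, started at *z·a*, plus a non-decision offset *t₀*. The package
uses **accuracy coding**: the upper boundary is "correct", the lower
"error", and the start point is fixed at *z* = 0.5 (no bias toward correct
vs incorrect is expressible, which is the point of accuracy coding).
The **diffusion coefficient is fixed at 1**; parameters from tools using
the 0.1 convention must be multiplied by 10 before comparison.

The defective first-passage density at the lower boundary is evaluated by
the classical dual series

- small normalized time *w = t/a²*: Gaussian-image expansion
  `(2πw³)^{-1/2} Σ_k (z+2k) exp(-(z+2k)²/2w)`,
- large *w*: Fourier sine series `π Σ_k k exp(-k²π²w/2) sin(kπz)`,

choosing per evaluation whichever series needs fewer terms for a
truncation error ≤ 1e-7. The upper-boundary density follows by reflection
(*v → -v*, *z → 1-z*). Inter-trial variability is handled as

- drift: *v′ ~ Normal(v, s_v)*, integrated in closed form (the Gaussian
  integral has an explicit expression),
- non-decision time: *t₀′ ~ Uniform(t₀ - s_t/2, t₀ + s_t/2)*, integrated
  with 11-node Gauss–Legendre quadrature (validated in the test suite
  against adaptive quadrature to 1e-6 relative error),
- start point: no variability (*s_z = 0*), consistent with the fixed
  unbiased start.

Responses faster than the minimal non-decision time get log-likelihood
-∞ rather than an exception, so samplers reject such states gracefully.

## Hierarchy and model families

Participant *i*, condition *j* (factor codes F = ±0.5 for FM/NM,
C = ±0.5 for OC/SC, so each population effect is directly the FM-NM or
OC-SC drift difference):

- drift: `v_ij = v_i + bF_i·F_j + bC_i·C_j (+ β_v·score_i)`
- boundary: `a_i (+ β_a·score_i)` — condition-constant within participant
- non-decision time: `t0_i (+ β_t·score_i)` — condition-constant

Subject-level parameters are Normal draws from group-level means and SDs
(*a_i* and *t0_i* restricted to positive support via a joint indicator —
equivalently, the prior is the untruncated Normal conditioned on
positivity; the truncation constant is absorbed into the posterior
normalizer). `sv` and `st` are single group-level values shared across
participants. Covariate slopes are population-level only: the covariate is
between-subject (one score per participant), so subject-level slopes would
be unidentifiable. Covariate scores are z-scored across included
participants, which makes slopes comparable across the seven tests.

Three families: **Null** (no condition or covariate terms), **FC**
(condition effects on drift only), **Full** (FC plus one covariate's
slopes on drift, boundary, and non-decision time).

Group-level priors (moderately informative, all configurable):

| node | prior | rationale |
| --- | --- | --- |
| drift intercept mean | Normal(2, 3²) | typical two-choice drift scale |
| boundary mean | Gamma(shape 1.5, scale 1) | positive, mode below 1, long tail |
| non-decision mean | Normal(0.4, 0.2²) truncated ≥ 0 | a few hundred ms |
| effect / slope means | Normal(0, 1²) | effects of order ≤ 1 |
| group SDs | Half-Normal(1) | weakly regularizing |
| sv | Half-Normal(2) | drift variability of order 1 |
| st (s) | Half-Normal(0.3) | fraction of t₀ |

## Sampling

Metropolis-within-Gibbs with single-site Gaussian random-walk proposals.
Participants are conditionally independent given the group level, so each
subject-level family (v, bF, bC, a, t0) is proposed and accepted per
participant in one vectorized pass; group means/SDs are likelihood-free
updates (three sweeps per iteration, they are cheap and mix the hierarchy),
and `sv`, `st`, and the three slopes each require a full-data likelihood
pass. Per-node step sizes adapt every 50 burn-in iterations toward a
0.3–0.5 acceptance rate (×0.7 when below, ×1.4 when above) and are frozen
after burn-in, preserving detailed balance for the retained draws.
Initialization puts group locations at their prior means (non-decision
time capped at 80% of the fastest response so the likelihood is finite),
subjects at the group locations, everything jittered by 1%; up to 100
jittered restarts are attempted before declaring failure. Defaults are a
single chain of 12,000 iterations with 2,000 burn-in; every result is
reproducible bit-for-bit from the seed.

The likelihood core is compiled (numba) with a pure-numpy reference
implementation kept alongside; the test suite pins the two paths together
to 1e-10.

## Inference summaries

- **HDI**: the shortest contiguous window of sorted draws containing
  ⌈0.95·n⌉ points; ties resolve to the leftmost window. The decision rule
  "95% HDI excludes zero" declares an effect credible.
- **DIC**: deviance conditioned on subject-level parameters (the focused
  hierarchical variant): `D̄ + p_D` with `p_D = D̄ − D(θ̄)` at the
  posterior mean of all likelihood-relevant parameters. `p_D < 0` or a
  posterior mean outside the support flags non-convergence rather than
  failing.
- **Geweke**: first 10% vs last 50% of the chain, batch-mean standard
  errors with 20 batches per segment. Because the batch count is fixed,
  the raw statistic is Student-t (≈38 df via Welch–Satterthwaite), whose
  |t| < 2 band holds only ~94.7% of the time under an iid null; the
  statistic is therefore mapped through the t CDF onto the standard normal
  scale so the conventional |z| < 2 cut keeps its nominal level (measured
  95.3% over 1,000 iid chains in the suite).
- **Posterior predictive checks**: replicate datasets simulated from
  randomly chosen retained draws; per condition, accuracy and correct-RT
  deciles (0.1–0.9) are compared with the observed values via two-sided
  tail p-values (twice the smaller tail, counting replicates at or beyond
  the observed statistic). Censored replicate trials are dropped, exactly
  as the data pipeline drops them.

## Classical pipeline

- Participant screen: remove participants whose mean RT, or whose mean
  across the seven test scores (each z-scored first, so the scales are
  commensurable), is > 3 SD from the cohort mean. Trial screen: per
  participant, remove RTs > 3 SD from the participant mean, in a **single
  pass** with the mean/SD computed including the candidates (an iterated
  variant would remove more; the single pass is the least-assumption
  choice and the second pass's removals are logged if applied). Equality
  at exactly 3 SD never removes, so zero-spread participants lose nothing.
  Every stage appends a ledger entry (rule, counts before/after, percent).
- 2×2 repeated-measures ANOVA: with two-level factors each effect is
  carried by one within-subject contrast, so F is the squared one-sample t
  of the contrast with df (1, n−1) — algebraically identical to the
  MS_effect / MS_effect×subject decomposition (pinned to an independent
  general-linear-model oracle in the tests).
- Pairwise comparisons: paired t-tests over the four displayed condition
  pairs, Bonferroni-corrected by exactly those four.
- Correlation table: per (test, condition), Pearson r between z-scored
  test scores and z-scored mean correct RTs, two-sided p from the t
  transform (df = n−2), stars at 0.05/0.01/0.001 uncorrected.
- Welch t from summary statistics: `t = (m₁−m₂)/√(sem₁²+sem₂²)` with
  Welch–Satterthwaite df — for norming-style comparisons where only group
  summaries are available.

RTs are seconds internally and on disk; milliseconds only in summaries.

## Synthetic cohorts

The generator emulates the study design: 38 participants × 124 trials
(31 per cell), a 5 s response deadline (censored trials are flagged and
dropped by the pipeline with a ledger entry), and a seven-test covariate
battery with realistic score distributions (e.g. semantic fluency
44.79 ± 10.00). Trials are simulated from the hierarchical DDM itself by
Euler–Maruyama (default step 0.1 ms), so the generating parameters are
exact ground truth for recovery scoring.

Default truth: familiarity drift effect 0.76, context effect 0.06,
covariate slopes 0.16 / −0.11 / −0.03 on drift / boundary / non-decision
time for the semantic-fluency covariate only (the other six tests carry
zero true effect, making specificity testable). Base values — drift
intercept 1.5, boundary 2.0, non-decision time 0.4 s, sv 0.7, st 0.2 s —
were chosen once, via the closed-form choice probability and mean decision
time, to put condition accuracies in the mid-80s-to-mid-90s percent range
and the grand mean RT near 1 s. Exact joint targets (e.g. 93%/87% FM/NM
accuracy together with a 0.76 drift effect at boundary 2) are not
simultaneously attainable in this parameterization; the chosen defaults
land at roughly 95%/84% with FM ≈ 0.95 s and NM ≈ 1.13 s mean RT, which
preserves the qualitative structure (FM faster and more accurate, context
effect marginal).

What the generator does **not** emulate: item-level stimulus variability,
sequential effects (fatigue, practice), contaminant/guessing responses,
and any misspecification of the DDM itself. Passing recovery tests
therefore demonstrate correctness of the inference machinery under the
model, not robustness of the model on real data.

## Problem sizes in the test suite

The suite exercises recovery at the full design scale (38 × 124) with
reduced sampling (3,000 draws / 500 burn-in, 3 replicates), and the model
selection and type-I calibration properties on scaled-down cohorts
(12 participants × 40 trials, 20 replicates each) with proportionally
shorter chains — sizes chosen so each property retains a decisive margin
(e.g. DIC gaps of tens of units, familiarity-effect posteriors entirely
positive) while the whole suite stays desk-runnable. The simulator-vs-
density Kolmogorov–Smirnov check uses a 30 µs step because the
Euler–Maruyama first-passage bias is O(√dt) and would otherwise consume
most of the 0.01 tolerance.

## Known limitations

- Single-site random-walk sampling mixes more slowly than gradient-based
  samplers; variance components (`sv`, group SDs) carry the highest
  autocorrelation, and short chains can under-cover them.
- The censoring model is exclusion, not integration: censored trials are
  dropped rather than contributing a survival term (at the default truth
  censoring is < 2%, so the bias is negligible; with slow parameter
  regimes it would not be).
- `sz` (start-point variability) is intentionally absent.
- DIC is the only model-comparison score (no WAIC/LOO/bridge sampling),
  matching the analysis this package reproduces.
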