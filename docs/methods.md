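# Methods

`metasdt` analyzes prospective and retrospective metacognitive efficiency in a
two-group (instruction: bet vs. confidence), two-condition (difficulty: easy
vs. hard) auditory delayed match-to-sample design. This note documents the
models, the numerical choices, and what the synthetic-data generator does and
does not emulate.

## Type-1 and type-2 signal detection

The type-1 task is a match/nonmatch judgment. "Match" is treated as the
signal class: the hit rate is P(respond *match* | match) and the false-alarm
rate P(respond *match* | nonmatch), giving

    d' = z(HR) - z(FAR),      c = -(z(HR) + z(FAR)) / 2.

Edge correction adds 1/(2K) to every cell of the stimulus × response × rating
table before point estimation (K = number of rating levels), which is the
standard smoothing in the meta-d' literature and reduces to the familiar
+0.5-per-type-1-cell rule. Raw counts are used in all likelihoods.

Type-2 (metacognitive) sensitivity is **meta-d'**: the type-1 sensitivity an
SDT-ideal observer would need to produce the observed rating data. We use the
response-conditional Gaussian model (Maniscalco & Lau): metacognitive
evidence distributions sit at ±meta-d'/2 with unit variance, the type-1
criterion is rescaled to c' = c·meta-d'/d', and K−1 ordered type-2 criteria
per response side partition the evidence axis. Rating probabilities are
Gaussian-CDF segment ratios within each response region, and the
single-subject fit maximizes the multinomial likelihood of ratings
conditional on (stimulus, response) with d' and c fixed at their point
estimates. Criterion ordering is enforced by optimizing log-increments away
from c'; the optimizer is L-BFGS-B followed by a Nelder-Mead polish, started
from three initial meta-d' values (0.5, 1.0 and 1.5 × d', clipped to the
[−5, 5] search interval), with ties broken by likelihood and then by smaller
|meta-d'|. Likelihood probabilities are floored at 1e-12. **M-ratio** is
meta-d'/d'; 1 means ratings exploit all the evidence available to the
decision, values below 1 mean metacognitive information loss.

The binary prospective pre-rating (bet or memory belief) is analyzed as a
K = 2 rating, the retrospective confidence report as K = 5; both groups'
pre-ratings are treated at the same granularity.

## Hierarchical Bayesian group model

Per participant *s* and difficulty *c*, rating counts follow the type-2
multinomial likelihood at meta-d' = m(s,c) · d'(s,c), with a two-way mixed
linear model **on the M-ratio scale**:

    m(s,c) = mu + b_I·x_I(s) + b_D·x_D(c) + b_ID·x_I·x_D + u_s + eps(s,c)

with effect coding x_I = +0.5 (confidence group), x_D = +0.5 (hard), a
participant random intercept u_s ~ N(0, s_u²) ("mixed" part) and cell noise
eps ~ N(0, s_e²). Priors: mu ~ N(0.5, 1), b ~ N(0, 1), s_u, s_e ~
HalfNormal(1). Separate, independent models are fit to the pre- and
post-rating phases.

**Why an identity link rather than log.** A log link (meta-d' = exp(λ)·d') is
common because M-ratio is nominally positive-scaled, but at this design's
cell sizes (36 trials, binary pre-ratings) a substantial fraction of cells
shows a *negative* type-2 sample signal purely by chance. Under a log link
the likelihood of such a cell increases monotonically as λ → −∞ (a plateau at
the meta-d' = 0 boundary), so sampling noise turns into a one-sided pile-up
that biases the group mean and the difficulty contrast even on long,
converged chains (we measured ≈ −0.4 on mu and ≈ −0.3 on the difficulty
effect in simulation). Leaving m unbounded makes those cell posteriors
symmetric around small or mildly negative values and restores unbiased group
contrasts (recovered instruction effect −0.298 at truth −0.3 across
replicates). All effects are therefore reported in M-ratio units (an
instruction effect of −0.3 means the confidence group's M-ratio is 0.3
lower).

**Stabilized type-1 inputs.** The model follows two-stage practice: d' and c
are fixed per cell, not jointly sampled. Raw 36-trial estimates, however,
put d̂ near or below zero in ~10% of hard cells, which wrecks the M-ratio
scaling. By default both d' and c are therefore stabilized by
empirical-Bayes (James–Stein-style) shrinkage toward their instruction ×
difficulty group means, with weights from a delta-method variance
decomposition, and d' floored at 0.05. Shrinkage never pools across
instruction groups, so group contrasts cannot leak through it.
`stabilize_type1="none"` recovers the literal raw-estimate variant.

The shrinkage target is itself a noisy group mean, and its error moves every
cell of one instruction × difficulty design cell *coherently* — left
untreated this leaks into the within-participant (difficulty) contrast as
unmodeled variance (we measured the null-data spread of the difficulty
effect at ~1.4× its posterior width, with the excess correlated with the
group-level d̂ error). The sampler therefore treats the two
difficulty-level d' values as errors-in-variables nuisances: each gets an
additive offset parameter with a zero-centered Gaussian prior whose scale is
the delta-method standard error of the cohort mean, updated by Metropolis
against the full likelihood of that difficulty's cells. The offsets are
deliberately **shared across instruction groups**: both groups judge the
same stimuli, so the true d' is common, and a shared nuisance cannot absorb
an instruction contrast (a per-group offset would open a ridge
m·d ≈ const along which part of a real group effect leaks into the
nuisance, attenuating it). This restores the nominal false-positive rate of
the decision rule on null simulations without costing effect recovery.

**Type-2 criteria.** Each cell has its own 2(K−1) criteria, parameterized as
log-increments from c' and partially pooled toward an instruction ×
difficulty group mean (prior N(log 0.5, 1) on the group means,
HalfNormal(0.5) on the between-cell spread). Free per-cell criteria are
unidentifiable at K = 2 with 36 trials; pooling supplies the missing
information without forcing identical criteria.

**Sampler.** A vectorized Metropolis-within-Gibbs scheme written on numpy:

* per-cell m and criteria: adaptive random-walk Metropolis, all cells
  proposed and accepted in parallel (the likelihood factorizes over cells);
  three sweeps per iteration;
* u_s, the fixed effects, and the criterion group means: exact conjugate
  Gaussian updates;
* s_u, s_e and the criterion spread: log-scale Metropolis against their
  half-normal priors;
* blocked location moves that shift a participant's intercept together with
  both of their cell m values, and each fixed effect together with every
  cell it loads on (residuals stay invariant, so only the likelihood and the
  one prior term enter the ratio). These moves target the slow hierarchical
  directions and are what brings split-R-hat at the reduced test settings
  from ~1.3 down to ≤ 1.03.

Proposal scales adapt toward standard acceptance targets during burn-in only,
so the retained chain is a valid fixed-kernel Markov chain. Defaults are 3
chains × 10,000 iterations with 1,000 burn-in; the test suite and acceptance
script run 3 × 1,500/500, which we verified is enough for R-hat ≲ 1.03 and
tail-ESS in the hundreds on this model. With a fixed seed the draws are
bit-identical across runs; chains derive their generators from a spawned
`numpy.random.SeedSequence`.

**Summaries and decision rule.** Each fixed effect is summarized by the
pooled-chain posterior median, the 95% highest-density interval (shortest
contiguous interval over sorted draws), the probability of direction
(posterior mass on the dominant side of zero, zeros split evenly), the
rank-normalized split-R-hat and the tail effective sample size (both via
arviz). An effect is declared present exactly when the HDI excludes zero
*and* pd > 0.95. Summaries with R-hat ≥ 1.01 are returned but flagged
non-converged.

## Behavioral statistics

* **Exclusions.** A trial is dropped when any of the three responses
  (pre-rating, answer, post-rating) is missing or faster than 100 ms. A
  participant is dropped when, in either difficulty, all valid trials share
  one pre-rating value (the anti-fixing rule; the response field it applies
  to is configurable) or fewer than 18 valid trials remain.
* **Score.** High-risk bets pay +2 / −1 (correct / wrong), low-risk +1 / 0.
  The confidence group's score is emulated by mapping the high belief level
  to the high-risk option — the only order-preserving binary mapping.
* **Mixed ANOVA.** pingouin's mixed ANOVA with generalized eta squared
  (Olejnik–Algina; participant and residual variance components in the
  denominator). The test suite verifies F and η²G against an explicit
  sums-of-squares decomposition to 1e-10. Perfectly constant input
  (zero SS everywhere) is reported as F = 0, p = 1 rather than NaN.
* **Paired t with Bayes factor.** scipy paired t, Cohen's d =
  mean(diff)/sd(diff), and the JZS BF10 with the default Cauchy prior
  (r = √2/2) via pingouin; verified against direct quadrature of the Rouder
  integral. Zero-variance differences are an error, so the textbook "x equals
  y" case must carry at least numerical jitter.
* **Levene + Holm.** Original (mean-centered) Levene per difficulty on
  participant-level mean pre-ratings, with Holm step-down adjustment across
  the two difficulty tests. No other family-wise correction is applied
  anywhere, matching the analysis plan the pipeline implements.

## Synthetic-data generator

One simulated trial: stimulus match/nonmatch with p = 0.5; type-1 evidence
x ~ N(±d'/2, 1); response by criterion (default 0). Metacognitive evidence is
y = x + N(0, σ_meta); the pre-rating thresholds z = sign(response)·(y − c) at
θ_pre = 0.6 (bet high when z ≥ θ_pre), the post-rating bins a second
metacognitive sample at θ_post = (0.4, 0.8, 1.2, 1.6) into five levels. The
pre- and post-phase noises share a common component (`meta_noise_corr`,
default 0.3); together with the shared x this produces the positive pre→post
association seen in real data.

σ_meta is not a free dial: per cell it is solved so that the *asymptotic*
meta-d' MLE equals the target M-ratio. The solver computes exact joint
(stimulus, response, rating) probabilities from bivariate-normal rectangle
integrals, fits meta-d' to those expected proportions, tabulates M(σ) on a
grid, and inverts by interpolation (cached per d', criterion and threshold
set). M-ratio = 1 corresponds exactly to σ = 0 — ratings thresholding the
very sample that drove the decision. Targets above 1 (super-optimal) are
supported by adding stimulus-locked signal to y instead of noise and trigger
a warning when a design cell's mean requests them.

Per-cell targets come from the same two-way mixed linear model the
hierarchical fit estimates. Defaults are the study's conditions: groups of
104 (bet) and 100 (confidence); 6 sessions × 12 trials with difficulty
blocked in session halves, order counterbalanced by participant parity; d'
calibrated to 70% (easy) and 60% (hard) expected accuracy (d' = 1.049 and
0.507); pre-phase effects mean 0.75, instruction −0.35, difficulty 0;
post-phase mean 0.75, instruction −0.2, difficulty −0.25 (confidence group
and hard condition lower, matching the direction of the findings the design
targets); participant SD 0.2, cell SD 0.1; sub-zero target draws (<1% at
these settings) floored at 0.02. Lapses hit 2% of trials: one of the three
responses becomes missing or faster than 100 ms (uniform 0–99 ms), with
response times otherwise log-normal (median 800 ms, σ = 0.4) — RTs exist
only to exercise the exclusion rules.

**What the generator does not emulate:** the acoustic stimuli (difficulty
acts only through d'), learning or sequential effects across sessions,
feedback-driven strategy changes, RT dynamics beyond exclusions, and any
dependence of the type-1 criterion on instruction. Passing recovery tests
therefore show the estimation pipeline is calibrated for data of this
structure; they cannot certify the psychological assumptions themselves.

## Problem sizes used in tests

The acceptance-style checks run at the design's scale with reduced MCMC
settings (3 × 1,500/500): 20 replicate cohorts of 40 + 40 participants for
effect recovery and null calibration, one full 104 + 100 cohort for the
performance/metacognition dissociation, 20 random tables for the MLE–grid
comparison, and 200,000 trials with 5-point ratings for the ideal-observer
check (at a few thousand binary-rating trials the sampling dispersion of the
fitted M-ratio, ~0.09, would exceed the property being tested; 200k brings it
to ~0.006).

## Known limitations

* Type-1 parameters are stabilized point estimates, not jointly sampled;
  group-level d' uncertainty is propagated through the errors-in-variables
  offsets, but residual per-cell d'/c uncertainty is not.
* The identity link admits (rare) negative cell-level M-ratios by design;
  group-level summaries are the meaningful quantities.
* The split-plot ANOVA follows pingouin's least-squares conventions for
  mildly unbalanced groups (104 vs 100); heavily unbalanced designs were not
  a target.
* Pre-phase meta-d' at K = 2 with 36 trials is weakly identified per
  participant; all single-cell quantities in that regime should be read
  through the hierarchical posterior, never as individual estimates.
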