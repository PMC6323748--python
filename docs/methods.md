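# Methods

## Model and estimation

Each gene is analyzed independently. Tumor expression values (log scale) are
modeled as a three-component Gaussian mixture with ordered means
μ₁ ≤ μ₂ ≤ μ₃ and one shared standard deviation σ; normal-sample expression is
modeled as draws from the middle component alone. The shared variance
prevents one component from collapsing onto a few points and claiming
unreasonable memberships; the normal anchor gives the middle mode its
interpretation — "similar to normal" — and identifies the labeling (without
it, component labels are arbitrary).

The EM alternates:

* E-step: responsibilities of the three components for each tumor sample.
  Two weightings are provided. `standard` (default) is the classic mixture
  posterior π_j f_j / Σ_k π_k f_k, which guarantees the log-likelihood never
  decreases. `paper_literal` is the plain density ratio f_j / Σ_k f_k; it is
  not a true posterior and carries no ascent guarantee, but is retained as a
  documented variant because the downstream updates (π from responsibility
  sums, the cutoff formula) are well defined under it too. Which variant a
  given historical analysis used is generally unknowable from a published
  formula alone; both are first-class and tested.
* M-step: π_j = Σ_i γ_ij / n_tumor; μ_j = responsibility-weighted tumor mean,
  with the full normal sample added to the middle component's numerator and
  denominator; σ² pools the responsibility-weighted tumor residuals and the
  normal residuals around μ₂, divided by n_tumor + n_normal.

Ordering violations in the mean update are resolved by pooling: if the
unconstrained μ₁ exceeds μ₂, both are set to their combined weighted mean
(similarly μ₂/μ₃, or all three when both adjacencies are violated). Pooled
means are an absorbing state: once two components share a mean, their
responsibilities stay proportional and the components never separate again.
One guard goes beyond the three pooling cases: if pooling one adjacent pair
leaves the remaining pair out of order (possible when the non-pooled mean
lies between the two pooled ones), all three means are pooled, keeping the
ordering invariant unconditionally. An empty component (zero total
responsibility) takes the global pooled mean rather than producing NaN.

Numerical choices:

* Initialization: μ⁰ = (10th, 50th, 90th) percentiles of the pooled
  tumor+normal values, π⁰ = (0.15, 0.70, 0.15), σ⁰ = pooled SD. One
  deterministic start by default; optional seeded random restarts jitter μ⁰
  and keep the best final log-likelihood.
* Convergence: absolute change in log-likelihood < 1e−6, max 500 iterations.
* σ floor: 1e−3 × range of the pooled values (1e−12 if the range is zero),
  preventing degenerate zero-variance spikes.
* Responsibilities are computed in log space; if all three log-densities
  underflow to −inf for a sample it is assigned to the nearest mean.

## Trimodality, cutoffs, mode assignment

A fit is trimodal when μ₂ − μ₁ > 1e−8, μ₃ − μ₂ > 1e−8 and every π_j > 0.01.
Mode boundaries are the points where adjacent π-weighted component densities
are equal (closed form in the README). When a cutoff escapes its bracketing
means — which happens when σ is large relative to the separation or the π
ratio is extreme — it is replaced by the 10% (low/middle) or 90%
(middle/high) empirical tumor quantile (linear-interpolation quantiles) and
flagged. Samples exactly on a cutoff go to the middle mode, conservative
toward "similar to normal". Empirical mode proportions are counted from
these hard assignments and are the quantities the ≥ 5% mode-size filter uses.

### False-trimodality on unimodal genes

The procedure's specificity limit is worth stating plainly: on pure N(0,1)
genes (no mode structure at all), roughly half of fits end flagged trimodal
— the outer components absorb tail noise, and only trajectories whose means
cross during EM reach the absorbing merged state. Longer runs and the
`paper_literal` weighting leave this rate essentially unchanged; it is a
property of the estimator, not of the stopping rule. The screen therefore
does not rely on the trimodality call for specificity: the four one-sided
association filters carry it (see the planted-signal test, where 200 null
genes produce no false candidates in the large majority of runs). The test
suite pins the measured baseline so regressions are visible.

## Association tests

Survival: Cox proportional-hazards regression of (time, event) on two
indicator contrasts, low-vs-middle and high-vs-middle, optionally plus
covariates, with all times administratively censored at 20 years (events
after the horizon become censored observations at 20). One-sided p-values
come from the Wald z of each contrast, upper tail, so small p means the
outer mode fares *worse* than middle. Covariate p-values are reported
two-sided; categorical covariates are dummy-coded against a declared
reference level ("Basal" by default for PAM50-style subtype columns).
Samples missing a covariate are dropped listwise and the deletion is
flagged; collinear covariates are dropped with a warning. Degenerate fits
(no events, empty middle mode, non-convergence) yield missing p-values with
explicit flags, never silent zeros.

Grade: the Cochran–Armitage trend statistic on the 2×3 table of
(contrast-group membership) × (grade 1/2/3) with integer scores, restricted
to contrast + middle samples. The chi-square is converted to a signed z and
the one-tailed p is the upper-tail probability that higher grades are
enriched for the contrast group; a flat trend gives p = 0.5 and a reversed
trend gives p > 0.5. Grade levels with no samples are dropped (scores keep
their original values). p-values are floored at 1e−300.

Overlap: upper-tail hypergeometric probability of observing at least the
realized intersection of two gene lists inside a declared universe.

## Screen

Per cohort: fit every gene (genes with missing values, or too few samples,
are recorded with a reason); trimodal fits with min empirical mode
proportion ≥ 0.05 proceed to the four association tests; a candidate needs
all four one-sided p < 0.05. Cohorts without normal samples cannot anchor
the middle component, so each gene is rank-split at fixed proportions
carried over from anchored cohorts (supplied proportions are renormalized to
sum to 1 and the adjustment logged; stratum sizes are floor(n·p) for the
outer modes with leftovers to the middle, ties broken by stable input
order). Cross-cohort candidates: `strict` intersects per-cohort candidate
sets; `relaxed` requires candidacy in the discovery cohorts and a consistent
trend (every available p < 0.5) elsewhere.

## Synthetic cohorts

The generator produces what the estimator assumes, so tests measure
estimation and testing error, not model mismatch:

* Expression: planted risk genes follow the three-component mixture with
  defaults matching the reference validation simulation — mode sizes
  100/250/150, means (−4, 0, 3), σ = 1, 50 normal samples from the middle
  component. Null genes are unimodal N(0,1) with no clinical linkage.
* Survival: exponential event times with rate 0.05/year in the middle mode
  and hazard ratio 3 in each outer mode by default; independent exponential
  censoring calibrated to a 20% censored fraction, plus administrative
  censoring at 20 years. Exponential baselines keep the effect sizes
  analytically transparent; the Cox model is agnostic to the baseline shape.
* Grade: a three-level proportional-odds model with baseline probabilities
  (0.25, 0.45, 0.30) and a +1.0 shift of the linear predictor in the outer
  modes — the simplest mechanism producing the monotone trend the test
  targets.
* Each gene draws from an RNG stream keyed by (master seed, gene index), so
  per-gene results do not depend on generation order, and the whole cohort
  is exactly reproducible from (config, seed).

What the generator does **not** emulate: probe-level noise, batch and
platform effects, correlated genes, non-Gaussian within-mode shapes,
informative censoring, covariate-confounded hazards, and copy-number
structure. Passing tests therefore demonstrate correctness of the machinery
under its own assumptions, not performance on real cohorts.

## Problem sizes used in the checked runs

Parameter-recovery runs use 50 replicates of the 550-sample reference
simulation; the acceptance script averages 25 replicates. Null calibration
uses 200 simulated cohorts of 500 tumors. The planted-signal screen uses 20
cohorts of 201 genes (200 null + 1 planted) × 550 samples. These sizes give
stable Monte-Carlo estimates of the quantities asserted while keeping the
suite fast.

## Known limitations

* No multiple-testing correction is applied across genes; the screen reports
  raw p-values and leaves correction to the user (the candidate definition —
  four simultaneous one-sided p < 0.05 plus trimodality and mode-size
  filters — is itself a strong joint requirement, but it is not an FDR
  guarantee).
* The number of components is fixed at three and variances are shared by
  design; no model selection is attempted.
* Whether a published analysis used π-weighted or density-ratio
  responsibilities is not decidable from formulas alone; both are provided
  and neither is asserted as anyone's original code.
* The false-trimodality baseline above means the trimodal flag alone should
  never be read as evidence of real substructure.
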