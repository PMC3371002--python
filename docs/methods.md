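# Methods

## The measurement model

The package analyses accuracy on five-move Tower of London (ToL) problems
arranged in a 2×2 within-subject design crossing **Search Depth** (SD;
how many intermediate moves must be anticipated before the first goal move)
and **Goal Ambiguity** (GA; how completely the goal configuration dictates
the order of the final moves).  Each subject attempts `T` problems per cell
(default `T = 2`, as administered in the study cohort this package was built
around) and the datum per cell is the number solved in the minimum number of
moves.

A multinomial processing tree (MPT) model assigns each cell a success
probability built from three parameters per latent class:

* `b` — baseline success probability (both demands low);
* `g` — multiplicative factor applied when Goal Ambiguity is high
  (the planning literature sometimes labels this parameter *f*; the package
  uses `g` everywhere);
* `s` — multiplicative factor applied when Search Depth is high.

In the canonical cell order `(LL, GA, SD, HH)` the success probabilities are
`(b, bg, bs, bgs)`.  `g = s = 1` means the demands cost nothing; values
below 1 scale performance down; `s = 0` puts the two high-search-depth cells
at floor.  Within a class the four cell counts are independent
`Binomial(T, p_cell)` draws — the model deliberately ignores move-by-move
behaviour, latencies, and trial order; only counts enter the likelihood.

Population heterogeneity is modelled as a finite mixture: `K` latent
classes, each with its own `(b, g, s)`, mixed with weights that sum to one.
The free-parameter count is `P = 3K + (K − 1)`.

## Estimation

`em_fit` maximises the observed-data likelihood by EM:

* **E-step** — posterior class probabilities by Bayes' rule, in log space.
* **M-step** — mixing weights update to posterior column means; the class
  parameters maximise the posterior-weighted binomial log-likelihood over
  the box `[1e-8, 1 − 1e-8]³` using L-BFGS-B with analytic gradients,
  warm-started at the current parameters and guarded never to return a
  worse objective, so each EM iteration cannot decrease the log-likelihood
  (a generalised EM step).  When a parameter is restricted to be equal
  across classes the M-step optimises all classes jointly with the shared
  coordinate tied.
* **Aggregation** — subjects with identical count 4-vectors are pooled into
  unique response patterns (at most `(T+1)⁴ = 81` for `T = 2`).  This is an
  exact rewrite of the likelihood, not an approximation, and is what makes
  cohorts of several thousand subjects cheap to fit.
* **Multi-start** — `n_starts` initialisations (parameters ~ Uniform(.1, .9),
  weights ~ symmetric Dirichlet(1)), each run for a 40-iteration burn-in;
  the best continues to convergence (`|Δ loglik| < tol`, default
  `tol = 1e-8`, `max_iter = 2000`).  A single integer seed drives all starts
  through a spawned seed sequence, so fits are bit-reproducible.
* **Canonicalisation** — classes are reported in descending `s` (ties:
  descending weight), so class 0 is always the class that copes best with
  high search depth.  Estimates within `1e-3` of the box boundary are
  reported as exactly 0 or 1, matching how floor-level performance is
  conventionally printed; the reported log-likelihood is that of the
  unsnapped maximiser, and posteriors are computed from it.

Equality restrictions are compared by the likelihood-ratio statistic
`Δl = 2(l_full − l_restricted)` with `df` equal to the number of active
restrictions (`K − 1` per restricted parameter) against a central
chi-square.  When an estimate sits on the boundary (`s = 0`) this reference
distribution is an approximation — the standard caveat for boundary
parameters — and is used knowingly, as is conventional for this analysis.

## Goodness of fit

Two moment-based statistics judge a fitted mixture; both are exactly
computable because the outcome support is finite (81 outcomes at `T = 2`),
and both are zero when the observed moments equal the fitted ones.

**Mean structure (M3).**  A Pearson chi-square on the pooled
correct/incorrect counts per cell against their model-implied expectations,
`df = 4 − P`.  With one class (`P = 3`) one degree of freedom remains; any
`K ≥ 2` saturates the mean structure and the statistic is reported without
df or p-value.

**Covariance structure (S1).**  Let `S` be the sample covariance of the
per-subject count 4-vectors (divisor `N`, matching the asymptotic scaling)
and `Σ̂` the model-implied covariance; `d = vech(S − Σ̂)` collects the 10
distinct entries.  The statistic is the residual-based quadratic form

    S1 = dᵀ [W − W D (Dᵀ W D)⁺ Dᵀ W] d ,

where `W` is the pseudo-inverse of the asymptotic covariance of `vech(S)` —
entries `(μ_cdef − σ_cd σ_ef)/N` with the central fourth moments `μ_cdef`
computed exactly by enumerating the outcome support under the fitted model —
and `D = ∂vech(Σ)/∂θ` is the Jacobian in the free parameters (central
differences, one-sided at the box edge).  Projecting out the model tangent
space makes the statistic asymptotically chi-square with `df = 10 − P` for
any √N-consistent estimator of θ.  A plainer form that weights by `W` alone
and handles estimation error through the df reduction only was tried first
and over-rejected in null simulations (rejection rate ≈ .13–.18 at a nominal
.05), because `d` carries the sampling noise of θ̂ on top of that of `S`;
the projected form restores nominal calibration while keeping the same df
bookkeeping — 7 at one class, 3 at two classes.  Singular values below
`1e-10` of the largest are discarded from the pseudo-inverses; any rank
deficiency of `W` reduces the df further and is recorded as a warning.
Note one degenerate corner: for Bernoulli cells at `p = .5` the sample
variance has zero sampling variance, so `W` is legitimately rank-deficient
there.

The sample-covariance divisor is `N`, not `N − 1`, to match the asymptotic
weight; at the study's `N = 60` the distinction is immaterial relative to
the chi-square approximation itself.

**Critical values and power.**  `chi2_critical` is the central chi-square
upper-alpha quantile (reports display two decimals: 6.63, 11.34, 18.48 for
df 1, 3, 7 at α = .01).  `detectable_effect` solves for the noncentrality λ
at which the noncentral chi-square first attains power `1 − β` past that
critical value — a bracketed Brent root find to `1e-8`, which agrees with
Monte-Carlo simulation of `(Z + √λ)²` to three decimals — and converts to
Cohen's `w = √(λ/n)`, classified against the conventional anchors
(small .1, medium .3, large .5).  The number of observations `n` is an
explicit argument (the study's natural choice is 480 = 60 subjects × 8
problems), since the convention is not uniquely determined by the design.

## Synthetic cohorts

`simulate` draws exactly from the generative model: class ~
Categorical(weights), counts ~ Binomial(T, p_class,cell), then optionally a
group label and a Gaussian screening covariate.  `study_scenario` fixes the
study conditions: `N = 60`, `T = 2`, classes mixing .73/.27 with parameters
(.76, .82, .78) and (.71, .78, 0).  The .73/.27 weights are the published
class split; the same source reports 44/16 subjects assigned by posterior
mode, which coincides to rounding — the generator treats .73/.27 as the
mixing weight, and the assignment share is an output, not an input.  Group
labels are drawn per-subject at the configured fractions ({PD: .5,
control: .5}), independent of class unless the `group_class_log_odds` knob
tilts the log-odds of the first label for members of the last (lowest-`s`)
class; the cohort therefore has a binomially varying, not exactly equal,
group split.  The screening covariate is a deliberately simple Gaussian
shift model (default −1 standard unit for the floor class) — enough to
exercise class–covariate association analyses, with the shift size
user-set because no effect size is established for it.

What the generator does **not** emulate: move sequences and latencies,
item-level difficulty variation within a cell, practice or fatigue effects,
and any non-binomial overdispersion within subject and cell.  Tests passing
on these cohorts therefore validate the estimation and testing machinery
under the model's own assumptions; they cannot certify those assumptions
for real task data.

## Pipeline and conventions

`run_pipeline` fits `K = 1..max_K`, computes both fit statistics per K,
selects the smallest K whose covariance-structure p-value exceeds
`alpha_fit` (default .01, the critical-value convention used throughout; if
no testable K qualifies the largest K is kept and flagged), runs the three
single-parameter equality-restriction tests at the selected K, assigns
subjects by posterior mode (ties to the lower class index, i.e. the
higher-`s` class), and cross-tabulates assignment against the group label.
The 2×2 Pearson chi-square applies **no** continuity correction — required
to reproduce the .341 value of the published 7/23 vs 9/21 split — and the
Fisher test is two-sided by the probability-mass convention.  Repeated-
measures ANOVAs on accuracy or clinical scores are intentionally out of
scope; the report's tidy per-subject table (class, group, covariates) is
the hand-off point to any standard ANOVA tool.

Problem sizes used by the shipped checks were chosen to make each claim
statistically meaningful at interactive cost: parameter recovery uses 100
replicates of `N = 5000` (mean bias per parameter < .02), null calibration
uses 500 replicates (`N = 200` for the mean structure, `N = 500` for the
covariance structure), and the study-size replication uses 100 replicates
at `N = 60`.

## Known limitations

* LR tests with a boundary estimate (`s = 0`) use the standard chi-square
  reference; a mixture-of-chi-squares reference would be more accurate.
* No standard errors or confidence intervals for the parameter estimates
  (Fisher information or bootstrap would both fit naturally on top).
* The covariance-structure statistic is asymptotic; at `N = 60` its
  calibration is approximate even with the projection, which is why class
  selection is treated as a decision rule rather than a strict test.
* Class-number selection considers `K` up to `max_K` only, and `K = 3`
  already saturates the 10 covariance moments (`P = 11`), leaving the
  covariance structure untestable for the default design.
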