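# tolmpt — latent-class MPT analysis of Tower of London planning

Planning impairments in neurodegenerative disease are usually studied by
comparing manifest groups (e.g. Parkinson's disease patients vs. healthy
controls) on overall Tower of London (ToL) accuracy.  That approach assumes
every subject in a group copes with the task's demands in the same way.
`tolmpt` implements the opposite, data-driven logic: model each subject's
accuracy with a cognitive measurement model, let a finite mixture discover
latent classes of subjects who cope differently, and only then ask whether
class membership lines up with diagnosis or clinical covariates.

The measurement model is a multinomial processing tree (MPT) over a 2×2
within-subject design crossing **Search Depth** (SD) and **Goal Ambiguity**
(GA), with `T` problems per cell and three parameters per latent class:

```
P(correct | cell) = b · g^[GA high] · s^[SD high]
```

— `b` the baseline success probability, `g` and `s` the multiplicative
costs of high goal ambiguity and high search depth (`g` is called *f* in
parts of the planning literature).  A `K`-class model mixes `K` such
triples with weights summing to one (`P = 3K + K − 1` free parameters) and
is fitted by maximum likelihood (EM with multi-start).  Model adequacy is
judged by two asymptotically chi-square moment statistics — `M3` for the
mean structure (df `= 4 − P`) and `S1` for the covariance structure of the
per-subject count vectors (df `= 10 − P`) — and parameter differences
between classes are probed with equality-restriction likelihood-ratio
tests, `Δl(df = K−1)`.  Subjects are assigned to the class with the highest
posterior probability, and the assignment is cross-tabulated against
manifest labels with Pearson (no continuity correction) and Fisher tests.
A power module gives chi-square critical values and the smallest detectable
Cohen's `w` at chosen α and β.

Because the original cohort data are not publicly deposited, the package
ships a synthetic-cohort generator whose default preset reproduces the
study conditions: 60 subjects, 2 problems per cell, two latent classes
mixing .73/.27 with parameters (.76, .82, .78) — moderate search-depth
cost — and (.71, .78, 0) — floor performance under high search depth.

## Worked example

The numbered scripts under `analysis/` run the full study sequence on a
simulated cohort; each writes its table under `results/`:

```
$ python analysis/01_simulate_cohort.py
simulated N=60 subjects (seed 11)
  true class split: 48 SD+ / 12 SD-
  ...
$ python analysis/02_fit_latent_classes.py
K=1 class 0: weight=1.00 b=0.77 g=0.71 s=0.63
  loglik=-237.35  M3=0.092 (df=1)  S1=24.45 (df=7, p=0.0009)
  covariance structure rejected at alpha=.01 (critical 18.48)
K=2 class 0: weight=0.78 b=0.72 g=0.78 s=0.81
K=2 class 1: weight=0.22 b=1.00 g=0.40 s=0.06
  loglik=-228.11  M3=saturated  S1=1.61 (df=3, p=0.6563)
  covariance structure acceptable at alpha=.01 (critical 11.34)
$ python analysis/03_restriction_tests.py
equality of b: delta_l(df=1) = 2.66, p = 0.1028 -> no significant loss
equality of g: delta_l(df=1) = 4.47, p = 0.0346 -> no significant loss
equality of s: delta_l(df=1) = 17.39, p = 0.0000 -> significant loss
```

Read: the one-class model reproduces the aggregate cell means (`M3` tiny)
but fails the covariance structure (`S1 = 24.45 > 18.48`), i.e. subjects
are too heterogeneous for a single parameter set.  Two classes fit
(`S1 = 1.61 < 11.34`), and the equality-restriction tests show the classes
differ specifically in the search-depth parameter `s` — not in baseline `b`
or goal-ambiguity `g`.  `04_class_group_association.py` then shows class
membership is statistically independent of the PD/control label, and
`05_power_analysis.py` prints the critical values (6.63, 11.34, 18.48 for
df 1, 3, 7 at α = .01) and detectable effect sizes (`w ≈ .22–.28`,
small-to-medium).

The same machinery is available programmatically
(`tolmpt.em_fit`, `tolmpt.run_pipeline`, ...) and through a thin CLI:

```
tolmpt simulate --n 60 --seed 9 --out cohort.csv
tolmpt report --data cohort.csv --max-k 2 --seed 2 --out report.json
tolmpt power --df 1 --n-observations 480
```

## Layout

```
src/tolmpt/        model.py (MPT model + exact moments), estimation.py (EM,
                   LR tests, posteriors), fitstats.py (M3, S1, power),
                   simulate.py (synthetic cohorts), io.py (CSV schema),
                   contingency.py (2x2 tests), pipeline.py, cli.py
analysis/          numbered narrative drivers (simulate, fit, restrict,
                   associate, power)
tests/             pytest suite (unit, property, and end-to-end checks)
docs/methods.md    modelling and numerical choices in detail
```
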