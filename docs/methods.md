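# Methods

## State-space model

Each patient-day is a point in an encoded, standardized clinical feature
space. Recovery is modeled as movement toward a reference distribution R:
the set of state vectors whose SOFA total equals 1, pooled over arms and
days of the analysis set (patients held out for generalizability checks
are excluded). SOFA = 0 states are typically too rare to define a
distribution, which is why the reference sits at 1.

The distance from state A to R is the Mahalanobis distance
`D(A,R) = sqrt((A−μ) Σ_reg⁻¹ (A−μ)ᵀ)` with μ, Σ the member mean and
covariance and `Σ_reg = Σ + λI`. The ridge is needed because the number of
reference members is usually of the same order as the feature count, so Σ
is ill-conditioned or singular; `λ = 1e-6 · trace(Σ)/dim` by default
(configurable, including `0` for well-conditioned cases). All distances —
member pairs included — use the same regularized inverse, so the
normalization below stays internally consistent.

Daily aggregates per arm: the patient count P(t), the cumulative distance
sum CumSum(t), and the per-patient mean CumSum(t)/P(t). Every statistic is
also reported normalized by c, the mean pairwise Mahalanobis distance
among reference members; the members' own normalized mean pairwise
distance is exactly 1 by construction. Because arm sizes differ and shrink
over time as patients exit, the raw sum conflates recovery with attrition;
the per-patient normalized mean is therefore the headline trajectory and
both are emitted. The pairwise metric for c is Mahalanobis under the
reference covariance (not plain Euclidean) so numerator and denominator
share units.

Day-1 exchangeability is checked separately: each day-1 patient's mean
Euclidean distance to all other patients (in the scaled space), compared
between arms with a 1,000-draw label-permutation test on the difference of
arm means, plus seeded 2-D embeddings (deterministic PCA with a fixed sign
convention; t-SNE delegated to scikit-learn).

## Encoding

Discrete features are target-encoded against the SOFA total — the only
supervised signal the pipeline uses — with the smoothed category mean
`(Σ targets + s·prior)/(n + s)`, smoothing weight `s = 1` by default;
unseen categories map to the global prior. Pathogen flags are encoded
identically when the distance-based path is selected (they are already
numeric 0/1 otherwise). All features are then standard-scaled.
Zero-variance columns are scaled by 1 so transforms stay finite. Both
steps fit on training rows only; transforming held-out rows never touches
their statistics (asserted exactly in tests). Ordered/permutation-aware
encoding variants are out of scope: the encodings feed distance
computations, not gradient boosting.

## Feature selection

A genetic algorithm evolves fixed-cardinality feature subsets; the fitness
of a subset is the grouped cross-validated negative mean absolute error of
an estimator predicting the SOFA total (5 folds; folds split by patient so
within-patient autocorrelation cannot leak). Estimators: an
information-based random forest on raw features, or a distance-based
linear model on encoded + scaled features. The linear path evaluates CV
fitness with a direct least-squares solver and memoizes scores per subset
(verified in tests against an independent scikit-learn CV loop); the GA
routinely revisits subsets, so this dominates wall-time.

Operators (fixed-cardinality preserving): tournament selection of size 3,
crossover that keeps the parents' intersection and fills up to k from
their symmetric difference, single-swap mutation with probability 0.1 per
individual, and one elite per generation — which also makes the
best-so-far fitness trace provably non-decreasing. Full-scale defaults are
a population of 160 for 100 generations, 100 repetitions, 5-fold fitness
CV; tests and the default `RunConfig` use reduced sizes (population 40, 25
generations, 20 repetitions) that preserve every structural property.

Protocol: 10 patients held out entirely; the rest split 4:1 by patient
(re-drawn per repetition with derived seeds, since repetitions are meant to
average over split randomness); subset size k swept over its range and
scored by repeated grouped k-fold (10 splits × 3 repeats = 30 fold
scores); per-feature pick frequencies across repetitions thresholded at
10 %, and a final GA over the thresholded pool yields the chosen set. An
empty pool falls back, loudly logged, to the top-k features by frequency.
Four scenarios combine estimator family × whole-universe vs. independent
per-kind (continuous / discrete / pathogen) searches; the per-kind path
cannot select cross-group interactions by construction.

## Outcome statistics

- **KS statistic**: two-sample sup-difference of empirical CDFs of
  per-patient exit days (delegated to `scipy.stats.ks_2samp`, cross-checked
  against a brute-force step-CDF oracle). Per-patient exit days — not the
  cumulative count curves — are the compared samples, being the standard
  statistical object.
- **Hellinger distance**: `sqrt(0.5 Σ (√f_i − √g_i)²)` on probability
  masses over integer-day bins spanning the union support. This is the
  standard Hellinger form, whose [0, 1] bounds the implementation attains
  exactly on identical / disjoint densities and which matches the Gaussian
  closed form `sqrt(1 − exp(−1/8))` on a fine grid.
- **ANOVA**: last recorded SOFA of patients leaving alive before a cutoff
  day (default 11) regressed on arm and exit day by OLS; Type-2
  (marginal) sums of squares are the named decomposition, Type-1
  (sequential) is exposed as an option. Time enters as a continuous
  single-degree covariate by default, with a categorical-day option.

## Synthetic cohort generator

The generator defines the study conditions for every test: two arms
(defaults 123 TDM / 125 control, up to 10 daily state vectors each, ~1,800
state vectors per cohort — the same order as a mid-size TDM trial). Each
patient carries six latent organ-dysfunction levels drawn i.i.d. from
Gamma(3, 0.55) at day 1 — identically for both arms, so arms are
exchangeable at randomization; day-1 severity totals land near 7 ± 2,
typical of septic ICU admissions. Levels decay exponentially at the
control recovery rate (0.08/day) until the effect onset day (2), then at
the arm's own rate (default TDM 0.12/day; equality encodes the null).

Observed features: informative continuous features are noisy linear
mixtures of the latent vector, each loading mainly (weight ≈ 0.85 after
normalization) on one primary organ — as clinical markers do — plus
Gaussian noise (sd 0.3); non-informative features are pure noise.
Informative discrete features threshold a noisy latent mixture into
ordinal codes; the rest are uniform codes. Pathogen flags are Bernoulli at
baseline with shared per-pathogen prevalence across arms, constant over
the stay. Organ subscores are equal-width unit bins of the latent level
clamped to 0..4 (the clinical SOFA cut-points are deliberately not
modeled); the total is their sum. Exits: death with per-day hazard
`1 − exp(−h · Σ latent)` (default h = 0.004, ~25 % ten-day mortality),
discharge alive once the total falls to the threshold (default 1).
Day 1 is the first day after randomization.

What the generator does **not** emulate: real lab-unit systems and
clinically calibrated SOFA thresholds, informative missingness,
measurement batch effects, within-day dynamics, or correlated pathogen
ecology. Passing tests therefore demonstrate that the pipeline recovers
known truths under its stated assumptions, not that those assumptions hold
in trial data.

Two simulation-protocol details matter for the effect-recovery checks:
exits must follow the study's discharge rule (leave at SOFA ≤ 1) — without
it, fully recovered patients linger below the healthy region, their
distance grows again, and the arm curves cross late for reasons no real
trial would exhibit; and per-day arm comparisons are only meaningful while
both arms retain a minimal aggregate (≥ 5 patients), since a late-day
"curve" of two stragglers is an individual trajectory, not an arm mean.

## Numerical and design choices

- Covariance inversion via Cholesky of `Σ + λI`; distances through
  triangular solves (no explicit inverse in the hot path).
- PCA sign fixed by making each component's largest-magnitude loading
  positive.
- Median of an even count: mean of the two middle values; mode ties in
  imputation break lexicographically (deterministic, seed-free).
- Missing-fraction thresholds: drop a column above 0.5 missing, impute
  below 0.05; both configurable.
- Repeated grouped k-fold (patients shuffled per repeat, then split) fills
  the role of plain repeated k-fold while preserving the
  no-patient-straddling guarantee.
- Stage seeds are SHA-256 digests of `(master seed, stage name)` reduced
  below 2³¹ — reproducible, collision-free across stages.
- Permutation p-values use the add-one estimator `(b + 1)/(m + 1)`.

## Known limitations

- The reference is a population proxy for health; individualized healthy
  baselines are out of scope.
- The generator's linear latent-to-feature map makes the planted-recovery
  problems easier than heterogeneous trial data; forest-vs-linear
  estimator comparisons on it should not be over-interpreted.
- Full-scale GA settings (160 × 100 × 100 repetitions over ~199 features)
  are computationally heavy by design; the package exposes them but the
  shipped configurations run at reduced scale.
- Real-trial headline values (its KS, Hellinger and ANOVA numbers) require
  the request-only dataset and are intentionally not reproduced here.
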