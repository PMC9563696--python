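# Methods

## Match play and the feature-learning ledger

A match pairs two disjoint feature teams of equal size *t*, drawn uniformly
without replacement from the candidate universe. Each of *r* rounds draws a
fresh random 50:50 split of the rows (stratified on the outcome for binary
data and on the event indicator for survival data, so both halves retain
both outcome levels); both teams' models are fitted on the same training
half and evaluated on the same validation half, making each round a paired
comparison. Win accounting:

- better metric per the adapter's direction → 1 win;
- exactly tied metrics → 0.5 wins each (the likelihood accepts fractional
  counts, so no information is discarded);
- one fit fails (`FIT_FAILURE` or a non-finite metric) → the other team
  wins: producing a usable model is itself part of being the better model;
- both fits fail → the round is discarded entirely, since it carries no
  information about relative strength.

Rows with missing values in either team's features are dropped per match
(complete cases within the union of the two teams), which keeps matches
independent and adapters simple; no imputation is attempted.

Match generation stops when every feature has appeared in at least *k*
matches (appearances, not rounds: one match is one independent comparison
context) or when the match cap is reached. Defaults t=10, r=30, k=5,
max_matches=1000 reflect the regime where the ranking is most stable for
tabular clinical data of a few hundred rows and tens of candidate features;
all are overridable.

## The ranking model

The ledger is modeled by the team-generalized Bradley–Terry likelihood: the
probability that the plus-team wins a round is a logistic function of the
difference of team strength sums. Implementation details:

- **Identifiability.** The likelihood is invariant to adding a constant to
  all scores; we report the sum-zero representative, which makes scores
  interpretable as deviations from an average feature.
- **Ridge.** A feature that wins every match it plays has an infinite MLE
  (the paired-comparison analogue of separation). A default ridge of 1e-4 on
  ‖v‖² keeps the optimum finite with negligible bias elsewhere; `ridge=0` is
  available and raises a targeted error when the observed information is
  singular at the optimum.
- **Optimization.** The penalized negative log-likelihood is convex. We run
  L-BFGS with the analytic gradient, then polish with projected Newton steps
  (analytic Hessian, backtracking line search) until the sum-zero-projected
  gradient norm falls below 1e-8. Softplus/log-sum-exp forms keep the
  computation stable for score sums up to about ±700.
- **Uncertainty.** Standard errors come from the observed information at the
  optimum, projected onto the sum-zero subspace (pseudo-inverse of PHP with
  P the centering projector). Wald intervals use the normal quantile at the
  requested level. For a feature set S, the strength g(v) = Σ_{j∈S} v_j is
  linear, so the delta method is first-order exact: se² = 1_Sᵀ Cov 1_S.
- **Selection.** `select_top` takes the m highest scores, breaking ties by
  smaller standard error and then feature name, so results are reproducible
  bit-for-bit.

Features that never entered a match carry no information; they are excluded
from the fit and flagged rather than silently assigned a score.

## Wrapper baselines

Forward, backward, bidirectional and random search all evaluate candidates
through the same adapter on one fixed train/validation split (optional
re-splitting per step is deliberately off by default: a single split keeps
the baselines directly comparable to each other and cheap). Greedy ties
break lexicographically. Bidirectional search compares the best add (below
the target size) with the best drop (above one feature), accepts the better
move only if it strictly improves the current metric, memoizes visited sets
to prevent cycling, and stops after 10·p moves at the latest. Random search
enumerates all C(p, m) subsets outright whenever the candidate budget covers
them, making the "exhaustive" case deterministic.

## Adapters and calibration

- **Continuous outcomes:** ordinary least squares, evaluated by validation
  mean squared error. Constant columns are dropped with a log message; a
  design that is still rank-deficient returns `FIT_FAILURE`.
- **Binary outcomes:** logistic regression with a weak L2 ridge (C = 1e4).
  The ridge means separated training data still yields a finite model that
  scores AUROC 1.0 on a separable validation half, rather than aborting the
  search; `FIT_FAILURE` is reserved for single-class training halves and
  solver failure. Metrics: AUROC (maximize), ICI (minimize), or a composite
  AUROC − ICI (maximize) as a concrete arbitration between discrimination
  and calibration.
- **Survival outcomes:** Cox proportional hazards (lifelines, penalizer
  1e-4). Discrimination by Harrell's concordance on the validation half;
  calibration by the ICI of the predicted event probability at a fixed
  horizon τ (default: median observed training time; a τ beyond the last
  observed time is rejected) against the smoothed observed status among
  subjects whose status at τ is known. Subjects censored before τ are
  excluded from that comparison — a pragmatic estimator that is slightly
  optimistic under heavy censoring.

Calibration curves regress the 0/1 outcome on the predicted probability
with a lowess smoother (span 0.75, zero robustness iterations), evaluated
at each predicted value and clipped to [0, 1]; near-constant predictions
degenerate to the event rate. The indices are ICI = mean |d|, E50/E90 = the
50th/90th percentiles of |d| under the linear-interpolation quantile
convention, and Emax = max |d|. Resampled estimation supports hold-out,
k-fold cross-validation (k = n is exact leave-one-out) and out-of-bag
bootstrap, returning mean and standard deviation.

## Variable construction

`screen_transformations` scores identity, sqrt, cbrt and log by the
Shapiro–Wilk W statistic (subsampling above n = 5000, where the statistic is
undefined) and recommends the argmax. sqrt requires x ≥ 0 and log x > 0; an
optional shift x − min(x) + 1e-6·range makes them applicable to
negative-domain variables, otherwise they are marked inapplicable. A
Box-Cox candidate at its normality-maximizing exponent is available but
opt-in: a continuous family tuned on the same statistic nearly always edges
out the fixed transforms by a hair, which would make the recommendation
useless for choosing among the interpretable ones.

`boxcox_fit` instead chooses the exponent *for the outcome model*: it
maximizes the profile likelihood of y on boxcox(x, λ) — least squares for
continuous y, logistic for binary — over a λ grid on [−3, 3] with bounded
golden-section refinement around the grid optimum.

### Mixture modeling and cut points

Component counts 1..K (default 3) are fitted by EM and compared by AIC.
Two numerical choices matter and were made deliberately:

- **Initialization.** The Gaussian-mixture likelihood with free variances
  is unbounded, so "find the highest likelihood over many restarts" is the
  wrong target: aggressive multistart locates spurious near-degenerate
  optima whose AIC beats the true order. Each component count is therefore
  fitted by a single EM run initialized with means at the (j+½)/k sample
  quantiles, equal weights and equal variances Var(x) — a well-dispersed
  deterministic start that converges to the consistent root, in the spirit
  of hierarchical-clustering initializations used by mature mixture
  software.
- **Degeneracy floor.** Component variances are floored at 1% of Var(x). A
  component narrower than that is a likelihood spike around a handful of
  points, not a subpopulation worth a category of its own. The floor
  slightly inflates genuinely narrow components (variance below 1% of the
  marginal), which matters little for cut-point placement between
  well-separated modes but is a known limitation for extreme
  separation-to-width ratios.

Cut points between adjacent-by-mean components solve the equal-posterior
condition w_a N(c; μ_a, σ_a) = w_b N(c; μ_b, σ_b) on (μ_a, μ_b) by Brent's
method, falling back to the means' midpoint when no crossing exists in the
interval (possible with very unequal weights/variances). Unequal weights
shift the boundary toward the lighter component, as they should.
`categorize` assigns right-closed intervals "(lo, hi]" — a value exactly at
a cut point falls in the lower level — and leaves missing values missing.

## Influence diagnostics

Influence is metric-based rather than coefficient-based because the
framework is model-agnostic: score(i) = metric(fit without training row i) −
metric(full fit), evaluated on the fixed validation half. Exact
leave-one-out is used up to 2000 training rows; above that a 50-group
jackknife shares each group's score among its members. Rows are flagged when
|score − median| exceeds 3 scaled MADs (consistency factor 1.4826). Failed
leave-one-out fits record a missing score and never abort the report.

## Synthetic data

The generator emulates the structure of clinical tabular data: independent
standard-normal features, a handful of informative ones with stated
linear-predictor coefficients, optional lognormal (standardized) skew for
informative features, and three outcome families — Gaussian regression,
Bernoulli-logistic binary, and Weibull proportional-hazards survival with
independent Uniform(0, c) censoring whose horizon c is calibrated by root
finding so the realized censoring fraction matches the request. What it does
*not* emulate: correlated features, measurement error, informative
censoring, missingness patterns, or site/batch structure. Passing tests on
these fixtures therefore demonstrate correctness of the algorithms under
clean identifiable conditions, not robustness to the full messiness of real
clinical data.

Default benchmark conditions used by the test suite and the acceptance
script: 5 informative features with coefficients 1.0 among 45 noise
features, n = 500, binary outcome; ledgers for oracle checks use 4–6
single-feature teams; calibration checks use n = 2000; Box-Cox and mixture
checks use n = 1000. These sizes make every check run comfortably on one
CPU while keeping Monte-Carlo error well inside the asserted margins.

## Known limitations

- The ranking's standard errors treat matches as independent Bernoulli
  aggregates; rounds within a match share the same team pairing, so the
  effective information per match is slightly overstated when round
  outcomes are strongly correlated across splits.
- With far fewer matches than features (m < p), the ridge pins
  unidentified score directions near zero; the ranking among barely-covered
  features is then driven by the few matches they appeared in, which the
  (wide) confidence intervals do reflect.
- Survival calibration at a fixed horizon ignores subjects censored before
  the horizon instead of reweighting them (no inverse-probability-of-
  censoring correction).
- The bidirectional search is a validation-metric stepwise procedure, not
  an information-criterion one; with noisy metrics it can stop early at a
  local optimum, which the move-budget and memoization make explicit rather
  than hide.
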