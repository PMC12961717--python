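# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and what the test suite does and does not
establish.

## The prediction problem

Risk adjustment pays insurers a prospective amount per enrollee based on
predicted one-year medical cost, so plans are compensated for sicker
members and have less incentive to select healthy ones. The inputs are
deliberately restricted to the three elements used by the CMS
Hierarchical Condition Category (HCC) model — age, sex, and the set of
diagnosis codes recorded in the base year — and the target is total cost
in the following year. Costs are heavily right-skewed, so the regression
target is log(cost + c); working on the log scale both stabilizes the fit
and connects directly to the actuarial dispersion theory below.

## Franklin: embeddings, clusters, boosted trees

**Co-occurrence.** A beneficiary's diagnosis profile is an unordered,
deduplicated code set for the year; every unordered pair of distinct
in-vocabulary codes in a profile increments a symmetric count matrix.
There is no windowing or sequence structure — the data model has none.
The vocabulary keeps codes appearing in at least `min_count` profiles
(default 5); rarer codes produce degenerate embeddings and are treated as
out-of-vocabulary everywhere downstream.

**Embeddings.** The count matrix is transformed to positive pointwise
mutual information, PPMI(i,j) = max(0, log [ c_ij · S / (r_i r_j) ]), and
factored by rank-d truncated SVD (default d = 50, randomized SVD with a
fixed seed). A code's embedding is the sum of its "word" and "context"
factor rows, (u_i + v_i) · s^α with α = 0.5. The sum matters: for a
symmetric matrix, u-only embeddings capture only second-order similarity
(shared neighbors), and two codes that co-occur exclusively with each
other would come out orthogonal. Adding the context row cancels the
negative-eigenvalue directions and makes directly co-occurring codes
similar, which is the behavior a clinical co-occurrence embedding should
have. PPMI+SVD was chosen over a skip-gram-style objective because it is
exactly reproducible and operates natively on the co-occurrence counts;
the contract (codes in, vectors out) leaves room for alternatives.

**Clusters.** Spherical k-means — k-means on length-normalized embeddings
(default k = 250, 10 restarts, best inertia kept, seeded). Similarity is
cosine throughout, which bounds features in [−1, 1] and matches the
geometric interpretation of the embedding space. When the vocabulary is
smaller than k (as in small synthetic demos), k is clipped with a warning.

**Features and regression.** Feature j of a beneficiary is the maximum
cosine similarity between any of their code embeddings and cluster center
j; profiles with no in-vocabulary codes get the zero vector, so they are
scored on demographics alone. (age, female, k features) feed an XGBoost
regressor on log(cost + c) with squared-error loss and early stopping on
the validation split. Defaults: 500 trees, depth 6, learning rate 0.05,
80% row subsampling, patience 20 — conventional values, all overridable;
single-threaded `hist` growth keeps runs bit-reproducible.

**Cohort roles.** The cohort is split 20/40/20/20 into embeddings /
training / validation / test by a seeded permutation cut into
largest-remainder blocks (realized counts within ±1 of exact proportions).
Embeddings are fit on the first split, trees on the second, early
stopping and all calibrations on the third, and every reported metric
comes from the fourth.

**Retransformation and calibration.** Dollar predictions are
exp(log-pred) − c floored at $1, then scaled within each of 10
predicted-risk deciles by factor_d = mean(observed)/mean(predicted) fitted
on the calibration (validation) split. Decile calibration is also the
retransformation-bias correction: a parametric smearing estimator would
correct the mean globally, but the decile factors absorb the same bias
locally while directly enforcing the PR = 1 per-decile payment target.
Decile membership for new predictions uses the fitted deciles' value
boundaries; ties within the fitting set break by stable input order.

## The HCC-style baseline

The baseline reproduces the structure of HCC scoring: a partial ICD→
category map, transitive suppression along a severity hierarchy (an
acyclic dominant→subordinate edge set; only the most dominant present
category in a chain survives), non-negative category weights, a
demographic (age-band × sex) cell weight, optional category-pair
interaction weights, and predicted cost = score × base cost ($12,963 per
unit by default). Scores are normalized so the cohort mean is 1. The
actual production category/weight tables are proprietary; the package
ships a 10-category toy map and can derive a map from the synthetic
generator's ground truth covering any subset of conditions (weights
floored at zero, since the design constrains category weights to be
non-negative — cost-lowering conditions are exactly what the baseline
cannot express).

For log-scale fit comparisons the baseline's dollar predictions are
recalibrated by OLS of log(obs + c) on log(pred + c), fitted on the
validation split and applied out-of-sample: a monotone, rank-preserving
two-parameter map. Its dollar payments go through the same decile
calibration as Franklin's.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline relies on,
with defaults chosen to resemble an aged Medicare population:

* **Demographics.** Ages 65 + ⌊Gamma⌋ (mean ≈ 74.9, SD ≈ 7.2, capped at
  110); 55.9% female.
* **Latent conditions.** K = 10 conditions with geometrically declining
  prevalences (25% down to 3%) and additive log-cost effects from +1.2
  down to −0.4 — the negative tail exists so a flexible model can exploit
  cost-lowering diagnoses, which non-negative linear weights cannot.
* **Costs.** log cost = 8.0 + 0.02·(age − 65) − 0.08·female + Σ condition
  effects + N(0, 0.9²). The implied marginal log-cost SD is ≈ 1.2 and the
  cost distribution is right-skewed log-normal, with median ≈ $7,000 and
  mean ≈ $16,000 at the defaults. Costs are strictly positive by
  construction; a `zero_cost_fraction` switch zeroes a stated share to
  exercise the log-offset policy.
* **Codes.** Each condition owns 12 of 300 ICD-10-like codes (letter +
  two digits + optional subcode) and emits each with probability 0.8 when
  present; a Poisson(1) number of uniformly random noise codes is added;
  5% of beneficiaries have their diagnosis set erased entirely, mirroring
  the large real-world stratum with no baseline-mapped codes.

The generator returns ground truth (condition indicators, code→condition
map, true expected log cost), which the recovery tests use as an oracle.

What the generator does **not** emulate: longitudinal claims, utilization
events, mortality, code ontology structure, payer-driven coding behavior,
and the empirical fine structure of real cost distributions beyond
log-normality. Passing tests therefore demonstrate that the pipeline
recovers planted structure and satisfies its accounting identities — not
that any particular accuracy level transfers to real claims.

## Dispersion decomposition and its Monte-Carlo check

For log-normal costs with log-scale SD σ, the variability of a plan's
predictive ratio splits into a structural factor exp(σ²/2) — set by cost
outliers, untouchable by any risk model — and a residual factor
exp((1−R²_log)σ²) − 1 that better prediction shrinks. The package checks
the decomposition by simulation: costs exp(L), L ~ N(0, σ²) with σ = 1.2,
and for each target R² a log-scale predictor P = L + ε with
Var(ε) = (1−R²)σ², payments exp(P) scaled to cohort PR = 1. Under this
truth-plus-noise construction the delta-method variance of a plan's PR is
(1/n) · exp(σ²) · [exp((1−R²)σ²) − 1], i.e. structural² × residual, so
the *ratio* of PR variances between two predictors equals the ratio of
their residual factors exactly. (The alternative conditional-mean
construction P = E[L | signal] yields an R²-dependent constant instead
and does not satisfy the ratio identity — the construction is part of the
model, and this is the one under which the decomposition is exact.) The
two predictors share the latent costs and the standard-normal noise
(scaled per model), so the variance-ratio estimate is paired and its
Monte-Carlo error at 2000 plans of 1000 members stays within a few
percent.

## Selection simulation

Enrollment probability is expit(logit(baseline) + τ·(rank_pred −
rank_actual)) with percentile ranks normalized to (0, 1) via
(rank − 0.5)/n, so the midpoint of the lowest decile is 0.05 and of the
highest 0.95. This is the convention under which τ = 0.1 and τ = 0.5 map
the extreme-decile pair to enrollment probabilities of 52% and 61% at a
50% baseline, and it is fixed as the contract. Each Monte-Carlo sample
draws N members without replacement, enrolls each independently, and
records mean(payment − cost) over the enrolled; the two compared payment
models see identical member draws and identical enrollment uniforms, so
per-sample differences are purely model-driven. Payments entering the
simulator must be cohort-calibrated (PR = 1 on the simulated population);
the demo pipeline enforces this rescale so that residual calibration
drift between validation and test does not masquerade as selection
profit. Positive overpayment means the payer pays more than enrollees
cost (favorable selection succeeded). Desk defaults (plans of 5,000, 500
samples; 2,000 in the demo so plans fit inside the test split) trade CI
width for speed and scale to larger settings by config.

## Numerical choices and edge cases

* Log offset c = 1 USD; payment floor $1 (avoids non-positive payments
  after the offset subtraction).
* Percentile ranks use average-rank ties scaled to (0, 100]; tail
  classification picks exactly ⌊q·n⌉ extreme members with stable
  tie-breaking, which forces sensitivity = precision by construction.
* The two-sample KS statistic is computed between log(pred + c) and
  log(obs + c) with the asymptotic method.
* The downsampled t-test resamples with replacement by default (100
  samples of 1000); all-zero differences are reported as the degenerate
  p = 1. Disjoint sampling is available when the cohort is large enough.
* Decile dispersion CIs are percentile bootstrap over within-decile
  resampling (200 replicates by default).
* Subgroup tables flag levels below 30 members rather than dropping
  them; levels below 3 get NaN metrics.
* Hierarchy validation reports one explicit cycle path; suppression is
  transitive by iterative reachability.
* All stochastic stages (generator, split, SVD, k-means, boosting,
  bootstrap, simulation) take explicit seeds derived from one top-level
  seed, and the demo report is byte-identical across runs with the same
  config.

## Problem sizes

Defaults used by the demo and the reproduction script: 20,000
beneficiaries (4,000 test), 10 latent conditions, 300-code vocabulary,
d = 50, k = 50 clusters (the vocabulary is far smaller than real claims,
so 250 clusters would exceed it), 2,000 plans × 1,000 members for the
dispersion check, plans of 2,000 with 500 samples for the selection
simulation. These sizes give stable orderings and tight identities while
keeping a full run in seconds; all scale up by config.

## Known limitations

* The baseline's toy category maps are structurally faithful but not the
  production tables; absolute baseline scores are not comparable to
  published risk scores.
* Decile calibration by value boundaries can shift a boundary-tied
  prediction into the neighboring decile; with continuous predictions
  this is measure-zero.
* The embedding method is one defensible instantiation (PPMI+SVD, w+c,
  cosine); the upstream literature offers several others, and cluster
  interpretability is not evaluated.
* The selection model is reduced-form: no plan behavior, benefit design,
  churn, or cost-control response, and enrollment decisions are
  independent across beneficiaries.
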