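# Methods

## Scope and model of the data

`carescreen` treats a survey as a wide integer matrix: n respondents × J
items with ordered categories 1..K (defaults J = 60, K = 5), organized by
a `ScaleDesign` into C constructs (default 6 × 10 items) with per-item
reversed-keying flags and a page size (default 10) used for response-time
parcels. Two respondent populations are modeled: *regular* respondents,
whose answers reflect correlated latent traits, and *careless*
respondents, whose answers ignore item content. Detection is a binary
classification problem with carelessness as the positive class.

## The synthetic-data generator

### Regular respondents: calibrated Gaussian copula

Responses are generated by discretizing a latent multivariate normal
vector at per-item thresholds t_{jk} = Φ⁻¹(Σ_{l≤k} p_{jl}), where p_j is
the item's marginal category distribution. The latent correlation matrix
is calibrated so the *ordinal* (post-discretization) Pearson correlations
match a target matrix: for each pair, the implied ordinal correlation as
a function of the latent ρ is expanded through the tetrachoric series of
the bivariate normal CDF,

    cov(X_i, X_j)(ρ) = Σ_{m≥1} (ρ^m / m) · A_i[m−1] · A_j[m−1],
    A_j[m] = Σ_k φ(t_{jk}) He_m(t_{jk}) / √(m!),

a polynomial in ρ solved by monotone bisection (300 terms, |ρ| ≤ .97;
truncation error ≲ 1e−4). Targets outside a pair's attainable
(Fréchet-type) range raise an error naming the pair, except in the
default pipeline where they are clamped to 95% of the bound — a surrogate
target matrix drawn independently of the margins can ask for the
infeasible, which empirically calibrated matrices never do. The generator
object stores the *effective* targets actually reproduced. An independent
Gauss–Legendre quadrature oracle in the test suite confirms the
calibration (ordinal r = .500 ± .001 for the uniform-margin test pair).
Indefinite matrices are repaired by eigenvalue clipping at 1e−6 with
unit-diagonal renormalization; the maximum entry drift is reported on the
spec (typically < .02).

### The target correlation structure

The default target matrix mimics a mixed-keyed six-construct personality
inventory: one factor per construct with loadings uniform on [.50, .79]
for positively keyed items and [.45, .57] (negative sign) for reversed
items — the asymmetry keeps opposite-keyed pairs within −.45 while
same-keyed pairs reach ≈ .62; construct intercorrelations uniform on
[0, .20]; and a facet bump of +.18 (toward the keyed sign, clipped to
[−.45, .63]) on consecutive same-construct item pairs, mirroring the
facet substructure of real inventories. The resulting mean absolute
intercorrelation is ≈ .08 with all entries inside [−.45, .63], and the
signed mean is near zero — real mixed-keyed inventories print small
signed means precisely because reversed items cancel. An optional
`mean_abs_target` rescale exists but is off by default: shrinking the
matrix toward a .05 mean magnitude produces a population in which
multivariate outlier detection cannot approach its published operating
characteristics, i.e. a strictly easier-to-imitate and less realistic
population.

### Item margins

Per-item category probabilities are drawn from a Dirichlet centered on an
agreement-leaning base profile (.05, .12, .22, .38, .23) — mirrored for
reversed items — with concentration 6 and a .02 probability floor. The
low concentration is deliberate: real personality items vary strongly in
skew (item means ≈ 1.9–4.2 on the 5-point scale here), and this
heterogeneity is what gives multivariate and model-based screens their
published power against uniform-random responding. The floor keeps every
category attainable so threshold estimation never degenerates.

### Careless respondents

Three styles, each iid across items given the respondent:

* **random** — uniform over {1..K} (20% per category at K = 5);
* **midpoint** — category probabilities (.05, .20, .50, .20, .05);
* **pattern** — two distinct categories a < b are drawn (redrawing ties),
  and the ascending run a, a+1, …, b is tiled across the J items
  (truncating the last cycle), e.g. draws {1, 3} give 1-2-3-1-2-3…;
  within a cycle the response always changes, so patterns defeat
  longstring-type screens by construction. Draws of more than two
  categories and non-contiguous patterns are not modeled; the two-draw
  ascending-run reading matches the canonical example.

A condition is assembled by rounding prevalence·n to the careless count
(counts of zero are an error), stacking regular and careless blocks, and
shuffling. Every function takes a seed or Generator; study loops spawn
independent substreams per replication via `SeedSequence`.

### Response times

Item-level durations are log-normal: regular median 7 s (log-sd .45),
careless median 3 s (log-sd .55). These values are package defaults, not
estimates: the literature supports only the qualitative shape (heavy
overlap between conditions, differences concentrated in the lower tail),
which these defaults produce. They are fully configurable, and a
"no-signal" configuration (identical parameters across conditions) serves
as a negative control: the RT-only classifier must then score a balanced
accuracy near .5.

### What the generator does not emulate

Real response styles beyond the three modeled (acquiescence, social
desirability), within-person onset of carelessness partway through a
questionnaire, item-content effects, and respondent-level RT–trait
dependence. Passing benchmarks on these synthetic conditions therefore
demonstrates correctness of the machinery and faithfulness to the
simulated designs — not field performance on real surveys, where
published results show all methods degrade substantially.

## Detection indices

Index-specific data handling follows the benchmark's assignments:
longstring, IRV and antonyms use raw (un-recoded) responses; Mahalanobis
and even–odd use recoded responses (x → K+1−x on reversed items).

* **Mahalanobis**: D²ᵢ with sample mean and (n−1)-denominator covariance
  of the analysis sample itself (careless included), via Cholesky solve;
  flag D² > χ²₁₋α(J) with α = .05. An optional ridge (λ·tr(S)/J on the
  diagonal) supports n ≤ J; it is off by default since benchmark samples
  have n = 180 > J = 60. The identity mean(D²) = J(n−1)/n is asserted in
  tests.
* **Antonyms**: qualifying pairs are all item pairs with sample r ≤ −.20
  (fewer than 3 is an error advising a laxer criterion); the score is the
  respondent's Pearson correlation between first- and second-element
  responses across pairs. Flag: score > 0 (strict).
* **Even–odd**: construct-wise means of odd- and even-positioned items,
  per-respondent correlation across constructs, Spearman–Brown adjusted
  r' = 2r/(1+r) (r = −1 maps to −1). Flag: score < .30.
* **Longstring**: maximum identical run in administration order; flag ≥ 6.
* **IRV**: per-row SD (ddof = 1); two-sided rule at the 5th/95th sample
  percentiles. Both tail variants are computed; the harness keeps the
  better-accuracy tail, reproducing the benchmark's acknowledged
  overestimate.

Scores that are undefined (zero within-person variance) are NaN and never
flagged; the count is surfaced. The antonym, even–odd, IRV and Z_h
cutoffs are package defaults (the benchmark never printed its
dichotomization for these), so only the fully specified rules
(Mahalanobis 95%, longstring ≥ 6) plus the cutoff-robust Z_h sensitivity
are anchored to published numbers.

## Graded response models and Z_h

The "multidimensional" structure is between-item: one unidimensional GRM
per construct with independent standard-normal traits. Items have
discrimination a > 0 and strictly ordered thresholds b₁ < … < b₄ in the
cumulative-logistic parameterization. Estimation is marginal ML via EM on
a fixed Gauss–Hermite grid (default 21 nodes; the E-step is exact given
the grid), with per-item M-steps by L-BFGS on the unconstrained
parameterization (log a, b₁, log-gaps) using analytic gradients.
Convergence: max absolute parameter change < 1e−3 or 200 cycles
(harness runs cap at 60 cycles — Z_h is insensitive to the tail cycles,
and contaminated samples otherwise crawl); non-convergence returns the
best iterate with a warning. A small prior-shaped pseudo-count
(`category_smoothing` = 1e−3) added to the expected category totals keeps
thresholds finite and ordered when a category is rare or unobserved —
the stabilization that a collapse-and-expand rule would otherwise
provide, without changing K. EM ascent of the (negligibly penalized)
marginal likelihood is asserted in tests. Parameter recovery at n = 2000,
10 items: discrimination within ±.15, threshold RMSE ≤ .10.

Trait scores are EAP (finite for all patterns, prior mean 0 with zero
items). Z_h sums over all 60 items at each item's own construct estimate:
ℓ = Σ log P, E[ℓ] = ΣΣ P log P, V[ℓ] = Σ[Σ P (log P)² − (Σ P log P)²],
Z_h = (ℓ − E[ℓ])/√V[ℓ]; zero total variance (all items flat) is an
error. The standardization is exact conditional on θ (null mean 0, SD 1,
verified on model-consistent simulees at their true traits); plugging in
EAP estimates shifts the null upward by ≈ 0.5 per estimated trait, which
makes the default lower-tail flag (Z_h < −1.96) conservative. By default
models are calibrated on the full analysis sample being scored
(contamination included), matching the benchmark's per-sample usage;
fitted parameters are JSON-exportable so samples can share calibrations.

## Boosted trees

The classifier is written from first principles. Margins F start at the
prior log-odds F₀ = ln(p̄/(1−p̄)) (computed on the up-sampled training
data, hence ≈ 0). Each round fits a depth- and leaf-limited regression
tree to the pseudo-residuals g = y − p on a without-replacement subsample
(fraction .5 by default; the benchmark states subsampling without a
fraction, and .5 is the reference implementation's default), then updates
F ← F + λ·tree(x). Split search is exhaustive least squares over all
features with candidate thresholds at midpoints of the unique values
present at the node, ties broken toward the lowest feature index then
lowest threshold; leaf values take one Newton step γ = Σg / Σp(1−p).
For speed, feature values are coded into per-feature bins once per
ensemble so each node's scan is two `bincount`s; the public `fit_tree`
uses the identical code path. Tests pin the split choice to an
exhaustive-search oracle and the ensemble's balanced accuracy to within
.05 of scikit-learn's gradient boosting on matched hyperparameters
(the library is a cross-check only, never the implementation).

Class imbalance is handled by up-sampling: minority rows are resampled
with replacement to the majority count, *inside each training fold only*;
a provenance-index test asserts no replicate reaches a validation fold.
Grid search uses stratified 10-fold CV minimizing mean validation
logistic loss; all tree counts in the grid are read from one staged fit
per (depth, leaf, shrinkage) cell; ties break toward fewer trees, then
shallower depth, then larger leaves. The full benchmark grid (depth
2–4, leaf 4–10, shrinkage .001–.03 step .002, trees 250–800 step 50;
3780 cells) is available behind `TuningGrid.full()`; the default reduced
grid (depth {2,3}, leaf {5,10}, shrinkage {.005,.015,.03}, trees
{250,500}) keeps replicated studies at desk scale. Classification is at
p ≥ .5.

## Study harness

*Simulation mode*: per replication, fresh training (n = 425) and test
(n = 180) samples at the condition's prevalence and style; traditional
indices and Z_h are evaluated on the test sample alone (sample-level
rules — the Mahalanobis covariance, IRV percentiles — are computed on the
test sample itself, the benchmark-faithful if statistically generous
choice); the classifier is tuned and trained on the up-sampled training
sample. The grid search runs once on the first replication and its
selection is reused (`tune_per_replication=True` restores per-replication
tuning at ~20× the cost). Failures abort a replication and are logged
(JSONL: seed, chosen hyperparameters, errors); more than 5% failed
replications aborts the run.

*Empirical-emulation mode*: one labeled dataset (605 respondents,
361 regular / 244 careless by default) with response times is repeatedly
split by the constrained draw — test size = round(.30·n) adjusted down to
the nearest size admitting an exact 9:1 regular:careless ratio (here
162:18; remainder 199:226 trains) — and three feature sets are compared:
raw responses, RT parcels, and both. RTs are winsorized at the 95th
percentile per item (upper tail only) and summed into page parcels of 10
(sums; means are an equivalent rescaling for trees). Winsorizing and
parcel construction use the full dataset once, as in the emulated design.

Metrics per method and replication: sensitivity TP/(TP+FN), specificity
TN/(FP+TN), precision TP/(TP+FP) (NaN when nothing is flagged), accuracy,
balanced accuracy = (sens+spec)/2 — identities asserted exactly. Tables
report means and SDs across replications.

## Problem sizes and determinism

Replicated runs use 200 replications for index-only benchmarks, 50 for
GRM- and classifier-inclusive ones — sizes at which the reported means
are stable to well under the comparison tolerances (SDs shrink as
1/√replications). All stochastic stages flow from one seed through
spawned substreams; identical configuration and seed reproduce tables
bit-for-bit.

## Known limitations

* The surrogate population is cleaner than real survey data: published
  field results show every method, supervised or not, performing far
  worse on real respondents than on simulated ones. In particular the
  supervised classifier here reaches slightly higher balanced accuracy
  against uniform-random respondents (≈ .94) than the published simulated
  benchmark (.86) — on a population calibrated so that unsupervised
  multivariate screens achieve their published near-perfect operating
  characteristics, a supervised learner cannot be made much worse without
  breaking those anchors.
* Correlated traits and cross-loadings are out of scope for the IRT
  layer; Z_h at EAP estimates is conservative (upward-shifted null).
* No missing-data support: a missing cell is a validation error by
  design (the emulated surveys forced responses).
* Guttman-error counts and polytomous U3 indices are not implemented.
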