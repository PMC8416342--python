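# Methods

This note records the statistical procedures the package implements, the
modelling choices that were genuinely open, the synthetic-data model and
what it does and does not emulate, and the numerical conventions that make
runs reproducible.

## Scale scoring

PSS-10 items are coded 0–4 with the four positively stated items (4, 5, 7,
8; 1-based) reverse-scored as `4 − raw`, giving totals 0–40. GAD-7 and
PHQ-9 items are coded 0–3 with no reversals (totals 0–21 and 0–27);
"moderate" anxiety/depression is flagged at total ≥ 10, the cutoffs
validated for this population. Attitude items stay on the −2…+2 scale on
which the source survey reports means; for discrete network modelling they
are treated as 5-level categorical codes. Records with any missing analysis
variable are dropped before analysis and counted in the run manifest;
item-level imputation is out of scope.

## Group comparisons

Binary items use the Pearson chi-square test of homogeneity without
continuity correction — the design is 4 × 2 (df = 3), where the Yates
correction has no justification and would not reproduce the published
statistics. Ordinal attitude items use Kruskal–Wallis with tie correction;
all-constant input returns H = 0, p = 1 rather than an error. Scale totals
use one-way fixed-effects ANOVA; `anova_from_summary` computes the
algebraically identical F from per-group (mean, SD, n) so published
statistics can be checked from rounded summaries — with moments rounded to
one decimal an absolute tolerance of 0.15 on F is appropriate, and the
recomputed PSS F (8.83 vs printed 8.92) sits inside it. Main tests are
flagged at α = 0.05/3 (three content domains), pairwise contrasts at
α = 0.05/6 (six grade pairs). The source does not name the post-hoc
procedure; the convention here applies the same family of test to each
grade pair. One published contingency row ("sleep") is internally
inconsistent (grade-3 counts sum to 131 against a grade size of 121) and is
excluded from exact reproduction checks.

## PCA of the attitude items

PCA is computed on the correlation matrix (the items share a response
scale), components retained by the strict Kaiser rule (eigenvalue > 1), and
retained loadings rotated by varimax with Kaiser row normalization
(tolerance 1e−6, ≤ 100 iterations). Orientation is made reproducible by
flipping each component so its largest-magnitude loading is positive and
ordering components by explained variance. Sampling adequacy uses the
Kaiser–Meyer–Olkin ratio of squared correlations to squared plus squared
anti-image partial correlations (overall and per item) and Bartlett's
sphericity test, χ² = −(n−1−(2p+5)/6)·ln det R on p(p−1)/2 df. Cronbach's α
is the classical variance-ratio form; component reliabilities are computed
over the items assigned to each rotated component by largest absolute
loading. Ordinal responses are treated as numeric (Pearson correlations);
polychoric correlation and parallel analysis are out of scope. The
published KMO/Bartlett/variance/α values depend on the unavailable raw
data and serve as documentation anchors, not test targets.

## Bayesian-network structure learning

All 43 items are modelled as discrete multinomial variables with level sets
fixed from the instrument codings — a bootstrap resample that happens to
miss a level still scores against the full level set. The network score is
the decomposable BIC: per node, the multinomial log-likelihood given the
parent configuration minus `(ln n / 2) · (r−1)·Πq` free parameters. A
configurable cap on per-family parameter counts (default 100 000) guards
against parent-configuration explosion.

Hill climbing greedily applies the single-edge move (add / delete /
reverse) with the largest strictly positive gain, skipping moves that would
create a cycle. The search is fully deterministic: ties break on the
lexicographically smallest (operation, source, target), so no seed is
needed and results are invariant to respondent order. Family scores are
cached per (node, parent-set).

Bootstrap model averaging draws resamples of size n with replacement,
learns one structure per resample, and tabulates for each unordered pair
how often it is connected (presence strength) and, among those, how often
each orientation occurs (direction strength; the two orientations sum
to 1). The final averaged graph keeps pairs with presence ≥ 0.5 (the
published account says only "most consistent"; 0.5 is the package default
and is configurable, with a data-driven threshold — the strength level
whose step CDF is L1-closest to the empirical strength CDF — available as
`threshold="auto"`). Majority orientation is applied; if the result
contains a directed cycle, the lowest-presence edge in each cycle is
dropped, deterministically and recorded in the manifest. Local conditional
probability tables are not estimated: the analysis reports structure only.

The replicate count is a runtime dial, not a statistical one: tests and the
acceptance script use tens to hundreds of replicates on small variable
sets; the fidelity setting of 10 000 replicates over all 43 items is
reachable through `RunConfig(bootstrap_reps=10_000)` and costs on the order
of an hour of CPU.

## Intra-individual covariance networks

The printed similarity formula is typographically corrupted in the source;
it is implemented as `w_ab = exp(−(z_a − z_b)²)`, the unique reading that
is bounded in (0, 1] with larger values meaning more similar deviation.
z-scores use cohort mean and SD with ddof = 1; a constant item is an error
naming the item. Note the proportional threshold depends only on the
ordering of |z_a − z_b|, so every monotone decreasing transform of distance
yields the same binary graph: each respondent's network is a proximity
graph on their 43 z-values.

The sparsity grid runs 0.05–0.20 in steps of 0.01 (the published "intervals
of 0.1" cannot produce a grid inside that range; 0.01 contains the
published working point K = 0.14). Graph metrics are computed on the
binarized graph: connectedness as the fraction of nodes in the largest
component (a laxer "fraction of non-isolated nodes" reading is available
via `ScreenCriteria(connectedness_mode="non_isolated")`), clustering
coefficient averaged over all nodes, characteristic path length on the
largest component, small-worldness σ against 20 degree-preserving rewired
nulls (10·|E| swap attempts each, seeded), and modularity Q as the best of
5 seeded Louvain restarts. The working K is the smallest grid value at
which more than 95 % of respondents pass all three screens.

Betweenness is unweighted shortest-path betweenness; within-respondent
ranks are competition ("minimum") ranks so that "rank ≤ 4" keeps its
top-10 % meaning under ties. Hubs require rank ≤ 4 in more than 40 % of
respondents (the figure-caption preset — rank ≤ 5 in ≥ 25 % — ships as
`HUB_PRESET_FIGURE`). Hub-symptom associations are Spearman correlations
between an item's rank and each scale total, flagged at |ρ| > 0.3 and
p < 0.001.

### What betweenness hubs require, and a negative finding

Two structural facts about this construction matter for interpretation.
First, after cohort z-scoring every item has unit variance, so each
respondent's 43 z-values crowd an interval of roughly ±2: the gap between
any two item clusters almost always contains other items, and no single
item can be the sole bridge between two planted blocks. Second, 4- and
5-level items quantize z to a grid with steps of roughly 0.8–1.1, so an
item generated to sit midway between two tight bands rarely lands there
after thresholding. In extensive simulation (hundreds of generator
configurations, cohorts up to n = 400, and idealized continuous profiles),
an item whose latent value is coupled to the midpoint of two otherwise
independent blocks never attains top betweenness rank in anywhere near a
majority of respondents; its top-4-rank prevalence stays within a factor
of ~2 of the exchangeable-null expectation (4/43 ≈ 9 %) and is unstable
across seeds. The reliable, monotone signature of planting is instead the
hub's elevated similarity (and thresholded degree) to its two blocks,
which the tests assert end to end. Consequently, stable betweenness hubs
in real data of this kind are most plausibly driven by items with
consistent positions in the z-cloud — highly skewed items pinned near a
fixed standardized value — rather than by covariance bridging alone, and
hub lists from this method should be read with that in mind.

A related finding: with 43 items, the largest-component connectedness
criterion (> 80 %) is rarely satisfied by more than 95 % of respondents at
any K ≤ 0.20 — even idealized continuous Gaussian z-profiles only reach
that bar at K ≈ 0.20, and discretized survey items fall short at every
grid point. Sparsity selection on generated cohorts therefore raises a
`NoQualifyingSparsityError` carrying the per-K pass-rate table; selection
is exercised in tests on constructed weight matrices engineered to first
pass at K = 0.14, and pipeline runs on synthetic cohorts fix K = 0.14
directly (or use the non-isolated connectedness mode).

## Synthetic cohort generator

Per respondent in grade g the generator draws a general distress factor
G ~ N(0,1); block factors for stress, anxiety and depression shared by the
PSS, GAD-7 and PHQ-9 items; and attitude factors for the threat (3 items)
and coping (4 items) blocks. An ordinal item's latent value is
`λ_G·G + λ_B·B_block + shift(g) + noise_sd·ε`, cut into its response
levels by fixed thresholds; each item's cut-points are additionally shifted
by a deterministic per-item "difficulty" offset (golden-ratio sequence
scaled by `difficulty_spread`), mirroring the endorsement-rate
heterogeneity of real instruments and keeping different items' z-scores
off a common discrete grid. Binary lifestyle items are independent
Bernoulli draws at per-grade prevalences.

Defaults are the study conditions: grade sizes 123/110/121/100; binary
prevalences equal to the published per-grade proportions; latent grade
shifts (+0.3, +0.1, −0.1, −0.3 SD) mirroring the published decline of
distress across grades; loadings λ_G = 0.6, λ_B = 0.5 (attitude 0.8) and
noise SD 0.8, giving inter-item correlations in the 0.2–0.5 range typical
of symptom scales; 4-level thresholds (0, 1, 2) produce the right-skewed
screener marginals (per-item means ≈ 0.7–0.8) and 5-level thresholds
(±0.5, ±1.5) near-symmetric attitude/PSS marginals. `null_config()` zeroes
all grade effects (pooled prevalences, flat shifts) for type-I-error
calibration; `hub_test_config()` is the planted-hub regime (tight
correlated stress/depression bands, scattered anxiety block, spread binary
prevalences). Marginal frequencies converge to the thresholded-normal
probabilities (checked at n = 10 000 within 2 %); identical seeds give
byte-identical cohorts.

What the generator does **not** emulate: the real cohort's full joint
distribution (it is not fitted to the published moments beyond the binary
prevalences and grade sizes), item-specific loading patterns, differential
missingness, or response styles. Passing tests on synthetic cohorts
therefore demonstrate that the machinery is correct and calibrated — not
that the published multivariate findings would replicate.

## Numerical conventions

Proportional thresholding keeps exactly `round(K·p(p−1)/2)` edges, with
exact weight ties broken by lexicographic node-pair order. All stochastic
components (bootstrap resampling, null rewiring, Louvain restarts, the
generator) consume `numpy` Generators seeded from explicit arguments;
every pipeline run writes its seeds and parameters to `manifest.json`, and
identical configurations reproduce outputs byte for byte. Degenerate
inputs fail loudly with the offending item named: constant items in
z-scoring, zero marginals in contingency tables, zero within-group
variance with equal means in ANOVA, singular correlation matrices in KMO.

## Problem sizes used in tests and the acceptance script

Unit and acceptance tests run the generator at 40–454 respondents,
bootstrap averaging at 1–50 replicates on 3–4 variables, null ensembles of
3–10 rewirings, 100–1000 replicates for oracle-equivalence and calibration
checks, and 500 cohorts for the false-hub null. These sizes were chosen so
the full suite runs in well under a minute per module while keeping every
Monte-Carlo margin wide (e.g. type-I calibration at 1000 replicates has a
±1.4 % binomial standard error against a ±1.5 % acceptance band).
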