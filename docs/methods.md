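# Methods

`eddi` identifies **dosage-based dependency predictors (DDPs)**: genes
whose expression level predicts whether a cancer cell line depends on
another gene. The inputs are a genes × cell-lines expression matrix
(RPKM, transformed to log2(RPKM+1) on read), a genes × cell-lines
RNAi dependency-score matrix (DEMETER-style; more negative = more
dependent), and a cell-line → tissue annotation. Blood-lineage cell
lines are excluded by default (their genetic background differs from
solid tumours); the excluded label set is configuration, not code,
because annotation releases spell the lineage differently.

The pipeline has six stages. Each is a pure function of its inputs and
a seed; sub-seeds derive from the master seed through a fixed
`SeedSequence`, so a rerun reproduces every artifact byte for byte.

## Stage 1 — pairwise screen

For a dependency D and a gene G, dependency scores carry no canonical
"dependent" threshold, so the screen searches for one. Cells with
score < 0 seed the dependent class. A 10-fold cross-validated
single-feature logistic regression of the class labels on G's
expression is scored with the Brier score (mean squared difference
between forecast probability and outcome; 0 is perfect, 0.25 is the
uninformative constant-½ forecast). The least-dependent cell is then
dropped and the fit repeated, down to a floor of 20 dependent cells.
The boundary whose labeling attains the lowest CV Brier wins; exact
ties resolve to the more negative (stricter) boundary.

Numerical choices:

* Fold assignment is stratified on the *initial* labels, seeded, and
  reused at every iteration of one pair, so Brier values are
  comparable across boundaries. (Stratifying per-iteration is
  impossible to reconcile with fold reuse, since the labels change.)
* The logistic fits are a damped Newton solver written for the 1-D
  case: the screen performs on the order of 10⁵–10⁶ fits, and each is
  a two-parameter problem where Newton is exact and fast. All
  (iteration × fold) problems of one pair advance together as
  vectorized array rows. Perfect separation is handled by capping the
  linear predictor at ±30 — probabilities saturate, which is all the
  Brier score sees — and a row stops iterating once its step or
  training gradient vanishes. A unit test pins the solver to
  scikit-learn's unpenalized logistic regression on non-separated
  data.
* An uninformative gene's fold models forecast the training base rate,
  so its best achievable Brier is ≈ p(1−p) of the most imbalanced
  admissible labeling. With the default floor of 20 dependent cells
  this stays well above what a real dosage relationship reaches.

Two filters follow. **Separation**: the dependent and non-dependent
expression interquartile ranges must not overlap (linear-interpolation
quantiles; quartile rules are convention-sensitive, so the convention
is fixed and documented). The literal mutual "75th ≥ 25th" reading,
which passes on IQR *overlap*, is preserved behind
`separation_rule="as_printed"`, but the default implements the
separation the filter is for. **Linearity**: within the dependent
cells, the OLS slope of score on expression must be significant at
P < 0.001 (two-sided t-test). With a single predictor a relaxed-lasso
fit reduces exactly to this OLS test: the active set is either empty
or the unpenalized fit. A pair must pass **both** filters; pairs with
fewer than 20 initially dependent cells or constant expression are
skipped and recorded, never raised.

The all-pairs screen is O(genes × dependencies × iterations); the CLI
and library accept gene/dependency restrictions for desk-scale runs.

## Stage 2 — strict dependent-cell definition

Screen boundaries exist only to find candidate pairs; classification
needs one defensible label set per dependency. Each surviving pair is
clustered with k-means (k = 2, 10 seeded restarts, best inertia) on
z-scored (expression, score) points — 2-D standardization stops the
wider-range variable from dominating; score-only clustering is a
config switch. The cluster with more cells below the −2 hard
threshold is the dependent cluster, and only its members **below −2**
are labeled dependent. A pair contributes nothing when either cluster
has fewer than 20 cells or the below-−2 vote ties. The dependency's
final dependent set is the union over its pairs — so no cell scoring
≥ −2 can ever be labeled dependent, which the tests assert as a hard
guarantee.

## Stage 3 — random-forest gate and importances

One random-forest classifier per dependency: features are the
screened predictors' expression, the target the strict labels.
Defaults follow the classical setup — 500 trees, minimum node size 1,
and the per-split feature count m tuned by a stepwise out-of-bag
search from √p (doubling/halving by 2, accepted while OOB error
improves by > 5% relative). Performance is stratified 10-fold CV
repeated 5 times; because dependent cells are the minority, they are
up-sampled with replacement to the majority count **inside each
training split only** — the held-out fold is never resampled, which a
test asserts through an instrumentation hook. The per-fold ROC AUCs
are averaged (fold-level and repeat-level values are both exported;
pooled AUC is a flag). Dependencies with mean AUC ≥ 0.7 pass the
gate. A final forest on all (up-sampled) data yields mean-decrease-
in-Gini importances, from which coding vs antisense importance ranks
are reported (min-rank ties; `FOO-AS1`/`FOO-AS2` → `FOO` naming by
default, an explicit two-column map overrides).

## Stage 4 — relaxed lasso within dependent cells (SEESAW)

Some predictors scale linearly with the dependency score inside the
dependent set. The dependent cells' scores are regressed on the
z-scored screened predictors with a relaxed lasso: for each penalty λ
on a 100-point log-spaced path, the relaxed coefficients blend the
penalized fit with the OLS refit on the same active set,
β(γ,λ) = γ·β_lasso(λ) + (1−γ)·β_OLS, over γ ∈ {0, 0.25, 0.5, 0.75,
1}. (γ = 1 is the plain lasso — asserted against an independent
coordinate-descent fit.) The pair (γ, λ) minimizes leave-one-out
squared error; dependent sets are small (tens of cells), so LOOCV is
exact refitting — the path is recomputed on each n−1 subset at the
full-data λ grid — rather than an approximation, and a brute-force
per-observation refit oracle reproduces it in tests. Reported metrics
are LOOCV RMSE and LOOCV R² = 1 − PRESS/TSS (primary) plus training
R². Ties prefer the larger λ, i.e. the sparser model.

Predictors active at the optimum get the SEESAW label. Sign
convention, stated once: scores become **more negative** with
stronger dependency, so a **negative** coefficient (expression up ⇒
score down) means expression rises with stronger dependency — SEE —
and a positive coefficient is SAW.

## Stage 5 — modes of expression

Every predictor of a gate-passing dependency is labeled from the
dependent vs non-dependent contrast:

* **over / under** — |log2 fold change| ≥ 1 (two-fold) with
  BH-adjusted p < 0.05. The default differential-expression engine is
  Welch's t-test per gene on the log2(RPKM+1) values with
  Benjamini–Hochberg adjustment across all tested genes. A
  negative-binomial count model is deliberately not the default:
  RPKM-derived values do not satisfy count-model assumptions, and the
  downstream criteria (fold change, adjusted p) are engine-agnostic —
  an externally computed DE table can be plugged in unchanged.
  Zero-variance genes get p = 1.
* **suppressed_under** — under-expression where the dependent cells
  are essentially silenced: median log2(RPKM+1) < 0.1. The median (not
  "all cells") is the default aggregation for robustness to single
  outliers; an all-cells rule is a switch. Suppressed-under supersedes
  plain under and implies the under criterion, asserted on every
  output.
* **separable** — an orthogonal flag, not a class: |Pearson r| ≥ 0.5
  between expression and the 0/1 dependent-template vector. Note the
  entanglement with the screen: any pair passing the IQR-non-overlap
  filter has a point-biserial template correlation near or above 0.5,
  so most screened pairs are also separable; the flag mainly grades
  *how* cleanly the classes split.
* The SEESAW direction is attached when stage 4 selected the gene.

Pairs passing the forest but meeting no criterion stay in the output
with an empty mode for audit, excluded from DDP tallies.

## Stage 6 — systems layer

* **Shared-DDP network**: bipartite graph of dependencies and
  predictors appearing in ≥ 2 dependencies, plus the
  dependency–dependency projection weighted by exact shared-DDP
  counts (GraphML + edge-list + projection CSV).
* **Mode-profile clustering**: dependencies × DDPs matrix of
  categorical mode codes (0 absent, 1 over, 2 separable-over, 3
  under, 4 separable-under, 5 suppressed-under, 6 SEE, 7 SAW — the
  integers are labels only), agglomerated on both axes with Hamming
  distance and average linkage (configurable); ordered matrix CSV and
  Newick dendrograms are exported. When a record carries several
  labels the code takes the most specific one (SEESAW > suppressed >
  separable over/under > over/under).
* **Tissue composition**: per-dependency tissue fractions of the
  dependent lines (sum to 1) and per-tissue penetrance (dependent
  lines of tissue T / all lines of T).
* **Over-representation**: hypergeometric upper-tail test of a query
  gene list against user-supplied GMT gene sets within a stated
  universe, BH-corrected; a set is enriched when overlap ≥ 5 and
  FDR < 0.25. The implementation is pinned to brute-force tail
  enumeration on small universes in tests.

## Synthetic data generator

The generator is first-class code: it emulates the three inputs with
*planted* relationships so every stage is testable without external
data. Dependency scores are bimodal — dependent cells ~ N(−3, 0.3)
truncated below −2, non-dependent ~ N(0, 0.5) truncated above −2 — so
ground truth is unambiguous and the −2 rule of stage 2 is exactly
respected. Planted predictor modes: over/under (mean shift of
`effect_size` on the log2 scale), separable variants (shift forced
large enough that class IQRs cannot overlap), suppressed-under
(dependent expression pinned below 0.1), seesaw up/down (dependent
expression linear in the score with the configured slope sign), and
null (noise independent of every dependency). Every planted non-null
predictor also carries a linear dose component within the dependent
class, scaled to its effect size: the relationships being planted are
dosage-based by definition, and without a within-class trend no
over/under pair could pass the screen's linearity filter. The trend
coefficients are sized so the slope test passes with orders-of-
magnitude margin at the default noise (worst-case planted mode
p ≈ 10⁻⁶ against the 10⁻³ threshold across seeds).

Dependencies can be **correlated**: a child dependency copies its
parent's dependent-cell set and adds N(0, 0.15) noise to the parent's
scores (the −2 partition is preserved exactly). This emulates
co-dependencies, whose predictors are genuinely shared — the only way
shared-DDP network structure can exist in synthetic data, since an
expression row cannot track two unrelated score vectors through the
linearity filter.

The standard demo study (`demo_study`) is 200 cells, 60 genes, two
correlated dependencies with 50 dependent cells each, ten planted
pairs covering all seven modes (effect sizes 2.0, separable 3.5,
suppressed 2.5), noise SD 0.25, plus ~50 null genes. RPKM-scale
export inverts the log transform so the fixture feeds `read_expression`
end-to-end.

What the generator does **not** emulate — and hence what passing
tests do not show about real data: gene–gene correlation beyond the
planted pairs, RNAi off-target structure or DEMETER inference noise,
tissue-driven expression covariates, heavy-tailed expression
distributions, and batch effects. Recovery results on this generator
demonstrate correctness of the machinery, not expected sensitivity on
DepMap-scale screens.

## Problem sizes and defaults

Defaults follow the study conditions: screen floor 20 dependent
cells, slope threshold 10⁻³, k-means minimum cluster 20, forest 500
trees with 10×5 CV and AUC gate 0.7, γ grid of five values with a
100-point λ path, DE thresholds 2-fold / 0.05, suppression cutoff
0.1, separable threshold 0.5, enrichment overlap ≥ 5 at FDR < 0.25.
The test suite and the acceptance script run the same algorithms on
reduced study sizes chosen as the package's own trade-off between
statistical resolution and turnaround: repeated-seed loops use
100–150 trees with 2 CV repeats and a 50-point λ path, recovery runs
use the 200-cell demo study, and oracle comparisons use ≤ 60-cell
fixtures where brute-force enumeration is feasible.

## Known limitations

* The screen's AND of separation and linearity filters is strict: a
  purely non-linear mean-shift biomarker with no dose trend inside
  the dependent class will not survive. The filters are independently
  switchable for users who want the union instead.
* tuneRF-style OOB search is greedy and can stop at a local optimum
  of m; with the small feature sets the screen produces this is
  inconsequential.
* LOOCV by exact refitting scales as n × path length; dependent sets
  beyond a few hundred cells would want the approximate leave-one-out
  formula instead.
* The Welch-test DE engine treats log2(RPKM+1) as approximately
  normal per gene; for raw counts, plug in an external DE table.
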