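# Methods

## The model

`syntroscan` operationalizes a simple hypothesis: communities performing
syntrophic degradation carry more copies of the gene families that mediate
interspecies electron transfer — hydrogenases, formate dehydrogenases, FeS
oxidoreductases and the Rnf/Fnr and Fix membrane complexes — than
communities where other metabolisms dominate. The analysis has four
stages.

**1. Category scores.** Each sample is a map from gene-family identifiers
(opaque COG- or KO-style tokens) to gene counts, plus the total number of
detected genes `G`. A catalog assigns families to named categories in two
divisions, `universal` (housekeeping; negative control) and `syntroph`
(energy transfer; predictive). The score of category `C` is
`(Σ_{f∈C} n(f) / |C|) / G`. Dividing by `|C|` makes categories of
different sizes comparable; dividing by `G` removes sequencing depth, so
that doubling every count and `G` leaves the score unchanged (a tested
invariant). Families outside the catalog still count toward `G`: the
normalization is against all detected genes. Duplicated family ids within
a category are collapsed; the same family may appear in two different
categories and then counts once in each. Whether an annotation pipeline
reports one family hit per gene or several is upstream of this package;
records are counted as given.

**2. Ordination.** The sample × category matrix is analyzed by PCA on the
correlation matrix: columns centered and scaled to unit sample variance
(divisor n−1). Correlation (rather than covariance) PCA is essential here
because universal scores are an order of magnitude larger than syntroph
scores; without scaling they would own the components. Computation is by
SVD of the standardized matrix — algebraically the eigendecomposition of
the correlation matrix, numerically better conditioned — and is
contract-tested to 1e-8 against a dense symmetric eigensolver and against
scikit-learn. Component signs are fixed by making each component's
largest-magnitude loading positive; comparisons with other software hold
only up to per-component sign, and only component-wise where eigenvalues
are simple (with fewer samples than categories the trailing null space has
no preferred basis). A zero-variance category is an error naming the
category, never a silent drop. The scree table reports eigenvalues,
variance proportions and their cumulative sum; the circle of correlations
reports `loading × √eigenvalue`, the Pearson correlation between each
standardized category and each component (unit-disk bounded, tested
against direct correlation). Fitted models serialize to JSON and project
new samples by `((x − mean)/scale) · loadings`.

**3. Confidence ellipses and calls.** Groups are formed from the sample
labels: syntrophic-culture plus potentially-syntrophic samples versus
non-syntrophic samples; `other` samples are projected but never enter an
ellipse fit. On the first two components each group gets a normal-type
95% ellipse: sample mean, sample covariance (requiring ≥3 non-collinear
points) and squared Mahalanobis boundary at the χ²₂ quantile, computed
numerically (for level γ the closed form is −2 ln(1−γ), the test oracle).
A t-type boundary (Hotelling-style `2(n−1)/(n−2)·F`), heavier at small n,
is available as an option; the normal type is the default because it is
closed-form testable and the difference is small at these group sizes.
Separation is summarized by `area(e₁∩e₂)/min(area)`, estimated by grid
integration over the smaller ellipse's bounding box (default 256²) or by
uniform Monte-Carlo sampling inside the smaller ellipse; the two estimators
are cross-checked against each other. Calls: inside exactly one ellipse →
that group; both → `ambiguous`; neither → `neither`.

**4. Group statistics.** Per syntroph category, group means are compared
with a two-sided Welch t-test (statistic and Welch–Satterthwaite df from
the closed forms, p from the numerical t CDF; Student's pooled test by
flag). No multiple-testing correction by default, matching per-category
reporting; Bonferroni and Benjamini–Hochberg are options. `higher_in` is a
tie when the mean difference is below 1e-15. A lossless long-format melt
of the matrix backs surface/heatmap plots.

## The synthetic cohort generator

Real inputs of this kind live in annotation databases and are
version-dependent, so the generator provides cohorts with known ground
truth. Defaults emulate the reference study design: 14 syntrophic samples
(5 cultures + 9 potentially syntrophic), 24 non-syntrophic, 4 `other`;
total gene counts log-uniform over 25,694–14,687,361 (the span of the
reference cohort, ~3 orders of magnitude); universal baseline rate 2×10⁻³
and syntroph baseline 2×10⁻⁴ expected annotations per member family per
detected gene (order-of-magnitude choices: housekeeping families are
roughly tenfold more abundant than specialist energy-transfer families).
Syntrophic samples multiply every syntroph-category rate by 3 — 3.5 for
confurcating hydrogenases, which show the largest group difference — with
two deliberate exceptions: Fix gets multiplier 1 (its families also serve
nitrogen fixation and occur everywhere), and all universal multipliers are
exactly 1. `other` samples carry the non-syntrophic signal under their own
label, mimicking communities whose syntrophy is not expressed through the
cataloged families.

Counts are negative binomial (size 10, i.e. ~32% biological CV) realized
as a gamma rate multiplier shared by all families of a category within a
sample, then Poisson draws per family: marginally each family count is NB
with the configured size, and the category total keeps the full
overdispersion. The shared multiplier reflects how communities actually
vary — a shift in syntroph abundance moves all hydrogenase families
together — whereas independent per-family noise would average out at the
category level. Pure Poisson noise is available but is a degenerate
between-sample model: shot noise vanishes at high depth, so group scatter
would be an artifact of the depth distribution (deep samples glued to the
mean, shallow ones flung wide) rather than of community variation.

What the generator does *not* emulate: taxonomic composition,
compositional closure between categories, correlated category blocks,
annotation bias between databases, or heavy-tailed family distributions
within a category. Passing end-to-end tests therefore demonstrates that
the pipeline recovers the designed signal under realistic depth spread and
overdispersion — not that any particular real environment will separate.

## Numerical choices and edge cases

- n−1 variance everywhere (standardization, covariance, Welch).
- Ellipse fits reject <3 points and singular covariance (collinear or
  duplicated points) rather than regularizing.
- Overlap is reported relative to the smaller ellipse (a bounded,
  comparable index); absolute intersection area is also available.
- Grid overlap at resolution 256 agrees with Monte-Carlo at 2×10⁴ draws
  to well under 0.02 on test geometries.
- All simulation randomness flows through one `numpy` Generator seeded
  from the config; identical seeds give bit-identical cohorts and
  byte-identical CLI artifacts (run manifests record input/output hashes
  and the seed, and contain no timestamps).
- Cohorts whose total gene counts span ≥3 orders of magnitude trigger a
  warning (not an error): depth normalization cannot fully rescue
  comparability at extreme imbalance.

## Problem sizes in the test suite

The suite and the acceptance script size their simulations for laptop-scale
runs, as ordinary design choices: 50 random matrices for the PCA oracle,
10⁴ held-out points for ellipse coverage, 1000 null replicates (n=10 per
group) for t-test calibration, and 100 default cohorts (42 samples × 58
families each) for end-to-end recovery. The whole suite runs in well under
a minute.

## Known limitations

- The bundled catalog's member lists are representative placeholders;
  results on real data are only as good as the curated catalog supplied.
- Ellipse calls are a geometric screening rule, not a significance test of
  group separation (no PERMANOVA or similar is performed).
- The method assumes comparable annotation pipelines across samples;
  mixing databases or database versions shifts scores in ways the
  normalization cannot remove.
- With fewer samples than categories the trailing components are null
  directions; only the leading, well-separated components are
  interpretable (the package computes all of them but the analyses use
  the first two).
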