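# Methods

This note documents the models, parameter choices and numerical conventions
behind `comodmap`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Ortholog expansion

An ortholog table holds scored (human_gene, fly_gene) pairs; scores are
integer orthology-support votes (DIOPT-style, higher = stronger support).
Records with score ≥ `min_score` (default 3, inclusive) survive filtering.
Expansion then proceeds per human gene:

* a single fly partner is kept as is — category `one_to_one`, promoted to
  `many_to_one` when that fly gene also serves other human genes;
* several partners: all with score ≥ (best score − `tie_window`) are kept,
  category `one_to_many`. "High and similar scores" is not a formal rule in
  the field, so the tie window is an explicit parameter; the default of 1
  score point reproduces the published catalog arithmetic
  (163 + 17 + 107 = 287 fly genes from the published composition).

When different human genes imply different categories for the same fly
gene, all source paths are recorded, the first assignment (in input record
order) provides the label, and the conflict is logged. Catalog order is
first appearance in the input, which makes the expansion deterministic and
order-auditable; permuting input records changes only that ordering.

Human genes whose best score falls below the threshold contribute nothing —
which is why a 320-gene human list can shrink to fewer contributing genes
while still expanding past it through one-to-many fan-out.

## Expression filtering and cell selection

The count matrix is taken as given — raw or normalized, the pipeline never
renormalizes, and the total-count filter operates on whatever the values
are. This is deliberate and worth stating loudly: a Spearman statistic is
invariant to per-gene monotone transforms but *not* to per-cell depth
normalization, so whether the input was depth-normalized is part of the
data provenance, not of this package's behavior.

The gene filter keeps candidates whose total count across cells meets
`min_total_counts` (default 5000). The threshold is inclusive (≥) by
default with an exclusive (>) flag, since both conventions are defensible
readings of "a minimum of 5000"; the choice moves only genes sitting
exactly on the boundary. By default the filter runs on the full dataset
before cell-type subsetting, so the retained gene list is independent of
the neuronal selection; a `selected_cells` scope is available.

Cell-type selection is by exact, case-sensitive label match, include- or
exclude-list. The 45 neuronal labels used for the fly-brain analysis ship
as a package asset (`data/neuronal_cell_types.txt`). Labels absent from
the data warn rather than fail, because atlas label vocabularies drift
between releases; an empty selection is an error.

## Co-expression and module extraction

Counts are log2(x + 1)-transformed (immaterial for ranks, retained as the
conventional preprocessing), then pairwise Spearman r_s is computed across
cells with average ranks for ties — the standard treatment, and an
important one here since zeros dominate sparse single-cell counts and tie
handling is where naive implementations diverge. Genes with constant
expression have undefined correlations; they are reported and must be
dropped before clustering.

Genes are agglomerated on d = 1 − r_s. The linkage default is complete
(the default of the R `hclust` environment in which this style of analysis
is usually run), with average and single available. The implementation is
scipy's linkage; the test suite checks its merge heights against an
independent O(n³) agglomeration oracle. At exactly tied merge heights
scipy's internal deterministic order decides; exact ties arise essentially
only for duplicated genes, where all candidate merges have identical
heights and the dendrogram is height-equivalent whichever is chosen.

The published analysis identified its module by visual inspection of a
heatmap. That step is replaced by explicit parameters: a dendrogram cut
(height or cluster count), a minimum module size (default 10) and a
minimum mean intra-module r_s (default 0.3). The defaults bracket the
published module (26 genes, r_s 0.36–0.84): a cut height of 1.0 on 1 − r
separates positively-correlated blocks from the uncorrelated background,
and the 0.3 floor rejects the background itself. Qualifying clusters are
returned sorted by mean intra-correlation with their min/mean/max r_s, so
"module 1" is always the tightest block. Exact membership of the real
26-gene module is not reproducible without the original atlas; what the
package promises — and tests — is recovery of planted modules of that size
and correlation strength.

## Enrichment statistics

All three enrichment operations reduce to the hypergeometric upper tail
P(X ≥ k) including the observed k — the over-representation convention.
This choice is pinned by the published worked example: N=320, K=53, n=26,
k=13 gives 3.45×10⁻⁵ only with the inclusive upper tail. The
implementation delegates to `scipy.stats.hypergeom.sf`, which computes in
log space; tests verify exact agreement with integer-combinatorics
enumeration for all populations up to N=20.

Fold enrichment is (k/n)/(K/N). Published per-term folds from web ORA
services depend on their annotation universes and are not reproduction
targets; the formula is the package's fixed convention. BH FDR is applied
across all terms of one collection per run (no cross-collection pooling),
via statsmodels. The ORA background defaults to the collection universe
and is overridable.

The term-overlap test treats terms as genes: two enriched-term lists of
sizes a and b sharing m terms out of a universe of U annotatable terms give
P(X ≥ m) for X ~ Hypergeometric(U, a, b). The test suite checks this is
literally the category-enrichment computation under relabeling.

The disease vocabulary is closed — `epilepsy`, `epilepsy_related`, `none` —
and case-sensitive, so classification tables fail loudly rather than
silently mis-binning. Percentages are reported integer-rounded (53/320 →
17%), matching how such tables are printed.

## Seizure-assay fitting

The heat-assay model is the four-parameter logistic in log10 time
("variable slope" in dose-response software), with time as dose:

    f(t) = bottom + (top − bottom) / (1 + 10^((log10 T50 − log10 t) · h))

* `bottom` is fixed at 0 — no fly has seized at t → 0.
* `top` is free in (0, 1] by default because not every fly seizes within
  the 80-minute window; it can be fixed (e.g. at 1).
* h is the Hill slope; T50 (= 10^logEC50) is the time at which the curve
  reaches half of (bottom + top).

Fitting is trust-region least squares on the pooled per-vial fractions of
one genotype (all vials contribute all timepoints as data points).
Initialization is deterministic — T50 from the first crossing of
half-maximum by linear interpolation on the time-averaged curve, slope 1 —
so fits are reproducible without any random state. A fit is `converged`
only if the optimizer succeeded and the residual sum of squares does not
exceed that of the best flat line; it is `extrapolated` when the pooled
fraction never reaches 0.5, in which case T50 lies beyond the data and
should be interpreted accordingly. All-zero and constant-saturated
responses are rejected as degenerate rather than fitted.

Because absolute seizure latency drifts day to day, genotypes are compared
as T50 ratios against a same-day background control; the ratio is
dimensionless and invariant to rescaling the time axis.

At the published assay scale (≈12 vials × 5 flies), the pooled-fraction
least-squares estimator has a sampling sd of about 7–8% of T50: the median
over replicates recovers the truth within a couple of percent, but
individual replicates commonly deviate by 10–15%. Unweighted least squares
is used deliberately — it is what the field's standard curve-fitting
software does — rather than a binomial MLE, which would be somewhat more
efficient but would not match the analysis being emulated.

The mechanical (bang-sensitivity) assay is summarized as per-vial seized
fractions grouped by genotype; downstream rank tests are standard routines
left to the user.

## Synthetic-data generator

The generator's job is to produce inputs whose ground truth is known, at
the statistical scale of the real analysis (hundreds of genes, thousands
of cells, modules of ~26 genes with intra-module r_s in the 0.3–0.85
range).

Counts are gamma-Poisson (negative binomial) with shared dispersion
(default 2; dispersion → ∞ reaches the Poisson limit). Per-gene baseline
means are uniform on log2 in (0, 4). Cells belong to one of `n_cell_types`
types (default 10); each type shifts each gene's mean by a mild lognormal
factor (sd 0.1 on the natural-log scale). A per-cell depth factor with CV
0.1 multiplies all genes.

A planted module's genes share a per-cell latent factor f ~ lognormal(0, 1):
member means are baseline × f^loading. The loading tunes intra-module rank
correlation continuously; loading 1 with the default count law lands the
pairwise r_s around 0.35–0.6, inside the band observed in real fly-brain
modules.

Two generator realism limits matter for interpreting green tests:

* Depth variation and type structure are kept mild (CV 0.1, type-sd 0.1)
  because both are *global* correlates: since the pipeline never
  normalizes, strong depth variation would correlate all gene pairs and no
  clean null would exist. Real atlases have stronger depth variation —
  and are depth-normalized upstream before such an analysis. Passing the
  null-calibration tests therefore shows the statistics behave at nominal
  rates on depth-mild data, not that the pipeline is robust to
  unnormalized deep/shallow cell mixtures.
* No doublets, ambient RNA, batch effects or marker-gene structure are
  simulated; module recovery results quantify the clustering machinery,
  not robustness to those artifacts.

Ortholog tables realize exact compositions: many-to-one groups spread
humans over shared fly genes (every fly gene ≥ 2 humans), one-to-many
groups give each human ≥ 2 fly partners scored within 1 of the group's
best, so the default tie window keeps them all. Gene-set collections embed
planted terms whose target-gene content interpolates linearly between the
random expectation (excess 0) and purity (excess 1). Seizure time courses
draw each interval's newly-seized count binomially from the conditional
hazard of the logistic CDF, which makes cumulative counts monotone by
construction and the marginal seize-by-t probability exactly the curve.

All generators take explicit seeds and touch no global random state;
identical seeds give bit-identical outputs.

## Numerical conventions and degenerate inputs

* Correlation matrices are symmetrized to 1e−12, diagonal set to exactly 1,
  values clipped to [−1, 1].
* Agglomeration heights are compared to oracles at 1e−12.
* Sigmoid optimization runs with xtol = ftol = gtol = 1e−14; noiseless
  model data are recovered to better than 1e−6 in T50.
* Hypergeometric queries validate 0 ≤ k ≤ min(n, K), n ≤ N, K ≤ N before
  computing; K = 0 yields fold undefined (reported missing) with p = 1
  when k = 0.
* Empty module extraction results warn; empty cell selections and empty
  ORA queries raise.

## Problem sizes

The test suite exercises module recovery at 200 genes × 2000 cells (10
planted and 100 null replicates), T50 recovery over 200 seeded assay
replicates of 12 vials × 5 flies, and oracle equivalences at n ≤ 20
(hypergeometric), 20 × 200 (Spearman) and 15 genes (linkage). These sizes
were chosen as the smallest at which the statistical claims are sharp: the
planted-module band is well-separated from the null at 2000 cells, and the
T50 median stabilizes within a couple of percent by 200 replicates.
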