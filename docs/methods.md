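# Methods

This note documents the models and procedures `sigmap` implements, the
parameters that matter, the numerical conventions chosen where several are
defensible, what the synthetic-data generator does and does not emulate, and
the known limits of the approach.

## Data model

A *compendium* is a genes × samples matrix of log2 expression intensities
with per-sample annotations (dataset, cell type, species, replicate index).
Matrices are strictly genes-in-rows; a transposed input fails validation
rather than being auto-fixed, because silent transposition is the classic
compendium bug. Missing values are rejected, not imputed — the intended
inputs are already-summarized per-dataset intensity matrices, which are
complete by construction. *Classes* are cell types (pooling datasets) or
explicit (dataset, cell type) pairs.

## Preprocessing

**Noise floor.** Microarray intensities below the background level carry no
signal but produce wild log-ratios. Linear intensities are floored at a
threshold (default 5, in linear units, an estimate of the noise level from
the density of array signals) and then log2-transformed, so the output
minimum is log2(threshold). The operation refuses log2-scale input — a
double transform is unrecoverable downstream.

**Merging.** Datasets of one species are merged on the exact intersection of
feature identifiers. Merging checks that at least one cell type is present
in every dataset (an *anchor* population); without an anchor, the later
dataset-effect correction has no population in which "no biological
difference" is a plausible assumption, so its absence is loudly warned but
not fatal (the caller may have external reasons to proceed).

**Quantile cross-normalization.** Every sample column is forced onto the
reference distribution formed by the per-rank mean of the sorted columns.
Tie handling is configurable:

- `ordinal` (default): tied values receive consecutive reference values in
  stable input order. Every output column's multiset then equals the
  reference *exactly*, which is the defining contract of quantile
  normalization and the property the test suite verifies to machine
  precision.
- `average`: tied values all receive the mean of the reference values over
  their tied rank span (the classic microarray-stack convention). Under
  ties this sacrifices exact distribution identity between columns.

The ordinal default was chosen because the exact-identity contract is the
one downstream steps rely on; the averaged variant is provided for
compatibility with the older convention.

**Dataset-effect removal.** An additive dataset-constant expression shift
across D datasets occupies a (D−1)-dimensional subspace of the gene-centered
sample space and, when its magnitude dominates biological variation, the
leading principal components. The correction computes the SVD of the
gene-centered matrix (genes as variables, **no** unit-variance scaling —
scaling would misrepresent the relative importance of genes by equalizing
their variance) and subtracts the reconstruction of the selected components,
restoring gene means afterwards. Negative corrected values are retained; they
are an expected artifact of the subtraction, not an error. Component choice
is a configuration input, not auto-detected: the right number is a judgment
about the compendium's design (typically D−1 for D datasets — one component
for two datasets, two for three), and automating it would hide that
judgment. Removed variance fractions are logged in the result metadata.

Note on idempotence: subtract-and-recompute PC removal is idempotent only
when the removed components capture the entire centered structure (e.g. an
exact planted batch shift). On generic data a second application would
remove what was previously the next component; callers should apply the
correction once with the full set of intended components.

**Probe collapse and ortholog merge.** Probe-level rows collapse to genes
either by keeping the probe with the largest mean (default; deterministic
and variance-preserving for the dominant probe) or by per-sample medians.
Cross-species matrices are joined only through one-to-one ortholog pairs
(rows indexed `geneA|geneB`); one-to-many relationships are dropped at table
load, with counts reported.

## Exploration

PCA is the same gene-centered unscaled decomposition used for correction,
with a deterministic sign convention (each loading column's
largest-magnitude entry is positive) and explained-variance fractions per
component. Top-contributor selection takes the top `quantile` fraction of
genes by squared loading (default 1%), ties broken by gene id; lists from
different components can be intersected to separate dataset-effect genes
from biology-bearing genes.

Hierarchical clustering uses 1 − Pearson(r) distance between sample columns
(range [0, 2]) with Ward or average linkage. Ward is applied to the
correlation-derived distances directly (the Lance–Williams Ward update on
the given matrix, Ward.D style). These distances are not Euclidean, so this
is a declared convention — chosen to match the behavior of the classic
clustering stacks this mirrors — and is recorded in the dendrogram object.
Columns are processed in lexicographic sample-id order so merge ties break
deterministically. Running several distance/linkage settings and comparing
trees is the intended usage; a single tree overstates certainty.

## Signature derivation (minimal pairwise mean)

For a signature with test classes T and reference classes R:

- Class means are arithmetic means on the **linear** scale (2^x back-
  transform): the fold-change threshold is specified in linear units, and
  the arithmetic-vs-geometric distinction matters (log2 replicates [2, 4]
  average to 10, not 8).
- Per gene, `min_pairwise_fc = min over (t, r) in T×R of mean_t / mean_r`:
  the worst pair governs, so a signature gene beats *every* reference class.
- Significance: one-sided Welch t-test (test > reference) on log2 values per
  class pair, per-gene p = max over pairs (the same worst-pair logic),
  Benjamini–Hochberg across genes. The underlying tool family reports only
  "an FDR filter" without naming the test; this choice is a declared,
  conservative stand-in, congruent with the min-pairwise construction, and
  is flagged in the signature provenance. Classes with a single replicate
  cannot support the test; a fold-change-only mode sets q = 0 with a loud
  warning instead.
- Filters are inclusive (FC ≥ 1.5, q ≤ 0.01 at the defaults): a "minimal
  fold change of 1.5" reads naturally as an attained minimum.

Raising the FC threshold or lowering the FDR ceiling can only shrink a
signature (monotone filtering; tested). Signatures are derived within one
species only; cross-species questions go through ortholog mapping plus
enrichment, never direct gene-name matching.

## Enrichment testing

**Ranking.** Genes are ordered by the difference of class means on the log2
scale (a log fold change). Ties break lexicographically by gene id.

**Running sum.** With weight exponent p (default 1, the classic weighted
form), set members at rank i increment the walk by |score_i|^p normalized by
the total in-set weight; non-members decrement by 1/(N − N_hit). The walk
starts and ends at zero; ES is the extremum with the larger magnitude,
positive preferred on ties (ties within 1e-12 — summation round-off — also
resolve positive, so the scalar and vectorized evaluators agree bit-for-bit
with an independent sequential enumeration). If every in-set weight is zero,
hits fall back to equal steps. The leading edge is the set members at or
before the positive extremum (at or after, for negative ES).

**Null distribution.** "Geneset-based permutation": n_perm random gene sets
of the same size as the (post-intersection) test set, drawn uniformly
without replacement from the ranked universe. Sample-label permutation is
deliberately absent — with 2–3 replicates per class there are too few label
permutations to resolve small p-values. Genes of a signature missing from
the universe are dropped with a logged count and the null is size-matched to
what remains.

**NES and p.** NES = ES / mean(|null ES of the same sign|), so NES ≈ 1 means
"no enrichment" and values around 3–5 are very strong. The nominal p is
(1 + #{same-sign null at least as extreme}) / (1 + #same-sign null) — the +1
pseudocount keeps p > 0 at any permutation count.

## Bubble-map grids

`BubbleMap(compendium, sets).fit(seed)` evaluates every gene set against
every unordered pair of classes (lexicographic order and orientation) and
applies Benjamini–Yekutieli across **all** cells of the grid jointly
(default; a per-row mode exists). BY is chosen over BH because the grid's
cells are heavily dependent — the same samples and overlapping gene sets
enter many cells — and BY controls FDR under arbitrary dependence; it is
strictly more conservative than BH (tested per grid). Per-cell RNG seeds are
derived by hashing (global seed, set name, class pair), so results are
independent of evaluation order and of which other sets/classes are present,
and full reruns with one global seed reproduce grids byte-identically.

Significance for rendering and recovery scoring is |NES| > 1 **and**
q < 0.25. Bubble area is proportional to |NES|, clipped at 5 (the practical
upper range of NES; beyond it, area saturates rather than rescaling the
whole map), hue encodes the enriched side, and opacity grows with
−log10(q), capped at q = 1e-4.

## Reporting

Replicate collapsing uses the median (midpoint for even counts) per cell
type or per (dataset, cell type). Heatmaps use a single global color scale
over the whole displayed matrix and never center or z-score rows: per-gene
rescaling misrepresents the relative importance of genes and hides the case
where a gene varies in one species only. Requested genes missing from the
matrix are warned about and omitted, never silently dropped.

## Synthetic compendia and what passing tests mean

The generator writes log2 values as
`baseline(g) + effect·1[g marker of sample's type] + batch(dataset, g) + noise`,
with Gaussian noise on the log2 scale (the standard desk model for array
intensities), dataset-constant gene-wise batch vectors, and homologous cell
types sharing marker identity through the one-to-one ortholog map. Defaults
— 2000 genes, six MP-like subsets (cDC1, cDC2, pDC, LC, Mono, Mac), three
datasets in the first species and two in the second (the asymmetry typical
of public MP compendia; signatures are derived in the richer species),
3 replicates per type per dataset, 50 markers per type at +2 log2, noise SD
0.5, batch SD 2.5 (5× noise, so the dataset effect dominates the leading
PCs), ortholog fraction 0.7 — are the study conditions under which the
acceptance checks run; they keep the full suite within minutes on one CPU.

The generator's additive batch structure is exactly what PC subtraction can
remove; real batch effects are messier. A `nonlinear_batch` switch (per-
dataset gene rescaling) exists precisely to demonstrate that PC removal does
*not* fix such structure (tested). Likewise the generator has no probe-level
physics, no intensity-dependent variance, no dropout/count behavior, and
marker programs are disjoint across types — so passing recovery tests shows
the pipeline's logic is sound under its stated model, not that real
compendia will behave this well. Conclusions on real data still require the
anchor-population checks and multi-method corroboration (PCA, clustering,
enrichment) the package is built around.

## Numerical conventions, in one place

- Quantile-normalization ties: ordinal by default (exact distribution
  identity); averaged variant available.
- PC removal: 1-based component indices validated against
  min(n_genes, n_samples − 1); numerically null components subtract as ~0.
- ES extremum ties (within 1e-12): positive side wins.
- Nominal p and q are never 0 (+1 pseudocount; BY caps at 1).
- Enrichment direction of a cell: the lexicographically first class when
  ES ≥ 0, else the second.
- Collapse rule ties (max_mean): lexicographically smallest probe id.
- All stochastic steps consume a `numpy` Generator seeded from explicit
  integers; grid cells derive seeds from a SHA-256 hash of their identity.
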