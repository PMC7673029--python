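# Methods

This note documents the models, defaults and numerical choices behind
`olspatial`, what the synthetic generators do and do not emulate, and the
known limitations.

## ISS decoding

Each spot carries an L x 4 intensity matrix (cycles x channels; fixed
base order A, C, G, T). Base calling is per-cycle argmax with ties broken
to the lowest channel index — deterministic and documented, since a tie
carries no information anyway. The per-cycle quality is max/sum of the
channel intensities, so it lives in [0.25, 1] whenever the cycle has
signal and equals 1 exactly for a one-hot cycle; an all-zero cycle gets
quality 0 (no signal, no call). The per-spot quality is the **minimum**
over cycles: a barcode is only as reliable as its worst cycle, and one
ambiguous cycle is enough to mis-assign the whole spot. The default
threshold `q_min = 0.5` is the midpoint between the uninformative floor
(0.25) and a perfect call (1); it is configurable, and thresholding can
be reasoned about per spot because Q is the min of the per-cycle values.
No crosstalk unmixing is applied before calling — decoding operates on
the intensities as given.

## Segmentation and spot assignment

Nuclei segmentation is the canonical watershed recipe for blob-like
nuclei: Otsu foreground (parameter-free), seeds at local maxima of the
Euclidean distance transform with a minimum separation on the order of
the nucleus radius (default 7 px for simulated radii 6–9 px), watershed
on the negative distance transform restricted to the foreground.

Label expansion grows each nucleus into its cell territory by a Euclidean
radius (default 10 px, about one cell body at the simulated scale; the
radius used is always a logged parameter). Expansion is implemented with
an exact tie rule — a background pixel equidistant (tolerance 1e-9 px)
from two labels takes the lower label id — via a KD-tree over labelled
pixels, with re-query of the rare >=3-way ties. Nucleus pixels are never
overwritten, which makes territories monotone in the radius.

Spots are assigned by the territory label at their rounded pixel
(pixel-center convention, 0-based, x = column). Only `assigned`-status
spots are counted; spots on background go to a per-gene unassigned tally
so that counts are conserved exactly. A cell's region is the strip
containing its **nucleus** centroid (matching how ROIs are drawn over
nuclei); when only territories are available the territory centroid is
the fallback.

## Cell typing

Puncta mode implements molecule cutoffs of 12 / 4 / 3 / 7 for Ptgds
(MOL5/6), Klk6 (MOL2), Egr2 (MOL1) and Ptprz1 (OPC/COP) on Sox10+ cells;
boundaries are inclusive (count = cutoff flags the cell). ISS mode gates
lineage on Sox10 and Plp1 both at >= t decoded reads (default t = 1, the
weakest defensible positivity for targeted ISS counts; configurable) and
requires a full marker pair for a population flag — triple/quadruple
co-expression — because single-gene positivity at 1 read is noise-prone.
OPC/COP drops the Plp1 requirement (Plp1 signal also appears outside
segmented somata, and progenitors express little of it).

Population flags are deliberately **non-exclusive**: each population's
percentage is an independent quantity over the lineage denominator, so a
cell high in two markers contributes to both. Denominator modes: lineage
(Sox10+), all nuclei, Aspa+ mature oligodendrocytes (conditional-knockout
quantification), and reporter+ lineage (fate mapping; the reporter is a
boolean column supplied with the cell table, never inferred from
intensities).

## Composition statistics

Cluster frequencies are column-normalized to percentages per sample
(columns sum to 100); condition differences are reported in absolute
percentage points. Hypothesis tests run on per-animal percentages — the
experimental unit is the animal, not the cell. The two-way ANOVA uses
Type-II sums of squares, appropriate for the unbalanced 3–9
animals-per-cell designs this kind of quantification produces when
interaction is not the primary question. Pairwise contrasts use the
pooled residual variance (t on the residual df) and Sidak correction
p' = 1 - (1-p)^m, with the comparison family m always explicit
configuration — by default all within-level contrasts of the second
factor.

## Moran's-I manifold filtering

Spatial proximity between cells is taken from a 3D embedding: a kNN graph
(default k = 15), symmetrized by union (elementwise max), row-
standardized; distance ties break to the lower cell index so the graph is
a pure function of the coordinates. Moran's I uses the standard
cross-product form with S0 the total weight; the sparse evaluation is
tested to 1e-10 against the dense double sum. Significance is one-sided
(positive autocorrelation) by uniform permutation of the gene's values
over cells with the add-one estimator, so p is never 0 and never below
1/(nperm+1). Defaults alpha = 0.01, nperm = 999, max_rounds = 30.
Between rounds the graph can be recomputed from the retained gene
submatrix via a pluggable re-embed hook; the default keeps the graph
fixed, which makes retained sets nested and convergence well-defined —
re-embedding per round reproduces the exploratory behavior of running the
procedure to a data-dependent fixed point. Expression is normalized to
10,000 counts per cell and log1p-transformed before testing. Subclustering
is Ward agglomerative clustering on genes standardized to zero mean and
unit variance (constant genes left at zero); the number of clusters is a
user choice.

## Differential expression

Counts are normalized per cell to 10,000 and log1p-transformed before any
fold change or rank test; LFC = log2((mean_A + 1)/(mean_B + 1)) on that
scale (pseudocount 1 keeps low-expression LFCs bounded and the statistic
antisymmetric). The Wilcoxon rank-sum test enumerates the exact
permutation distribution (midranks for ties) when the combined group size
is <= 10 — the exact two-sided p is 2*min(P(W <= w), P(W >= w)) capped at
1, since tied data need not give a symmetric null — and otherwise uses
the tie-corrected normal approximation with continuity correction. The
approximation tracks exact enumeration within 0.05 once the combined n
reaches 6; at 2x2 / 2x3 the discrete null admits so few p values (three
at 2x2) that no continuous approximation can do better than ~0.09, which
is why production always enumerates at those sizes. Test units are cells
by default; a per-sample-average mode (rank samples' mean expression) is
provided because both readings of "Wilcoxon on cluster expression" exist
and the choice materially changes power. FDR control is
Benjamini–Hochberg with significance at q < 0.01.

The 2D volcano joins two comparisons on their shared genes and annotates
each gene with the **lower** of its two raw p values (q values reported
alongside); genes missing from either comparison are excluded and logged.
Pathway points are unweighted means of member-gene LFCs over genes
present in the table. Marker finding is one-vs-rest per-cell Wilcoxon
with BH-FDR per cluster, an LFC >= 0.25 cutoff, and top-20 ranking by the
enrichment z score (cluster mean - global mean) / global SD of
normalized expression — the simplest z consistent with "most enriched".

QC keeps cells with min_genes <= detected genes <= max_genes and mito
fraction strictly < max_mito; presets `corpus_callosum` (200, 3000, 5%)
and `spinal_cord` (500, 7000, 10%). The report attributes each removed
cell to its first failing criterion in the order min_genes, max_genes,
mito, so kept + removed = input exactly.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (config, seed) — every stream is
seeded and tagged, so adding one generator's output never perturbs
another's.

* **Tissue**: nuclei are disks with radii uniform in 6–9 px, placed by
  dart throwing with pairwise center distance > 2 r_max + 22 px (the
  margin covers the 10 px expansion twice over, making spot-to-cell
  ground truth unambiguous); placement failure raises after a bounded
  retry budget. Regions are vertical strips; population labels are drawn
  per region from configured proportions. The default field plants the
  study's qualitative structure: WM 30% MOL2 / 30% MOL5/6 / 40% MOL1,
  GM 5% / 60% / 35%.
* **ISS spots**: per cell and gene, Poisson (optionally NB) spot counts
  with population-specific means; spots uniform inside the nucleus disk;
  intensities one-hot on the barcode channel (amplitude 100) plus a
  crosstalk fraction on off-channels plus additive Gaussian noise
  truncated at 0 — the simplest model that degrades the quality score
  smoothly. Background spots draw barcodes uniformly from all 4^4
  sequences (mostly outside the book, emulating off-target products).
  No optics: no PSF, no cycle misregistration, no tile seams. Passing
  decoding tests therefore demonstrates the decoding logic, not
  robustness to registration artifacts.
* **Puncta**: negative-binomial marker counts (dispersion 8) with each
  population's own marker 3x above its cutoff and other markers 3x
  below. At the low cutoffs this model has an irreducible ~8–9%
  false-positive rate (P(NB(mean 1) >= 3)), which is why typing quality
  is stated as per-population recall plus a separate false-flag bound
  rather than a single accuracy.
* **Expression matrices**: per-gene lognormal base means; planted
  condition-DE genes (log2 FC 1.0 by default, balanced half up / half
  down so library sizes stay comparable between conditions — the implicit
  assumption of per-cell normalization — and planted only on genes with
  base mean >= 2, because a fold change on a nearly-undetected gene is
  statistically unidentifiable); planted spatial genes whose log2 rate is
  a standardized linear field over the 3D cluster-blob embedding scaled
  by the autocorrelation strength (1.5 by default); planted cluster
  markers; mito-fraction outliers (5% of cells at 12–40% against a
  Beta(2,78) background) and low/high library-size cells. Cluster markers
  are genuinely spatially autocorrelated on the embedding (clusters are
  blobs there), so Moran-filter specificity is evaluated against matrices
  generated without markers. No transcriptome-scale correlation
  structure, batch effects or ambient RNA are simulated.

## Problem sizes

Simulations are sized so the full test suite and the acceptance script
each run in well under a minute of CPU: tissues of 50–400 nuclei on
512–2000 px fields, cohorts of 6 animals, expression matrices of 200–600
cells x 200–600 genes, 999 permutations for the Moran filter, 2,000
replicates for the ANOVA null calibration, 1,000 null genes for rank-sum
type-I error. These sizes put 3-standard-error recovery bounds in the
single-percentage-point range, tight enough to catch real defects.

## Known limitations

* The decoder assumes spots arrive as intensity tables; image-level spot
  detection, cycle registration and crosstalk unmixing are out of scope.
* Watershed seeding assumes roughly convex, blob-like nuclei; heavily
  overlapping or irregular nuclei will merge or oversplit.
* The composition ANOVA treats percentages as approximately normal
  per-animal observations; no compositional (log-ratio) transform or
  mixed-effects structure is offered.
* The Moran filter tests positive autocorrelation only; genes structured
  as high-frequency alternation over the graph (negative I) are never
  retained.
* Typing thresholds are hard cutoffs; no mixture-model or doublet-aware
  calling.
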