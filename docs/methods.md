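# Methods

## The QC problem and the ssHEG ambient-RNA estimate

A raw droplet DGE matrix contains far more barcodes than cells. Cell-free
("ambient") transcripts are co-encapsulated in every droplet and dominate
the empty ones; by construction the ambient pool is enriched for the genes
most highly expressed across the whole sample. `dropqc` therefore defines
the **sample-specific Highly-Expressed Genes (ssHEGs)** as the top *n*
genes by total counts across all droplets and reports, per droplet, the
percentage of detected genes (`ssheg_gene_pct`) and of counts
(`ssheg_count_pct`) falling in that set. Ambient-dominated droplets score
high on both while detecting few genes overall; droplets containing a cell
dilute the ambient pool with their own transcriptome.

Ties in total counts are broken lexicographically by gene symbol so the set
is reproducible across platforms. The default *n* is 64, an explicit
parameter. A data-driven coupling is also provided
(`compute_qc_table(..., n_sshegs="auto")`): *n* = the lower nGene threshold
round(10^(median − 2.5·MAD) of log10 nGene). That statistic is meaningful
on cell-dominated tables; on tables dominated by ambient barcodes (such as
the simulator's defaults) the log10 nGene distribution is bimodal and the
back-transformed floor collapses toward a handful of genes, so the fixed
default is preferred there.

All MAD computations use the normal-consistency constant 1.4826 (the
default of R's `mad()`), exposed as a parameter. The mito:ribo ratio uses a
pseudocount of 0.01 percentage points in numerator and denominator so
ribosome-free droplets stay finite. Percentages are on a 0–100 scale.

## Self-labeling and the droplet classifier

No ground-truth labels exist for droplet quality, so training labels come
from the unambiguous extremes of the nGene distribution: nGene < 100 →
`low_quality`; nGene between the median and median + 2.5·MAD →
`true_cell`; everything else unlabeled. By default the band center (median
and MAD) is computed over droplets **at or above** the 100-gene cutoff
(`LabelRule.center_scope="above_cutoff"`). On a raw matrix in which ambient
barcodes outnumber cells, the all-droplet median falls inside the
presumed-garbage region and the bands would overlap; restricting the center
to above-cutoff droplets keeps the true-cell band anchored on cell-like
droplets in both regimes, and on cell-dominated tables the two scopes
coincide. `center_scope="all"` restores the plain reading.

The classifier is a random forest (500 trees, √p candidate features per
split, no depth limit, majority-vote threshold 0.5) trained on a stratified
3:1 split of the labeled droplets. The default feature set is {nUMI,
percent mito, percent ribo, mito:ribo ratio, housekeeping %, ssheg_gene_pct,
ssheg_count_pct}; **nGene itself is excluded** because the labels are
nGene-defined — keeping it would leak the labeling rule into the learner
(the leakage check in the test suite verifies that shuffled labels yield
chance-level held-out performance). Feature importance is reported both as
mean impurity decrease (the primary ranking) and as permutation importance
on the test set.

Held-out sensitivity (recall of `true_cell`, "cell" being the positive
class) and specificity (recall of `low_quality`) describe fidelity to the
self-labeling rule, not to ground truth; on simulated data the simulator's
truth table provides the independent evaluation via `truth_confusion`.

## Threshold filters

All published cut-offs are strict inequalities; boundary values are
retained. The baseline filter removes droplets with nUMI > 15,000 or
< 200, nGene > 5,000 or < 100, or percent mito > 20. The doublet rule
removes droplets with nGene above median + 2.5·MAD and the dead-cell rule
droplets with percent mito above median + 2.5·MAD, both recomputed on the
post-classifier cell population (the default chain order is classifier →
doublets → mito; each stage can be disabled). The doublet rule uses nGene
only; nUMI appears on the diagnostic plot but carries no cut. These MADs
are computed on the linear scale by default, with a log10 option.

## Clustering evaluation

Embeddings follow standard single-cell practice via scanpy: library-size
normalisation to 10,000 counts, log1p, top 1,000 variable genes by
dispersion, per-gene standardisation, PCA (10 components, deterministic
seeded solver). Average silhouette width is computed in PC space with
Euclidean distance (tSNE is regarded as visualisation only); members of
singleton clusters contribute 0, the standard convention. The
implementation delegates to scikit-learn; the test suite checks it against
a brute-force O(n²) transcription of the definition to 1e-12.

Filter chains are compared by `compare_pipelines` (identical downstream
parameters per variant). For simulated data with known classes,
`silhouette_of_partition` scores how well the embedding separates the
**true cell types**: droplets belonging to no type (empty droplets,
doublets) are absorbed into the nearest class centroid, the way an actual
clustering would absorb them. Treating "empty" as a class of its own would
reward, not penalise, retained empties — they share one ambient profile and
form a tight cluster — which is the opposite of what a QC evaluation should
measure.

## Dissociation signature

`score_signature` reports the percentage of each droplet's counts in a
signature gene set. `de_upregulated` tests each gene between two droplet
groups with a two-sided Wilcoxon rank-sum test on log1p library-size-
normalised expression (Bonferroni adjustment over genes tested) and
reports an average log fold change log(mean_A + 1) − log(mean_B + 1) on the
normalised scale. The fold-change base defaults to the natural log (the
Seurat-era convention; `lfc_base="log10"` is available). The natural-log
default matters: with strict thresholds of the form "log FC > 1", a
base-10 reading admits only effects strictly above 10-fold, and a true
10-fold change sits exactly on — in fact, after compositional normalisation
and pseudocount shrinkage, strictly below — the boundary, so the base-10
scale turns the threshold into a knife edge for realistic effect sizes.

`refine_signature` computes (reference ∩ upregulated) \ cell-type markers
and reports the three-way Venn counts. Cell-type markers can be derived
with `derive_cluster_markers` (scanpy Wilcoxon one-vs-rest, Bonferroni
p < 0.05, natural-log FC > 0.25 — widespread single-cell defaults).
`pc_signature_correlation` reports Spearman ρ between the signature score
and each PC, flagging |ρ| ≥ 0.23 by default, and `filter_high_signature`
removes droplets above median + 2.5·MAD of the score. A reference
signature (e.g. the murine dissociation signature) is a required input
file for real data; tests use a synthetic stand-in built around the
simulator's planted stress genes.

## The simulator

The simulator emulates the composition of a raw droplet DGE, not the
biology of any tissue. Defaults define the study conditions used throughout
the tests: 2,000 genes (13 "MT-", 20 "RPS/RPL", 10 housekeeping, 20
markers × 3 cell types, 11 dissociation-stress genes named after
immediate-early/heat-shock symbols, the rest background); 3 × 300 cells,
1,500 empty droplets, 60 doublets, 60 dying cells.

* **Ambient pool**: one sample-level profile drawn from a sparse symmetric
  Dirichlet (concentration 0.01 per gene) so a handful of genes dominate,
  with an explicit housekeeping share (Beta mean 5% — ambient RNA stems
  from pooled cells) and mito/ribo shares drawn from the same Beta families
  as cells.
* **Empty droplets**: library sizes log-normal with median ≈ 3% of the
  cell median and σ = 1.4 — the broad "shoulder" of a barcode-rank plot.
  Counts are Dirichlet-multinomial: each droplet draws a private
  realisation of the ambient profile with total concentration log-normally
  distributed around 15 (σ = 1.0), then samples multinomially. This capture
  overdispersion keeps even large ambient barcodes low-complexity while
  letting nGene, nUMI and count shares overlap the cell range — the regime
  in which single hard thresholds fail and the classifier earns its keep.
  With per-droplet concentration → ∞ this reduces to plain multinomial
  sampling of the ambient profile.
* **Cells**: a per-type core profile (markers 25% of mass, housekeeping 5%,
  dissociation genes 0.05% each, background Dirichlet), mixed with a
  per-cell ambient fraction (Beta mean 10%), with mito (Beta mean 5%) and
  ribo (Beta mean 18%) shares reallocated per droplet; library sizes
  log-normal (median 3,500, σ = 0.55).
* **Dying cells**: identical except the mito share is redrawn from a Beta
  with mean 35%.
* **Doublets**: exact column sums of two cells from the same condition;
  parent barcodes are recorded so the conservation invariant is testable.
* **Dissociation effect**: cells carry a short/long condition label; in the
  long condition the stress-gene rates are multiplied by 10 and the profile
  renormalised.

Everything derives from one `numpy` Generator seeded by the config, so a
config+seed pair reproduces the matrix bit for bit.

What the simulator does **not** model: gene–gene co-expression structure,
UMI collisions, batch effects, or an ambient pool derived from the cell
profiles themselves (the ambient profile is an independent draw, apart from
its housekeeping/mito/ribo shares). Passing tests therefore demonstrate
that each procedure behaves as designed in a regime shaped like droplet
data — not that any particular real dataset will show the same effect
sizes or a 100% classifier fidelity.

## Numerical choices and degenerate inputs

* Ties in ssHEG totals: lexicographic; k-means seeded, `n_init=10`; PCA via
  seeded ARPACK.
* Zero-count droplets get zero percentages and a `no_counts` flag; they are
  rejected by the embedding step (they cannot be normalised).
* A constant metric in a group comparison yields a NaN ("degenerate") test
  with a warning rather than an error; constant classifier features warn
  and are retained.
* `estimate_ngene_floor` rounds half away from zero and floors at 1 gene;
  zero MAD back-transforms to the common value with a warning.
* Filter reports record the thresholds applied, so reapplying a recorded
  rule to its retained set (without recomputation) removes nothing.

## Problem sizes

Default test and acceptance runs use the 2,520-droplet × 2,000-gene
simulated dataset above; the DE analyses use 200 cells in one type
(~100 per condition) over 2,000 genes; oracle-equivalence checks use
20 × 50-droplet silhouette instances and 100 random MAD vectors. These
sizes were chosen so the whole suite completes in about a minute and a
half on a single CPU while leaving every comparison well-powered.
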