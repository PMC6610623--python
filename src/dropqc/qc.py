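"""Per-droplet QC metrics, including the ssHEG ambient-RNA estimate.

The ambient-RNA estimate rests on a simple observation: cell-free transcripts
in the suspension are dominated by the genes most highly expressed across the
whole sample, so empty or low-quality droplets are enriched for those genes
and detect few genes overall.  The sample-specific Highly-Expressed Genes
(ssHEGs) are the top *n* genes by total counts; per droplet we report the
percentage of detected genes (``ssheg_gene_pct``) and of counts
(``ssheg_count_pct``) that fall in this set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .types import CountMatrix, GeneSet

__all__ = [
    "MAD_CONSTANT",
    "default_housekeeping_set",
    "mito_gene_set",
    "ribo_gene_set",
    "compute_basic_metrics",
    "estimate_ngene_floor",
    "identify_sshegs",
    "compute_ssheg_metrics",
    "compute_qc_table",
    "MetricComparison",
    "compare_metric_groups",
    "compare_qc_metrics",
]

#: Consistency constant making the MAD an unbiased scale estimate under
#: normality (1 / Phi^-1(3/4)); the default of R's ``mad()``.
MAD_CONSTANT = 1.4826

#: Pseudocount keeping mito:ribo ratios finite for ribosome-free droplets.
RATIO_EPSILON = 0.01


def default_housekeeping_set() -> GeneSet:
    """The small canonical housekeeping panel shipped with the package."""
    text = resources.files("dropqc").joinpath("data/housekeeping.txt").read_text()
    genes = [t.strip() for t in text.splitlines() if t.strip() and not t.startswith("#")]
    return GeneSet("housekeeping", genes)


def mito_gene_set(matrix: CountMatrix, prefix: str = "MT-") -> GeneSet:
    """Mitochondrial genes by symbol prefix (human convention ``MT-``)."""
    return GeneSet("mito", [g for g in matrix.gene_ids if str(g).startswith(prefix)])


def ribo_gene_set(matrix: CountMatrix, prefixes: tuple[str, ...] = ("RPS", "RPL")) -> GeneSet:
    """Ribosomal-protein genes by symbol prefix (``RPS``/``RPL``)."""
    return GeneSet("ribo", [g for g in matrix.gene_ids if str(g).startswith(prefixes)])


def _pct_in_set(matrix: CountMatrix, genes: GeneSet, numi: np.ndarray) -> np.ndarray:
    idx = matrix.gene_indices(genes.genes)
    if idx.size == 0:
        return np.zeros(matrix.n_droplets)
    in_set = np.asarray(matrix.counts[idx, :].sum(axis=0)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(numi > 0, 100.0 * in_set / np.maximum(numi, 1), 0.0)
    return pct


def compute_basic_metrics(
    matrix: CountMatrix,
    mito: GeneSet | None = None,
    ribo: GeneSet | None = None,
    hk: GeneSet | None = None,
    ratio_epsilon: float = RATIO_EPSILON,
) -> pd.DataFrame:
    """Per-droplet nUMI, nGene and percentage metrics.

    Percentages are on a 0-100 scale and computed against nUMI.  Droplets with
    nUMI = 0 receive 0 for all percentages and are flagged in ``no_counts``.
    Gene sets default to symbol-prefix conventions (``MT-``, ``RPS``/``RPL``)
    and the shipped housekeeping panel; all three are overridable.
    """
    if matrix.n_droplets == 0 or matrix.n_genes == 0:
        raise ValueError("empty count matrix")
    mito = mito or mito_gene_set(matrix)
    ribo = ribo or ribo_gene_set(matrix)
    hk = hk or default_housekeeping_set()
    if not matrix.gene_indices(mito.genes).size:
        warnings.warn("no mitochondrial genes found in the matrix; percent_mito will be 0",
                      stacklevel=2)

    numi = matrix.umi_per_droplet()
    ngene = matrix.genes_per_droplet()
    pm = _pct_in_set(matrix, mito, numi)
    pr = _pct_in_set(matrix, ribo, numi)
    table = pd.DataFrame(
        {
            "barcode": matrix.barcodes,
            "nUMI": numi.astype(np.int64),
            "nGene": ngene.astype(np.int64),
            "percent_mito": pm,
            "percent_ribo": pr,
            "mito_ribo_ratio": (pm + ratio_epsilon) / (pr + ratio_epsilon),
            "percent_hk": _pct_in_set(matrix, hk, numi),
            "no_counts": numi == 0,
        }
    )
    return table


def estimate_ngene_floor(
    table: pd.DataFrame, k: float = 2.5, mad_constant: float = MAD_CONSTANT
) -> int:
    """Lower nGene threshold: ``round(10 ** (median - k * MAD))`` of log10(nGene).

    Droplets with nGene = 0 are excluded from the statistic; the result is
    rounded half away from zero and floored at 1 gene.  A zero MAD (all nGene
    equal) back-transforms to that common value, with a warning.
    """
    ngene = np.asarray(table["nGene"], dtype=float)
    ngene = ngene[ngene >= 1]
    if ngene.size < 3:
        raise ValueError("need at least 3 droplets with nGene >= 1")
    log_n = np.log10(ngene)
    med = float(np.median(log_n))
    mad = mad_constant * float(np.median(np.abs(log_n - med)))
    if mad == 0.0:
        warnings.warn("nGene MAD is zero; floor equals the common value", stacklevel=2)
    floor = 10.0 ** (med - k * mad)
    return max(1, int(math.floor(floor + 0.5)))


def identify_sshegs(matrix: CountMatrix, n: int) -> GeneSet:
    """The ``n`` genes with the largest total counts across all droplets.

    Ties in total counts are broken lexicographically by gene ID so the set is
    reproducible across runs and platforms.  ``n`` may not exceed the number
    of genes with nonzero totals.
    """
    totals = matrix.gene_totals()
    n_nonzero = int((totals > 0).sum())
    if not 1 <= n <= n_nonzero:
        raise ValueError(
            f"n={n} ssHEGs requested but the matrix has {n_nonzero} genes with nonzero counts"
        )
    order = sorted(range(matrix.n_genes), key=lambda i: (-totals[i], str(matrix.gene_ids[i])))
    top = [matrix.gene_ids[i] for i in order[:n]]
    return GeneSet(f"ssHEG_top{n}", top)


def compute_ssheg_metrics(
    matrix: CountMatrix, sshegs: GeneSet, table: pd.DataFrame
) -> pd.DataFrame:
    """Append ``ssheg_gene_pct`` / ``ssheg_count_pct`` to a QC table.

    ``ssheg_gene_pct`` = 100 * |detected genes in ssHEGs| / nGene;
    ``ssheg_count_pct`` = 100 * counts in ssHEGs / nUMI.  Droplets detecting
    nothing get 0 for both and keep their ``no_counts`` flag.
    """
    unknown = sshegs.genes - set(matrix.gene_ids)
    if unknown:
        raise ValueError(f"ssHEG genes absent from the matrix: {sorted(unknown)[:5]}")
    table = table.copy()
    idx = matrix.gene_indices(sshegs.genes)
    sub = matrix.counts[idx, :]
    detected_in_set = np.asarray(sub.getnnz(axis=0)).ravel()
    counts_in_set = np.asarray(sub.sum(axis=0)).ravel()
    ngene = np.asarray(table["nGene"], dtype=float)
    numi = np.asarray(table["nUMI"], dtype=float)
    table["ssheg_gene_pct"] = np.where(ngene > 0, 100.0 * detected_in_set / np.maximum(ngene, 1), 0.0)
    table["ssheg_count_pct"] = np.where(numi > 0, 100.0 * counts_in_set / np.maximum(numi, 1), 0.0)
    return table


def compute_qc_table(
    matrix: CountMatrix,
    n_sshegs: int | str = 64,
    mito: GeneSet | None = None,
    ribo: GeneSet | None = None,
    hk: GeneSet | None = None,
) -> pd.DataFrame:
    """Full QC table: basic metrics plus ssHEG metrics and empty class columns.

    ``n_sshegs`` is the ssHEG top-gene count (default 64); pass
    ``"auto"`` to couple it to :func:`estimate_ngene_floor`.
    """
    table = compute_basic_metrics(matrix, mito=mito, ribo=ribo, hk=hk)
    if n_sshegs == "auto":
        n_sshegs = estimate_ngene_floor(table)
    sshegs = identify_sshegs(matrix, int(n_sshegs))
    table = compute_ssheg_metrics(matrix, sshegs, table)
    table["label"] = "unlabeled"
    table["predicted_class"] = "unset"
    return table


# ---------------------------------------------------------------------------
# group comparison of metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricComparison:
    metric: str
    statistic: float
    p_value: float
    p_adjusted: float
    n_a: int
    n_b: int

    @property
    def degenerate(self) -> bool:
        return math.isnan(self.p_value)


def compare_metric_groups(
    table: pd.DataFrame,
    metric: str,
    group_a: str,
    group_b: str,
    n_comparisons: int = 1,
    label_column: str = "label",
) -> MetricComparison:
    """Two-sided Wilcoxon rank-sum test of one metric between two label groups.

    The adjusted p-value is Bonferroni: ``min(1, p * n_comparisons)`` where
    ``n_comparisons`` is the number of metrics tested in the batch.  A metric
    constant across both groups is degenerate (NaN p, with a warning).
    """
    a = table.loc[table[label_column] == group_a, metric].to_numpy(dtype=float)
    b = table.loc[table[label_column] == group_b, metric].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"groups must have >= 2 droplets (got {len(a)} {group_a!r}, {len(b)} {group_b!r})"
        )
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn(f"metric {metric!r} is constant in both groups; test degenerate",
                      stacklevel=2)
        return MetricComparison(metric, math.nan, math.nan, math.nan, len(a), len(b))
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return MetricComparison(metric, float(stat), float(p),
                            min(1.0, float(p) * n_comparisons), len(a), len(b))


def compare_qc_metrics(
    table: pd.DataFrame,
    metrics: tuple[str, ...],
    group_a: str = "low_quality",
    group_b: str = "true_cell",
    label_column: str = "label",
) -> pd.DataFrame:
    """Batch rank-sum tests with Bonferroni correction over ``len(metrics)``."""
    rows = [
        compare_metric_groups(table, m, group_a, group_b,
                              n_comparisons=len(metrics), label_column=label_column)
        for m in metrics
    ]
    return pd.DataFrame([r.__dict__ for r in rows])
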