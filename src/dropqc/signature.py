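"""Disaggregation-signature scoring, refinement and filtering.

Enzymatic tissue dissociation induces a stress-response expression program
(immediate-early genes, heat-shock proteins).  Cells are scored by the
percentage of their counts contributed by a signature gene set; a reference
signature (e.g. the murine dissociation signature) can be refined against a
specific dataset by intersecting it with the genes upregulated under long
versus short dissociation and removing cell-type markers, and cells with
outlying signature expression can be filtered with the usual 2.5-MAD rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterAssignment, Embedding
from .thresholds import FilterReport, mad_bounds
from .types import CountMatrix, GeneSet

__all__ = [
    "DEResult",
    "score_signature",
    "de_upregulated",
    "refine_signature",
    "derive_cluster_markers",
    "pc_signature_correlation",
    "filter_high_signature",
]


@dataclass(frozen=True)
class DEResult:
    gene: str
    avg_logfc: float
    p_value: float
    p_adjusted: float


def score_signature(matrix: CountMatrix, signature: GeneSet) -> pd.DataFrame:
    """Per-droplet percentage of counts in the signature genes (0-100).

    Signature genes absent from the matrix are ignored with a warning; an
    empty intersection is an error.  Droplets with zero counts score 0.
    """
    absent = sorted(signature.genes - set(matrix.gene_ids))
    idx = matrix.gene_indices(signature.genes)
    if idx.size == 0:
        raise ValueError(f"signature {signature.name!r} shares no genes with the matrix")
    if absent:
        warnings.warn(
            f"signature {signature.name!r}: {len(absent)} gene(s) absent from the matrix: "
            f"{absent[:5]}",
            stacklevel=2,
        )
    numi = matrix.umi_per_droplet().astype(float)
    in_sig = np.asarray(matrix.counts[idx, :].sum(axis=0)).ravel()
    pct = np.where(numi > 0, 100.0 * in_sig / np.maximum(numi, 1), 0.0)
    return pd.DataFrame({"barcode": matrix.barcodes, "percent_expression": pct})


def _normalized(matrix: CountMatrix, barcodes: Sequence[str], target_sum: float = 1e4):
    sub = matrix.subset_droplets(list(barcodes))
    numi = sub.umi_per_droplet().astype(float)
    if np.any(numi == 0):
        raise ValueError("cannot normalise droplets with zero counts")
    dense = sub.counts.toarray().astype(float)
    return dense / numi * target_sum  # genes x droplets


def de_upregulated(
    matrix: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    p_max: float = 0.001,
    lfc_min: float = 1.0,
    lfc_base: str = "ln",
    pseudocount: float = 1.0,
    target_sum: float = 1e4,
) -> list[DEResult]:
    """Genes upregulated in ``group_a`` versus ``group_b``.

    Per gene: a two-sided Wilcoxon rank-sum test on log1p library-size-
    normalised expression, Bonferroni-adjusted over the genes tested, and an
    average fold change ``log(mean_a + eps) - log(mean_b + eps)`` on the
    normalised scale.  Returns genes with raw p < ``p_max`` and
    ``avg_logfc > lfc_min``, sorted by fold change (descending).

    ``lfc_base`` is ``"ln"`` (natural log, the Seurat-era convention, default)
    or ``"log10"``; the base in use is recorded on the result list's
    ``attrs``-style summary returned alongside (see ``summary`` in the list's
    first element docstring).  Genes expressed in neither group are skipped
    and counted.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if not group_a or not group_b:
        raise ValueError("groups must be non-empty")
    if lfc_base not in ("ln", "log10"):
        raise ValueError(f"lfc_base must be 'ln' or 'log10', got {lfc_base!r}")
    log = np.log if lfc_base == "ln" else np.log10

    a = _normalized(matrix, group_a, target_sum)
    b = _normalized(matrix, group_b, target_sum)
    expressed = (a.sum(axis=1) > 0) | (b.sum(axis=1) > 0)
    n_skipped = int((~expressed).sum())
    if n_skipped:
        warnings.warn(f"{n_skipped} gene(s) expressed in neither group skipped", stacklevel=2)
    genes = matrix.gene_ids[expressed]
    la, lb = np.log1p(a[expressed]), np.log1p(b[expressed])
    with np.errstate(invalid="ignore"):
        _, p = stats.mannwhitneyu(la, lb, alternative="two-sided", axis=1)
    p = np.nan_to_num(np.asarray(p, dtype=float), nan=1.0)
    lfc = log(a[expressed].mean(axis=1) + pseudocount) - log(b[expressed].mean(axis=1) + pseudocount)
    m = int(expressed.sum())
    results = [
        DEResult(str(g), float(fc), float(pv), min(1.0, float(pv) * m))
        for g, fc, pv in zip(genes, lfc, p)
        if pv < p_max and fc > lfc_min
    ]
    return sorted(results, key=lambda r: -r.avg_logfc)


def refine_signature(
    reference_sig: GeneSet,
    upregulated: Sequence[DEResult] | GeneSet,
    cell_type_markers: GeneSet,
) -> tuple[GeneSet, dict[str, int]]:
    """Refined signature: (reference ∩ upregulated) minus cell-type markers.

    Returns the refined :class:`GeneSet` together with the three-way
    membership counts (a Venn summary).  An empty result is returned with a
    warning, not an error.
    """
    up = set(upregulated.genes) if isinstance(upregulated, GeneSet) else {
        r.gene for r in upregulated
    }
    if not len(reference_sig) or not up or not len(cell_type_markers):
        raise ValueError("reference, upregulated and marker sets must be non-empty")
    ref, markers = set(reference_sig.genes), set(cell_type_markers.genes)
    refined = (ref & up) - markers
    venn = {
        "reference": len(ref),
        "upregulated": len(up),
        "markers": len(markers),
        "reference&upregulated": len(ref & up),
        "reference&markers": len(ref & markers),
        "upregulated&markers": len(up & markers),
        "reference&upregulated&markers": len(ref & up & markers),
        "refined": len(refined),
    }
    if not refined:
        warnings.warn("refined signature is empty", stacklevel=2)
    return GeneSet("refined_signature", refined), venn


def derive_cluster_markers(
    matrix: CountMatrix,
    clusters: ClusterAssignment,
    p_adj_max: float = 0.05,
    lfc_min_ln: float = 0.25,
) -> GeneSet:
    """Union over clusters of one-vs-rest marker genes.

    Wilcoxon one-vs-rest per cluster on normalised log counts (via scanpy),
    Bonferroni-adjusted p < ``p_adj_max`` and natural-log fold change >
    ``lfc_min_ln`` — the widespread single-cell defaults.  Clusters of size 1
    are skipped with a warning; fewer than 2 usable clusters is an error.
    """
    import scanpy as sc

    if not np.array_equal(np.asarray(clusters.barcodes), np.asarray(matrix.barcodes)):
        raise ValueError("cluster assignment barcodes do not match the matrix")
    labels = pd.Series(clusters.cluster_id.astype(str), index=clusters.barcodes)
    sizes = labels.value_counts()
    singletons = sizes[sizes < 2].index.tolist()
    if singletons:
        warnings.warn(f"cluster(s) of size 1 skipped: {singletons}", stacklevel=2)
    usable = sizes[sizes >= 2].index.tolist()
    if len(usable) < 2:
        raise ValueError("marker derivation needs at least 2 clusters of size >= 2")

    adata = matrix.to_anndata()
    adata.obs["cluster"] = labels.values
    adata = adata[adata.obs["cluster"].isin(usable)].copy()
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.tl.rank_genes_groups(
            adata, "cluster", groups=usable, method="wilcoxon", corr_method="bonferroni"
        )
    lfc_min_log2 = lfc_min_ln / np.log(2)  # scanpy reports log2 fold changes
    markers: set[str] = set()
    for grp in usable:
        df = sc.get.rank_genes_groups_df(adata, group=grp)
        hits = df[(df["pvals_adj"] < p_adj_max) & (df["logfoldchanges"] > lfc_min_log2)]
        markers |= set(hits["names"])
    return GeneSet("cluster_markers", markers) if markers else GeneSet("cluster_markers", [])


def pc_signature_correlation(
    embedding: Embedding, scores: pd.DataFrame, rho_threshold: float = 0.23
) -> pd.DataFrame:
    """Spearman correlation of signature expression with each PC.

    Flags components whose |rho| reaches ``rho_threshold``; a PC/score pair
    with zero variance yields an undefined (NaN) rho, reported as such.
    """
    aligned = scores.set_index("barcode").loc[list(embedding.barcodes), "percent_expression"]
    values = aligned.to_numpy(dtype=float)
    rows = []
    for comp in range(embedding.n_components):
        pc = embedding.coordinates[:, comp]
        if np.all(values == values[0]) or np.all(pc == pc[0]):
            rho = np.nan
        else:
            rho = float(stats.spearmanr(pc, values).statistic)
        rows.append(
            {
                "component": comp + 1,
                "spearman_rho": rho,
                "flagged": bool(abs(rho) >= rho_threshold) if np.isfinite(rho) else False,
            }
        )
    return pd.DataFrame(rows)


def filter_high_signature(scores: pd.DataFrame, k: float = 2.5) -> FilterReport:
    """Remove droplets whose signature expression exceeds median + k*MAD."""
    if len(scores) < 3:
        raise ValueError("signature filtering needs at least 3 droplets")
    values = scores["percent_expression"].to_numpy(dtype=float)
    _, upper = mad_bounds(values, k=k)
    removed = values > upper
    barcodes = scores["barcode"].to_numpy()
    return FilterReport(
        "high_signature",
        len(barcodes),
        int(removed.sum()),
        int((~removed).sum()),
        {"percent_expression_upper": float(upper)},
        list(barcodes[removed]),
        list(barcodes[~removed]),
    )
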