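"""Synthetic droplet scRNA-seq datasets with ground-truth droplet classes.

The generator emulates the composition of a raw droplet DGE matrix:

* a sample-level **ambient profile** — a sparse Dirichlet draw in which a
  handful of genes dominate, standing in for the pooled cell-free RNA of the
  suspension;
* **empty droplets** sampling that profile across a broad (log-normal)
  library-size continuum, with per-droplet Dirichlet-multinomial capture
  overdispersion so that even large ambient barcodes stay low-complexity and
  no single library-size or count-share cut separates them cleanly;
* **cells** of several types, each type defined by a block of boosted marker
  genes over a flat background, contaminated by a per-cell ambient fraction,
  with mitochondrial and ribosomal count shares injected per droplet from
  Beta distributions;
* **dying cells** — ordinary cells whose mitochondrial share is redrawn from
  a high-mito Beta;
* **doublets** — exact column sums of two cells from the same condition;
* a **dissociation-stress program**: a small gene set whose rates are
  multiplied by ``dissociation_effect`` in cells of the "long" dissociation
  condition.

Everything is reproducible bit-for-bit from the config seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .types import CountMatrix, GeneSet

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate", "truth_confusion"]

# Immediate-early / heat-shock symbols typical of dissociation stress; used to
# name the planted dissociation genes when exactly 11 are requested.
_DISSOCIATION_SYMBOLS = (
    "FOS", "FOSB", "JUN", "JUNB", "JUND", "EGR1",
    "HSPA1A", "HSPA1B", "SOCS3", "ZFP36", "DUSP1",
)


@dataclass
class SimulationConfig:
    """Generative parameters; defaults emulate a small Drop-seq style run."""

    seed: int
    n_genes: int = 2000
    n_cell_types: int = 3
    cells_per_type: int = 300
    n_empty: int = 1500
    n_doublets: int = 60
    n_dying: int = 60

    # ambient pool
    ambient_concentration: float = 0.01       # per-gene Dirichlet conc. of the sample profile
    ambient_capture_concentration: float = 15.0  # per-droplet Dirichlet-multinomial mass
    ambient_capture_sigma: float = 1.0        # log-normal spread of the per-droplet mass
    ambient_fraction_beta: tuple[float, float] = (2.0, 18.0)  # contamination inside cells
    ambient_hk_beta: tuple[float, float] = (5.0, 95.0)  # housekeeping share of the ambient pool

    # library sizes (log-normal, natural-log parameters)
    empty_library_loc: float = math.log(105.0)   # ~3% of the cell median
    empty_library_sigma: float = 1.4
    cell_library_loc: float = math.log(3500.0)
    cell_library_sigma: float = 0.55

    # per-droplet count shares
    baseline_mito_beta: tuple[float, float] = (2.0, 38.0)   # mean 5%
    dying_mito_beta: tuple[float, float] = (14.0, 26.0)     # mean 35%
    ribo_beta: tuple[float, float] = (9.0, 41.0)            # mean 18%
    ambient_mito_beta: tuple[float, float] = (2.0, 38.0)
    ambient_ribo_beta: tuple[float, float] = (4.0, 36.0)

    # gene architecture
    n_mito_genes: int = 13
    n_ribo_genes: int = 20
    n_hk_genes: int = 10
    n_marker_genes_per_type: int = 20
    marker_profile_share: float = 0.25
    hk_profile_share: float = 0.05
    cell_profile_concentration: float = 1.5

    # dissociation-stress program
    dissociation_gene_count: int = 11
    dissociation_effect: float = 10.0
    dissociation_base_share: float = 5e-4    # per gene, per type profile
    long_condition_fraction: float = 0.5

    n_ambient_top: int = 64   # size of the recorded ambient-top planted set

    def validate(self) -> None:
        special = (
            self.n_mito_genes + self.n_ribo_genes + self.n_hk_genes
            + self.n_marker_genes_per_type * self.n_cell_types
            + self.dissociation_gene_count
        )
        if special >= self.n_genes:
            raise ValueError(
                f"special genes ({special}) must be fewer than n_genes ({self.n_genes})"
            )
        for name in ("n_cell_types", "cells_per_type", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("n_empty", "n_doublets", "n_dying"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_doublets and self.n_cell_types * self.cells_per_type < 2:
            raise ValueError("doublets need at least 2 cells")
        if not 0.0 <= self.long_condition_fraction <= 1.0:
            raise ValueError("long_condition_fraction must be in [0, 1]")
        if self.dissociation_effect <= 0:
            raise ValueError("dissociation_effect must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "SimulationConfig":
        cfg = SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in d.items()
        })
        cfg.validate()
        return cfg


@dataclass
class SimulatedDataset:
    matrix: CountMatrix
    truth: pd.DataFrame          # barcode, truth_class, cell_type, condition, parent_a/b
    planted_sets: dict[str, GeneSet]
    config: SimulationConfig


def _gene_names(cfg: SimulationConfig) -> tuple[list[str], dict[str, np.ndarray]]:
    n_bg = cfg.n_genes - (
        cfg.n_mito_genes + cfg.n_ribo_genes + cfg.n_hk_genes
        + cfg.n_marker_genes_per_type * cfg.n_cell_types + cfg.dissociation_gene_count
    )
    names: list[str] = [f"G{i + 1:04d}" for i in range(n_bg)]
    groups: dict[str, np.ndarray] = {"background": np.arange(n_bg)}
    for t in range(cfg.n_cell_types):
        start = len(names)
        names += [f"T{t + 1}M{j + 1:02d}" for j in range(cfg.n_marker_genes_per_type)]
        groups[f"markers_type{t + 1}"] = np.arange(start, len(names))
    start = len(names)
    if cfg.dissociation_gene_count == len(_DISSOCIATION_SYMBOLS):
        names += list(_DISSOCIATION_SYMBOLS)
    else:
        names += [f"DAG{i + 1:02d}" for i in range(cfg.dissociation_gene_count)]
    groups["dissociation"] = np.arange(start, len(names))
    start = len(names)
    names += [f"HK{i + 1:02d}" for i in range(cfg.n_hk_genes)]
    groups["housekeeping"] = np.arange(start, len(names))
    start = len(names)
    half = cfg.n_ribo_genes // 2
    names += [f"RPS{i + 1:02d}" for i in range(half)]
    names += [f"RPL{i + 1:02d}" for i in range(cfg.n_ribo_genes - half)]
    groups["ribo"] = np.arange(start, len(names))
    start = len(names)
    names += [f"MT-{i + 1:02d}" for i in range(cfg.n_mito_genes)]
    groups["mito"] = np.arange(start, len(names))
    return names, groups


def _random_barcodes(rng: np.random.Generator, n: int, length: int = 12) -> np.ndarray:
    letters = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        draw = rng.integers(0, 4, size=(n - len(out), length))
        for row in draw:
            bc = "".join(letters[row])
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return np.asarray(out, dtype=object)


def _assemble_full(core: np.ndarray, ribo_share, mito_share,
                   w_ribo: np.ndarray, w_mito: np.ndarray,
                   core_idx, ribo_idx, mito_idx, n_genes: int) -> np.ndarray:
    """Compose full profiles from a core (non-mito/ribo) profile and shares.

    ``core`` may be 1-D (one profile) or 2-D (droplets x core genes);
    ``ribo_share`` / ``mito_share`` scalars or per-droplet vectors.
    """
    core = np.atleast_2d(core)
    r = np.atleast_1d(np.asarray(ribo_share, dtype=float))[:, None]
    m = np.atleast_1d(np.asarray(mito_share, dtype=float))[:, None]
    full = np.zeros((core.shape[0], n_genes))
    full[:, core_idx] = (1.0 - r - m) * core
    full[:, ribo_idx] = r * w_ribo
    full[:, mito_idx] = m * w_mito
    return full / full.sum(axis=1, keepdims=True)


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate a :class:`SimulatedDataset` from the config (seed mandatory)."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    gene_names, groups = _gene_names(cfg)
    n_genes = cfg.n_genes
    mito_idx, ribo_idx = groups["mito"], groups["ribo"]
    core_idx = np.setdiff1d(np.arange(n_genes), np.concatenate([mito_idx, ribo_idx]))
    core_pos = {g: i for i, g in enumerate(core_idx)}  # gene index -> core position
    n_core = core_idx.size

    # ---- sample-level structure -------------------------------------------
    w_mito = rng.dirichlet(np.full(mito_idx.size, 5.0))
    w_ribo = rng.dirichlet(np.full(ribo_idx.size, 5.0))
    hk_core = np.array([core_pos[g] for g in groups["housekeeping"]])
    dag_core = np.array([core_pos[g] for g in groups["dissociation"]])
    hk_within = rng.dirichlet(np.full(hk_core.size, 10.0))

    # ambient core profile: sparse Dirichlet — a handful of genes dominate —
    # with an explicit housekeeping share (ambient RNA stems from pooled cells)
    ambient_core = rng.dirichlet(np.full(n_core, cfg.ambient_concentration))
    amb_hk = rng.beta(*cfg.ambient_hk_beta)
    ambient_core[hk_core] = 0.0
    ambient_core = (1.0 - amb_hk) * ambient_core / ambient_core.sum()
    ambient_core[hk_core] = amb_hk * hk_within
    amb_mito = rng.beta(*cfg.ambient_mito_beta)
    amb_ribo = rng.beta(*cfg.ambient_ribo_beta)
    ambient_full = _assemble_full(
        ambient_core, amb_ribo, amb_mito, w_ribo, w_mito, core_idx, ribo_idx, mito_idx, n_genes
    )[0]

    # per-type core profiles, short and long dissociation conditions
    dag_total = cfg.dissociation_base_share * cfg.dissociation_gene_count
    free_share = 1.0 - cfg.marker_profile_share - cfg.hk_profile_share - dag_total
    if free_share <= 0:
        raise ValueError("marker/hk/dissociation shares exceed the whole profile")
    type_core = np.zeros((cfg.n_cell_types, 2, n_core))  # [type, condition(0=short,1=long)]
    for t in range(cfg.n_cell_types):
        own = np.array([core_pos[g] for g in groups[f"markers_type{t + 1}"]])
        soft = np.setdiff1d(
            np.arange(n_core), np.concatenate([own, hk_core, dag_core])
        )
        base = np.zeros(n_core)
        base[soft] = free_share * rng.dirichlet(
            np.full(soft.size, cfg.cell_profile_concentration)
        )
        base[own] = cfg.marker_profile_share * rng.dirichlet(np.full(own.size, 5.0))
        base[hk_core] = cfg.hk_profile_share * hk_within
        base[dag_core] = cfg.dissociation_base_share
        type_core[t, 0] = base / base.sum()
        boosted = base.copy()
        boosted[dag_core] *= cfg.dissociation_effect
        type_core[t, 1] = boosted / boosted.sum()

    # ---- droplets ----------------------------------------------------------
    n_cells = cfg.n_cell_types * cfg.cells_per_type
    cell_type = np.repeat(np.arange(cfg.n_cell_types), cfg.cells_per_type)
    cell_cond = (rng.random(n_cells) < cfg.long_condition_fraction).astype(int)

    def _beta(params, size):
        return rng.beta(params[0], params[1], size=size)

    def _cap_shares(m, r):
        tot = m + r
        bad = tot > 0.95
        if np.any(bad):
            scale = 0.95 / tot[bad]
            m = m.copy(); r = r.copy()
            m[bad] *= scale
            r[bad] *= scale
        return m, r

    def _draw_cell_like(types, conds, mito_params, n):
        amb = _beta(cfg.ambient_fraction_beta, n)
        m = _beta(mito_params, n)
        r = _beta(cfg.ribo_beta, n)
        m, r = _cap_shares(m, r)
        core = (1.0 - amb[:, None]) * type_core[types, conds] + amb[:, None] * ambient_core
        full = _assemble_full(core, r, m, w_ribo, w_mito, core_idx, ribo_idx, mito_idx, n_genes)
        sizes = np.maximum(
            1, np.round(rng.lognormal(cfg.cell_library_loc, cfg.cell_library_sigma, n))
        ).astype(np.int64)
        return rng.multinomial(sizes, full)

    cell_counts = _draw_cell_like(cell_type, cell_cond, cfg.baseline_mito_beta, n_cells)

    dying_type = rng.integers(0, cfg.n_cell_types, size=cfg.n_dying)
    dying_cond = (rng.random(cfg.n_dying) < cfg.long_condition_fraction).astype(int)
    dying_counts = (
        _draw_cell_like(dying_type, dying_cond, cfg.dying_mito_beta, cfg.n_dying)
        if cfg.n_dying else np.zeros((0, n_genes), dtype=np.int64)
    )

    # doublets: exact sums of two distinct cells from the same condition
    parent_a = np.zeros(cfg.n_doublets, dtype=int)
    parent_b = np.zeros(cfg.n_doublets, dtype=int)
    for d in range(cfg.n_doublets):
        cond = int(rng.random() < cfg.long_condition_fraction)
        pool = np.flatnonzero(cell_cond == cond)
        if pool.size < 2:
            pool = np.arange(n_cells)
        i, j = rng.choice(pool, size=2, replace=False)
        parent_a[d], parent_b[d] = i, j
    doublet_counts = (
        cell_counts[parent_a] + cell_counts[parent_b]
        if cfg.n_doublets else np.zeros((0, n_genes), dtype=np.int64)
    )
    doublet_cond = cell_cond[parent_a] if cfg.n_doublets else np.zeros(0, dtype=int)

    # empties: Dirichlet-multinomial around the ambient profile
    if cfg.n_empty:
        sizes = np.maximum(
            1, np.round(rng.lognormal(cfg.empty_library_loc, cfg.empty_library_sigma,
                                      cfg.n_empty))
        ).astype(np.int64)
        capture = rng.lognormal(
            math.log(cfg.ambient_capture_concentration), cfg.ambient_capture_sigma,
            size=cfg.n_empty,
        )
        alpha = capture[:, None] * ambient_full[None, :]
        gamma = rng.gamma(alpha)
        with np.errstate(invalid="ignore"):
            q = gamma / gamma.sum(axis=1, keepdims=True)
        # a pathological all-zero gamma row (possible only at absurdly tiny
        # concentrations) falls back to the ambient profile itself
        bad = ~np.isfinite(q).all(axis=1)
        if np.any(bad):
            q[bad] = ambient_full
        empty_counts = rng.multinomial(sizes, q)
        empty_cond = (rng.random(cfg.n_empty) < cfg.long_condition_fraction).astype(int)
    else:
        empty_counts = np.zeros((0, n_genes), dtype=np.int64)
        empty_cond = np.zeros(0, dtype=int)

    # ---- assemble ----------------------------------------------------------
    counts = np.vstack([cell_counts, dying_counts, doublet_counts, empty_counts])
    classes = (
        [f"cell:type{t + 1}" for t in cell_type]
        + ["dying"] * cfg.n_dying
        + ["doublet"] * cfg.n_doublets
        + ["empty"] * cfg.n_empty
    )
    cell_types = (
        [f"type{t + 1}" for t in cell_type]
        + [f"type{t + 1}" for t in dying_type]
        + [""] * cfg.n_doublets
        + [""] * cfg.n_empty
    )
    conds = np.concatenate([cell_cond, dying_cond, doublet_cond, empty_cond])
    n_total = counts.shape[0]
    barcodes = _random_barcodes(rng, n_total)
    order = rng.permutation(n_total)

    parent_bc_a = np.full(n_total, "", dtype=object)
    parent_bc_b = np.full(n_total, "", dtype=object)
    doublet_rows = np.arange(n_cells + cfg.n_dying, n_cells + cfg.n_dying + cfg.n_doublets)
    parent_bc_a[doublet_rows] = barcodes[parent_a]
    parent_bc_b[doublet_rows] = barcodes[parent_b]

    matrix = CountMatrix(
        sp.csr_matrix(counts[order].T),
        np.asarray(gene_names, dtype=object),
        barcodes[order],
        sample_id=f"sim_seed{cfg.seed}",
    )
    truth = pd.DataFrame(
        {
            "barcode": barcodes[order],
            "truth_class": np.asarray(classes, dtype=object)[order],
            "cell_type": np.asarray(cell_types, dtype=object)[order],
            "condition": np.where(conds[order] == 1, "long", "short"),
            "parent_a": parent_bc_a[order],
            "parent_b": parent_bc_b[order],
        }
    )

    ambient_top = np.argsort(-ambient_full, kind="stable")[: cfg.n_ambient_top]
    planted = {
        "ambient_top": GeneSet("ambient_top", [gene_names[i] for i in ambient_top]),
        "markers": GeneSet(
            "markers",
            [gene_names[i] for t in range(cfg.n_cell_types)
             for i in groups[f"markers_type{t + 1}"]],
        ),
        "dissociation": GeneSet(
            "dissociation", [gene_names[i] for i in groups["dissociation"]]
        ),
        "mito": GeneSet("mito", [gene_names[i] for i in groups["mito"]]),
        "ribo": GeneSet("ribo", [gene_names[i] for i in groups["ribo"]]),
        "housekeeping": GeneSet("housekeeping", [gene_names[i] for i in groups["housekeeping"]]),
    }
    for t in range(cfg.n_cell_types):
        planted[f"markers_type{t + 1}"] = GeneSet(
            f"markers_type{t + 1}", [gene_names[i] for i in groups[f"markers_type{t + 1}"]]
        )
    return SimulatedDataset(matrix=matrix, truth=truth, planted_sets=planted, config=cfg)


# ---------------------------------------------------------------------------
# evaluation harness
# ---------------------------------------------------------------------------

#: The prediction a perfect droplet classifier would make for each truth class.
EXPECTED_PREDICTION = {
    "empty": "low_quality",
    "doublet": "cell",
    "dying": "cell",
    # cell:typeN handled by prefix
}


def truth_confusion(
    dataset: SimulatedDataset, predictions: pd.DataFrame,
    prediction_column: str = "predicted_class",
) -> tuple[pd.DataFrame, pd.Series]:
    """Cross-tabulate truth class against predicted class; per-class recall.

    Recall for a truth class is the fraction of its droplets receiving the
    expected prediction (empty -> low_quality; any cell-containing droplet ->
    cell).  Missing barcodes in the predictions are an error.
    """
    pred = predictions.set_index("barcode")[prediction_column]
    missing = [b for b in dataset.truth["barcode"] if b not in pred.index]
    if missing:
        raise ValueError(f"predictions missing {len(missing)} barcode(s), e.g. {missing[:3]}")
    truth = dataset.truth.set_index("barcode")["truth_class"]
    aligned = pred.loc[truth.index]
    table = pd.crosstab(truth, aligned)
    expected = truth.map(lambda c: EXPECTED_PREDICTION.get(c, "cell"))
    hit = (aligned == expected).groupby(truth).mean()
    return table, hit.rename("recall")
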