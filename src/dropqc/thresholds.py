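"""MAD-based and hard-threshold droplet filters.

Three published rules are implemented: the widely-used baseline filter
(nUMI/nGene/percent-mito hard bounds), the doublet rule (nGene above
median + 2.5 MAD among cells), and the dead-cell rule (percent mito above
median + 2.5 MAD among cells).  All cut-offs are strict inequalities:
boundary values are retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qc import MAD_CONSTANT

__all__ = ["FilterReport", "mad_bounds", "apply_standard_filter", "flag_doublets", "flag_high_mito"]


@dataclass
class FilterReport:
    """Audit record of one filtering rule application."""

    rule_name: str
    n_input: int
    n_removed: int
    n_retained: int
    threshold_values: dict[str, float]
    removed_barcodes: list[str] = field(default_factory=list)
    retained_barcodes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.n_removed + self.n_retained == self.n_input
        assert len(self.removed_barcodes) == self.n_removed

    def to_dict(self) -> dict:
        return {
            "rule_name": self.rule_name,
            "n_input": self.n_input,
            "n_removed": self.n_removed,
            "n_retained": self.n_retained,
            "threshold_values": self.threshold_values,
            "removed_barcodes": list(self.removed_barcodes),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def mad_bounds(
    values,
    k: float = 2.5,
    log10_scale: bool = False,
    mad_constant: float = MAD_CONSTANT,
) -> tuple[float, float]:
    """``median +/- k * MAD`` of a vector, optionally on the log10 scale.

    With ``log10_scale`` the statistics are computed on log10-transformed
    values and the bounds are back-transformed to the original scale.  The
    MAD carries the usual normal-consistency constant 1.4826.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("mad_bounds requires at least one finite value")
    if log10_scale:
        n_bad = int((x <= 0).sum())
        if n_bad:
            raise ValueError(f"log10 scale requested but {n_bad} value(s) are <= 0")
        x = np.log10(x)
    med = float(np.median(x))
    mad = mad_constant * float(np.median(np.abs(x - med)))
    lower, upper = med - k * mad, med + k * mad
    if log10_scale:
        lower, upper = 10.0 ** lower, 10.0 ** upper
    return lower, upper


def _report(table: pd.DataFrame, removed_mask: np.ndarray, rule: str,
            thresholds: dict[str, float]) -> FilterReport:
    barcodes = table["barcode"].to_numpy()
    removed = list(barcodes[removed_mask])
    retained = list(barcodes[~removed_mask])
    return FilterReport(rule, len(barcodes), len(removed), len(retained),
                        thresholds, removed, retained)


def apply_standard_filter(
    table: pd.DataFrame,
    numi_max: float = 15000,
    numi_min: float = 200,
    ngene_max: float = 5000,
    ngene_min: float = 100,
    mito_max: float = 20.0,
) -> FilterReport:
    """The published baseline filter with its five hard bounds.

    Removes droplets with more than 15,000 or fewer than 200 nUMIs, over
    5,000 or below 100 genes, or over 20% mitochondrial reads (all strict;
    defaults exactly as printed, each overridable).
    """
    numi = table["nUMI"].to_numpy(dtype=float) if len(table) else np.array([])
    ngene = table["nGene"].to_numpy(dtype=float) if len(table) else np.array([])
    pm = table["percent_mito"].to_numpy(dtype=float) if len(table) else np.array([])
    removed = (
        (numi > numi_max) | (numi < numi_min)
        | (ngene > ngene_max) | (ngene < ngene_min)
        | (pm > mito_max)
    ) if len(table) else np.zeros(0, dtype=bool)
    thresholds = {
        "numi_max": numi_max, "numi_min": numi_min,
        "ngene_max": ngene_max, "ngene_min": ngene_min, "mito_max": mito_max,
    }
    return _report(table, removed, "standard_filter", thresholds)


def flag_doublets(
    table: pd.DataFrame, k: float = 2.5, log10_scale: bool = False
) -> FilterReport:
    """Doublet rule: remove droplets with nGene above median + k*MAD of nGene.

    Intended for a table already restricted to classifier-passed cells, where
    barcode doublets sit above the bulk of the nGene distribution.
    """
    if len(table) < 3:
        raise ValueError("doublet flagging needs at least 3 cells")
    _, upper = mad_bounds(table["nGene"], k=k, log10_scale=log10_scale)
    removed = table["nGene"].to_numpy(dtype=float) > upper
    return _report(table, removed, "doublet_ngene", {"ngene_upper": float(upper)})


def flag_high_mito(
    table: pd.DataFrame, k: float = 2.5, log10_scale: bool = False
) -> FilterReport:
    """Dead-cell rule: remove droplets with percent mito above median + k*MAD."""
    if len(table) < 3:
        raise ValueError("high-mito flagging needs at least 3 cells")
    values = table["percent_mito"]
    if log10_scale:
        # percent mito can be exactly 0; offset to keep the log defined.
        _, upper = mad_bounds(np.asarray(values, dtype=float) + 1e-3, k=k, log10_scale=True)
        upper -= 1e-3
    else:
        _, upper = mad_bounds(values, k=k, log10_scale=False)
    removed = values.to_numpy(dtype=float) > upper
    return _report(table, removed, "high_mito", {"percent_mito_upper": float(upper)})
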