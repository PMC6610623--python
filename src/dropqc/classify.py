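"""Self-supervised random-forest classification of low-quality droplets.

Ground-truth labels do not exist for droplet data, so training labels are
constructed from the unambiguous extremes of the nGene distribution
(self-labeling): droplets with nGene below a hard cutoff (default 100) are
assumed low-quality, droplets with nGene between the median and 2.5 MAD above
the median are assumed true cells, and everything in between stays unlabeled.
A random forest trained on the labeled bands — using QC metrics other than
nGene itself — is then applied to every droplet.

nGene is excluded from the default feature set because the labels are
nGene-defined; keeping it would leak the labeling rule into the learner.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split

from .qc import MAD_CONSTANT

__all__ = [
    "DEFAULT_FEATURES",
    "LabelRule",
    "ClassifierModel",
    "assign_training_labels",
    "split_train_test",
    "train_classifier",
    "rank_features",
    "classify_droplets",
]

#: Default classifier features: every QC metric except the label-defining nGene.
DEFAULT_FEATURES = (
    "nUMI",
    "percent_mito",
    "percent_ribo",
    "mito_ribo_ratio",
    "percent_hk",
    "ssheg_gene_pct",
    "ssheg_count_pct",
)

LOW_QUALITY = "low_quality"
TRUE_CELL = "true_cell"
UNLABELED = "unlabeled"


@dataclass
class LabelRule:
    """Self-labeling bands on the nGene distribution.

    ``low_quality_max_ngene`` is the hard low-quality cutoff (exclusive).  The
    true-cell band runs from the median of nGene to ``mad_k`` MADs above it.
    ``center_scope`` controls which droplets the median/MAD are computed on:
    ``"above_cutoff"`` (default) uses droplets at or above the low-quality
    cutoff, so that a raw matrix dominated by ambient barcodes still centers
    the band on cell-like droplets; ``"all"`` uses every droplet.
    """

    low_quality_max_ngene: int = 100
    mad_k: float = 2.5
    scale: str = "linear"  # or "log10"
    center_scope: str = "above_cutoff"  # or "all"
    mad_constant: float = MAD_CONSTANT

    def cell_band(self, ngene: np.ndarray) -> tuple[float, float]:
        """(cell_lower, cell_upper) = (median, median + k*MAD) of nGene."""
        x = np.asarray(ngene, dtype=float)
        if self.center_scope == "above_cutoff":
            x = x[x >= self.low_quality_max_ngene]
        elif self.center_scope != "all":
            raise ValueError(f"unknown center_scope {self.center_scope!r}")
        if x.size < 3:
            raise ValueError("too few droplets to place the true-cell band")
        if self.scale == "log10":
            lx = np.log10(np.maximum(x, 1))
            med = np.median(lx)
            mad = self.mad_constant * np.median(np.abs(lx - med))
            return 10.0 ** med, 10.0 ** (med + self.mad_k * mad)
        med = float(np.median(x))
        mad = self.mad_constant * float(np.median(np.abs(x - med)))
        return med, med + self.mad_k * mad


def assign_training_labels(table: pd.DataFrame, rule: LabelRule | None = None) -> pd.DataFrame:
    """Label droplets ``low_quality`` / ``true_cell`` / ``unlabeled`` by nGene bands.

    Raises if the bands overlap (cell_lower <= low-quality cutoff), which
    signals a table where the nGene median sits inside the presumed-garbage
    region.
    """
    rule = rule or LabelRule()
    ngene = table["nGene"].to_numpy(dtype=float)
    cell_lower, cell_upper = rule.cell_band(ngene)
    if cell_lower <= rule.low_quality_max_ngene:
        raise ValueError(
            f"label bands overlap: nGene median {cell_lower:.1f} <= "
            f"low-quality cutoff {rule.low_quality_max_ngene}"
        )
    table = table.copy()
    label = np.full(len(table), UNLABELED, dtype=object)
    label[ngene < rule.low_quality_max_ngene] = LOW_QUALITY
    label[(ngene >= cell_lower) & (ngene <= cell_upper)] = TRUE_CELL
    table["label"] = label
    table.attrs["label_rule"] = {
        "low_quality_max_ngene": rule.low_quality_max_ngene,
        "cell_lower": float(cell_lower),
        "cell_upper": float(cell_upper),
        "scale": rule.scale,
        "center_scope": rule.center_scope,
    }
    return table


def split_train_test(
    table: pd.DataFrame, ratio: float = 0.75, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified random split of the labeled droplets (default 3:1).

    Unlabeled droplets are dropped before splitting.  Each label class must
    have at least 4 members and the ratio must leave both sides non-empty.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    labeled = table[table["label"].isin([LOW_QUALITY, TRUE_CELL])]
    counts = labeled["label"].value_counts()
    for cls in (LOW_QUALITY, TRUE_CELL):
        if counts.get(cls, 0) < 4:
            raise ValueError(f"label class {cls!r} has {counts.get(cls, 0)} droplets (< 4)")
    train, test = train_test_split(
        labeled, train_size=ratio, stratify=labeled["label"], random_state=seed
    )
    return train, test


@dataclass
class ClassifierModel:
    """A trained droplet classifier with its evaluation and importances."""

    feature_names: tuple[str, ...]
    n_trees: int
    seed: int
    forest: RandomForestClassifier
    importance: pd.DataFrame
    test_sensitivity: float
    test_specificity: float
    confusion: dict[str, int] = field(default_factory=dict)
    format_version: int = 1

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "ClassifierModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, ClassifierModel):
            raise TypeError(f"{path}: not a ClassifierModel file")
        return model


def train_classifier(
    train: pd.DataFrame,
    test: pd.DataFrame,
    features: tuple[str, ...] = DEFAULT_FEATURES,
    n_trees: int = 500,
    seed: int = 0,
) -> ClassifierModel:
    """Fit a random forest on self-labeled droplets and evaluate it held-out.

    "cell" is the positive class: sensitivity = TP/(TP+FN) on true cells,
    specificity = TN/(TN+FP) on low-quality droplets, both from the test set.
    Feature importance is reported as mean impurity decrease and as
    permutation importance on the test set.  Forest defaults follow the
    canonical recipe: 500 trees, sqrt(p) candidate features per split, no
    depth limit.
    """
    for name, part in (("train", train), ("test", test)):
        missing = [f for f in features if f not in part.columns]
        if missing:
            raise KeyError(f"{name} table is missing feature column(s): {missing}")
        classes = set(part["label"])
        if not {LOW_QUALITY, TRUE_CELL} <= classes:
            raise ValueError(f"{name} set must contain both label classes, has {classes}")
    x_train = train[list(features)].to_numpy(dtype=float)
    y_train = (train["label"] == TRUE_CELL).to_numpy()
    constant = [f for f, col in zip(features, x_train.T) if np.all(col == col[0])]
    if constant:
        warnings.warn(f"constant feature(s) in training data retained: {constant}", stacklevel=2)

    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )
    forest.fit(x_train, y_train)

    x_test = test[list(features)].to_numpy(dtype=float)
    y_test = (test["label"] == TRUE_CELL).to_numpy()
    pred = forest.predict(x_test)
    tp = int(np.sum(pred & y_test))
    fn = int(np.sum(~pred & y_test))
    tn = int(np.sum(~pred & ~y_test))
    fp = int(np.sum(pred & ~y_test))
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)

    perm = permutation_importance(forest, x_test, y_test, n_repeats=10, random_state=seed)
    importance = pd.DataFrame(
        {
            "feature": list(features),
            "impurity_importance": forest.feature_importances_,
            "permutation_importance": perm.importances_mean,
        }
    )
    return ClassifierModel(
        feature_names=tuple(features),
        n_trees=n_trees,
        seed=seed,
        forest=forest,
        importance=importance,
        test_sensitivity=float(sensitivity),
        test_specificity=float(specificity),
        confusion={"tp": tp, "fn": fn, "tn": tn, "fp": fp},
    )


def rank_features(model: ClassifierModel, by: str = "impurity_importance") -> pd.DataFrame:
    """Features sorted by the primary importance measure (both are reported)."""
    return (
        model.importance.sort_values(by, ascending=False)
        .reset_index(drop=True)
        .assign(rank=lambda df: np.arange(1, len(df) + 1))
    )


def classify_droplets(model: ClassifierModel, table: pd.DataFrame) -> pd.DataFrame:
    """Predict cell / low_quality for every droplet, labeled or not.

    Adds ``predicted_class`` and ``prob_cell``; the decision threshold is the
    majority vote (probability 0.5).
    """
    missing = [f for f in model.feature_names if f not in table.columns]
    if missing:
        raise KeyError(f"table is missing feature column(s): {missing}")
    x = table[list(model.feature_names)].to_numpy(dtype=float)
    prob_cell = model.forest.predict_proba(x)[:, list(model.forest.classes_).index(True)]
    table = table.copy()
    table["prob_cell"] = prob_cell
    table["predicted_class"] = np.where(prob_cell > 0.5, "cell", LOW_QUALITY)
    return table
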