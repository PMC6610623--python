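import numpy as np
import pandas as pd
import pytest

import dropqc as dq
from dropqc.classify import (
    LabelRule, assign_training_labels, classify_droplets, rank_features,
    split_train_test, train_classifier,
)


def _table(ngene, **extra):
    n = len(ngene)
    base = {"barcode": [f"b{i}" for i in range(n)], "nGene": ngene,
            "nUMI": np.asarray(ngene) * 3}
    base.update(extra)
    return pd.DataFrame(base)


class TestLabeling:
    def test_band_assignment(self):
        # 40 ambient-like droplets below the cutoff, 60 cell-like around 500
        ngene = np.concatenate([np.full(40, 50), np.full(30, 480), np.full(30, 520)])
        labeled = assign_training_labels(_table(ngene))
        lab = labeled.set_index("nGene")["label"]
        assert (labeled.loc[labeled.nGene == 50, "label"] == "low_quality").all()
        # median of above-cutoff droplets is 500; both 480 (below) and 520 differ
        rule = labeled.attrs["label_rule"]
        assert rule["cell_lower"] == 500.0

    def test_ngene_at_median_is_true_cell(self):
        ngene = np.concatenate([np.full(10, 50), [400, 500, 500, 500, 600, 700]])
        labeled = assign_training_labels(_table(ngene))
        assert (labeled.loc[labeled.nGene == 500, "label"] == "true_cell").all()

    def test_between_bands_is_unlabeled(self):
        ngene = np.concatenate([np.full(10, 50), [150], np.full(20, 500)])
        labeled = assign_training_labels(_table(ngene))
        assert labeled.loc[labeled.nGene == 150, "label"].item() == "unlabeled"

    def test_overlapping_bands_error(self):
        # with the all-droplet scope the median sits below the cutoff
        ngene = np.concatenate([np.full(80, 50), np.full(20, 500)])
        with pytest.raises(ValueError, match="overlap"):
            assign_training_labels(_table(ngene), LabelRule(center_scope="all"))


class TestSplit:
    def _labeled(self, n_cell=300, n_low=100):
        t = _table(np.concatenate([np.full(n_low, 50), np.full(n_cell, 500)]))
        t["label"] = ["low_quality"] * n_low + ["true_cell"] * n_cell
        return t

    def test_three_to_one_stratified(self):
        train, test = split_train_test(self._labeled(), ratio=0.75, seed=0)
        assert len(train) == 300 and len(test) == 100
        assert train["label"].value_counts()["true_cell"] == 225
        assert test["label"].value_counts()["low_quality"] == 25

    def test_same_seed_same_partition(self):
        a = split_train_test(self._labeled(), seed=5)[0]
        b = split_train_test(self._labeled(), seed=5)[0]
        assert list(a["barcode"]) == list(b["barcode"])

    def test_degenerate_ratio_is_error(self):
        with pytest.raises(ValueError, match="ratio"):
            split_train_test(self._labeled(), ratio=1.0)

    def test_tiny_class_is_error(self):
        with pytest.raises(ValueError, match="< 4"):
            split_train_test(self._labeled(n_low=3))


def _feature_table(n_per_class, rng, informative=True):
    y = np.array(["low_quality"] * n_per_class + ["true_cell"] * n_per_class)
    x = rng.normal(0, 1, size=2 * n_per_class)
    if informative:
        x[n_per_class:] += 10.0
    return pd.DataFrame({"barcode": [f"b{i}" for i in range(2 * n_per_class)],
                         "feat": x, "noise": rng.normal(size=2 * n_per_class),
                         "label": y})


class TestForest:
    def test_separable_single_feature_is_perfect(self):
        rng = np.random.default_rng(0)
        t = _feature_table(40, rng)
        model = train_classifier(t.iloc[::2], t.iloc[1::2], features=("feat",),
                                 n_trees=1, seed=0)
        assert model.test_sensitivity == 1.0
        assert model.test_specificity == 1.0

    def test_shuffled_labels_give_chance_performance(self):
        rng = np.random.default_rng(1)
        t = _feature_table(100, rng)
        t["label"] = rng.permutation(t["label"].to_numpy())
        train, test = split_train_test(t, seed=1)
        model = train_classifier(train, test, features=("feat", "noise"), seed=1)
        # leakage check: no label signal left, performance near the prior
        assert model.test_sensitivity < 0.95
        assert 0.05 < (model.test_sensitivity + model.test_specificity) / 2 < 0.95

    def test_pure_noise_feature_ranks_last(self):
        rng = np.random.default_rng(2)
        t = _feature_table(150, rng)
        model = train_classifier(t.iloc[::2], t.iloc[1::2],
                                 features=("feat", "noise"), seed=0)
        assert list(rank_features(model)["feature"]) == ["feat", "noise"]

    def test_single_feature_model_rank(self):
        rng = np.random.default_rng(3)
        t = _feature_table(40, rng)
        model = train_classifier(t.iloc[::2], t.iloc[1::2], features=("feat",), seed=0)
        ranked = rank_features(model)
        assert ranked.loc[0, "feature"] == "feat" and ranked.loc[0, "rank"] == 1

    def test_constant_feature_warns_and_is_kept(self):
        rng = np.random.default_rng(4)
        t = _feature_table(40, rng)
        t["flat"] = 1.0
        with pytest.warns(UserWarning, match="flat"):
            model = train_classifier(t.iloc[::2], t.iloc[1::2],
                                     features=("feat", "flat"), seed=0)
        assert "flat" in model.feature_names

    def test_missing_feature_is_named(self):
        rng = np.random.default_rng(5)
        t = _feature_table(40, rng)
        model = train_classifier(t.iloc[::2], t.iloc[1::2], features=("feat",), seed=0)
        with pytest.raises(KeyError, match="feat"):
            classify_droplets(model, t.drop(columns=["feat"]))

    def test_model_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        t = _feature_table(40, rng)
        model = train_classifier(t.iloc[::2], t.iloc[1::2], features=("feat",), seed=0)
        model.save(tmp_path / "model.pkl")
        back = dq.ClassifierModel.load(tmp_path / "model.pkl")
        assert back.feature_names == model.feature_names
        a = classify_droplets(model, t)["prob_cell"]
        b = classify_droplets(back, t)["prob_cell"]
        assert np.array_equal(a.to_numpy(), b.to_numpy())


class TestPipelineDeterminismAndBehaviour:
    def test_fixed_seed_reproduces_everything(self, qc_default):
        def run():
            labeled = assign_training_labels(qc_default)
            train, test = split_train_test(labeled, seed=1)
            model = train_classifier(train, test, seed=1)
            return classify_droplets(model, labeled)

        a, b = run(), run()
        assert np.array_equal(a["prob_cell"].to_numpy(), b["prob_cell"].to_numpy())
        assert list(a["predicted_class"]) == list(b["predicted_class"])

    def test_training_band_cells_predicted_cell(self, classified_default):
        labeled, _, pred = classified_default
        band = pred[labeled["label"].to_numpy() == "true_cell"]
        assert (band["predicted_class"] == "cell").mean() >= 0.99
        assert (band["prob_cell"] > 0.5).mean() >= 0.99

    def test_all_zero_droplet_predicted_low_quality(self, classified_default, qc_default):
        _, model, _ = classified_default
        zero = qc_default.head(1).copy()
        for col in model.feature_names:
            zero[col] = 0.0
        assert classify_droplets(model, zero)["predicted_class"].item() == "low_quality"

    def test_classifier_more_sensitive_than_hard_thresholds(self, sim_default,
                                                            classified_default):
        """Empty-droplet recall at matched cell retention: forest >= hard filter."""
        _, _, pred = classified_default
        truth = sim_default.truth.set_index("barcode")["truth_class"]
        merged = pred.merge(sim_default.truth[["barcode", "truth_class"]], on="barcode")
        is_empty = merged["truth_class"] == "empty"
        is_cell = merged["truth_class"].str.startswith("cell")

        report = dq.apply_standard_filter(merged)
        removed = merged["barcode"].isin(report.removed_barcodes)
        std_recall = removed[is_empty].mean()
        std_retention = 1.0 - removed[is_cell].mean()

        thr = np.quantile(merged.loc[is_cell, "prob_cell"], 1.0 - std_retention)
        clf_recall = (merged.loc[is_empty, "prob_cell"] <= thr).mean()
        assert clf_recall >= std_recall
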