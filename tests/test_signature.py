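import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import dropqc as dq
from dropqc.clustering import ClusterAssignment, Embedding
from dropqc.signature import DEResult


def _matrix(counts, genes, barcodes=None):
    counts = np.atleast_2d(np.asarray(counts))
    barcodes = barcodes or [f"b{i}" for i in range(counts.shape[1])]
    return dq.CountMatrix(sp.csr_matrix(counts), genes, barcodes)


class TestScoreSignature:
    def test_hand_example(self):
        m = _matrix([[2], [8]], ["SIG1", "OTHER"])
        scores = dq.score_signature(m, dq.GeneSet("s", ["SIG1"]))
        assert scores["percent_expression"].item() == pytest.approx(20.0)

    def test_signature_absent_from_droplet_scores_zero(self):
        m = _matrix([[0, 2], [10, 8]], ["SIG1", "OTHER"])
        scores = dq.score_signature(m, dq.GeneSet("s", ["SIG1"]))
        assert scores["percent_expression"].iloc[0] == 0.0

    def test_signature_covering_all_genes_scores_hundred(self):
        m = _matrix([[3], [7]], ["A", "B"])
        scores = dq.score_signature(m, dq.GeneSet("s", ["A", "B"]))
        assert scores["percent_expression"].item() == 100.0

    def test_partially_absent_warns_fully_absent_errors(self):
        m = _matrix([[3], [7]], ["A", "B"])
        with pytest.warns(UserWarning, match="absent"):
            dq.score_signature(m, dq.GeneSet("s", ["A", "NOPE"]))
        with pytest.raises(ValueError, match="no genes"):
            dq.score_signature(m, dq.GeneSet("s", ["NOPE"]))

    def test_invariant_to_out_of_matrix_genes(self):
        m = _matrix([[2], [8]], ["SIG1", "OTHER"])
        with pytest.warns(UserWarning):
            padded = dq.score_signature(m, dq.GeneSet("s", ["SIG1", "GHOST1", "GHOST2"]))
        plain = dq.score_signature(m, dq.GeneSet("s", ["SIG1"]))
        assert padded["percent_expression"].equals(plain["percent_expression"])


class TestRefineSignature:
    def test_set_algebra_by_hand(self):
        refined, venn = dq.refine_signature(
            dq.GeneSet("ref", ["A", "B", "C"]),
            dq.GeneSet("up", ["B", "C", "D"]),
            dq.GeneSet("markers", ["C"]),
        )
        assert set(refined.genes) == {"B"}
        assert venn["reference&upregulated"] == 2
        assert venn["refined"] == 1

    def test_markers_superset_gives_empty_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            refined, _ = dq.refine_signature(
                dq.GeneSet("ref", ["A", "B"]),
                dq.GeneSet("up", ["A", "B"]),
                dq.GeneSet("markers", ["A", "B", "C"]),
            )
        assert len(refined) == 0

    def test_output_subset_of_reference_disjoint_from_markers(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(60)]
        ref = dq.GeneSet("ref", rng.choice(genes, 25, replace=False))
        up = [DEResult(g, 2.0, 1e-6, 1e-4) for g in rng.choice(genes, 30, replace=False)]
        markers = dq.GeneSet("m", rng.choice(genes, 20, replace=False))
        refined, _ = dq.refine_signature(ref, up, markers)
        assert refined.genes <= ref.genes
        assert not (refined.genes & markers.genes)


@pytest.fixture(scope="module")
def planted():
    cfg = dq.SimulationConfig(seed=21, n_cell_types=1, cells_per_type=200,
                              n_empty=0, n_doublets=0, n_dying=0)
    return dq.simulate(cfg)


class TestDifferentialExpression:
    def _groups(self, ds):
        t = ds.truth
        return (list(t.loc[t.condition == "long", "barcode"]),
                list(t.loc[t.condition == "short", "barcode"]))

    def test_planted_tenfold_genes_recovered(self, planted):
        long_bc, short_bc = self._groups(planted)
        up = dq.de_upregulated(planted.matrix, long_bc, short_bc)
        recovered = {r.gene for r in up}
        plantedset = planted.planted_sets["dissociation"].genes
        assert plantedset <= recovered
        # recall and precision both high with a 10x effect and ~100 cells/arm
        assert len(recovered - plantedset) <= 1

    def test_gene_only_in_reference_group_excluded(self):
        rng = np.random.default_rng(1)
        base = rng.integers(1, 20, size=(3, 40))
        base[2, :20] = 0  # gene g2 silent in group A
        m = _matrix(base, ["g0", "g1", "g2"])
        a = [f"b{i}" for i in range(20)]
        b = [f"b{i}" for i in range(20, 40)]
        up = dq.de_upregulated(m, a, b, p_max=0.5, lfc_min=0.0)
        assert "g2" not in {r.gene for r in up}

    def test_overlapping_groups_rejected(self, planted):
        long_bc, _ = self._groups(planted)
        with pytest.raises(ValueError, match="disjoint"):
            dq.de_upregulated(planted.matrix, long_bc, long_bc)

    def test_results_sorted_and_adjusted(self, planted):
        long_bc, short_bc = self._groups(planted)
        up = dq.de_upregulated(planted.matrix, long_bc, short_bc)
        fcs = [r.avg_logfc for r in up]
        assert fcs == sorted(fcs, reverse=True)
        assert all(r.p_adjusted >= r.p_value for r in up)


class TestClusterMarkers:
    def test_planted_markers_recovered(self, sim_default):
        truth = sim_default.truth
        cells = truth[truth["truth_class"].str.startswith("cell")]
        sub = sim_default.matrix.subset_droplets(list(cells["barcode"]))
        ids = pd.factorize(cells["cell_type"])[0]
        markers = dq.derive_cluster_markers(sub, ClusterAssignment(sub.barcodes, ids))
        assert sim_default.planted_sets["markers"].genes <= markers.genes

    def test_identical_clusters_have_no_markers(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 8, size=(40, 60)) + 1
        m = _matrix(counts, [f"g{i}" for i in range(40)])
        ids = np.array([0, 1] * 30)  # random halves of one population
        markers = dq.derive_cluster_markers(m, ClusterAssignment(m.barcodes, ids))
        assert len(markers) == 0

    def test_single_cluster_is_error(self):
        m = _matrix(np.ones((5, 10), dtype=int), [f"g{i}" for i in range(5)])
        with pytest.raises(ValueError, match="2 clusters"):
            dq.derive_cluster_markers(m, ClusterAssignment(m.barcodes, np.zeros(10, dtype=int)))


def brute_force_spearman(x, y):
    """Rank-correlation oracle: Pearson correlation of midranks."""
    def midrank(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sv = np.asarray(v, dtype=float)[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks
    rx, ry = midrank(x), midrank(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


class TestPCCorrelation:
    def _embedding(self, coords):
        return Embedding(np.array([f"b{i}" for i in range(len(coords))], dtype=object),
                         np.asarray(coords, dtype=float), np.zeros(coords.shape[1]))

    def test_perfect_monotone_gives_rho_one(self):
        coords = np.column_stack([np.arange(30.0), np.random.default_rng(0).normal(size=30)])
        scores = pd.DataFrame({"barcode": [f"b{i}" for i in range(30)],
                               "percent_expression": np.arange(30.0) ** 3})
        out = dq.pc_signature_correlation(self._embedding(coords), scores)
        assert out.loc[0, "spearman_rho"] == pytest.approx(1.0)
        assert bool(out.loc[0, "flagged"])

    def test_matches_rank_oracle(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(30, 3))
        scores = pd.DataFrame({"barcode": [f"b{i}" for i in range(30)],
                               "percent_expression": rng.uniform(0, 40, 30)})
        out = dq.pc_signature_correlation(self._embedding(coords), scores)
        for comp in range(3):
            oracle = brute_force_spearman(coords[:, comp], scores["percent_expression"])
            assert out.loc[comp, "spearman_rho"] == pytest.approx(oracle, abs=1e-12)

    def test_constant_scores_reported_undefined(self):
        coords = np.random.default_rng(4).normal(size=(20, 2))
        scores = pd.DataFrame({"barcode": [f"b{i}" for i in range(20)],
                               "percent_expression": np.full(20, 5.0)})
        out = dq.pc_signature_correlation(self._embedding(coords), scores)
        assert out["spearman_rho"].isna().all()
        assert not out["flagged"].any()


class TestFilterHighSignature:
    def test_constant_scores_remove_nothing(self):
        scores = pd.DataFrame({"barcode": [f"b{i}" for i in range(10)],
                               "percent_expression": np.full(10, 3.0)})
        assert dq.filter_high_signature(scores).n_removed == 0

    def test_single_extreme_droplet_removed(self):
        values = np.full(100, 2.0) + np.linspace(0, 0.5, 100)
        values[42] = 20.0  # ten times the median
        scores = pd.DataFrame({"barcode": [f"b{i}" for i in range(100)],
                               "percent_expression": values})
        report = dq.filter_high_signature(scores)
        assert report.removed_barcodes == ["b42"]

    def test_affected_subpopulation_removed_at_high_recall(self):
        rng = np.random.default_rng(5)
        values = np.concatenate([rng.uniform(1, 3, 180), rng.uniform(15, 25, 20)])
        scores = pd.DataFrame({"barcode": [f"b{i}" for i in range(200)],
                               "percent_expression": values})
        report = dq.filter_high_signature(scores)
        affected = {f"b{i}" for i in range(180, 200)}
        assert len(affected & set(report.removed_barcodes)) / 20 >= 0.95
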