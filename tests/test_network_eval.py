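import numpy as np
import pandas as pd
import pytest

from coexkit import (
    CoexpressionNetwork,
    Edge,
    GeneSet,
    GeneSetCollection,
    InputError,
    NetworkThresholds,
    build_network,
    compute_mutual_rank,
    compute_pcc_matrix,
    gba_scores,
    roc_curve,
    select_eval_terms,
    select_thresholds,
    shuffle_labels,
    threshold_grid_auc,
)
from coexkit.network_eval import ThresholdGrid
from coexkit.synthetic import SyntheticConfig, generate_dataset
from oracles import concordance_auc


def _collection(spec, namespace="GO_BP", universe=None):
    sets = {tid: GeneSet(tid, tid, namespace, frozenset(genes))
            for tid, genes in spec.items()}
    return GeneSetCollection(sets, frozenset(universe) if universe else None)


class TestSelectEvalTerms:
    def test_size_boundaries_inclusive(self):
        spec = {f"t{n}": [f"g{n}_{i}" for i in range(n)] for n in (3, 4, 20, 21)}
        kept = select_eval_terms(_collection(spec))
        assert set(kept.sets) == {"t4", "t20"}

    def test_size_measured_on_universe(self):
        spec = {"t": [f"g{i}" for i in range(10)]}
        kept = select_eval_terms(_collection(spec, universe=["g0", "g1", "g2", "zz"]))
        assert not kept.sets  # only 3 of its genes exist in the universe

    def test_namespace_filter(self):
        c = _collection({"t": ["a", "b", "c", "d"]}, namespace="KEGG")
        assert not select_eval_terms(c).sets
        assert set(select_eval_terms(c, namespace="KEGG").sets) == {"t"}

    def test_bad_bounds_rejected(self):
        with pytest.raises(InputError):
            select_eval_terms(_collection({"t": list("abcd")}), min_size=5, max_size=4)


class TestGBAScores:
    @pytest.fixture()
    def fixture(self):
        # g's neighbors: n1..n4 annotated (3 carry t), n5 unannotated
        net = CoexpressionNetwork(edges=[
            Edge("g", n, 0.9, i + 1.0, "positive")
            for i, n in enumerate(["n1", "n2", "n3", "n4", "n5"])
        ])
        sets = _collection({
            "t": ["g", "n1", "n2", "n3"],
            "u": ["n4", "q1", "q2", "q3"],
        })
        return net, sets

    def test_fraction_of_annotated_neighbors(self, fixture):
        net, sets = fixture
        pred = gba_scores(net, sets).set_index(["gene_id", "term_id"])
        rec = pred.loc[("g", "t")]
        assert rec["score"] == pytest.approx(0.75) and bool(rec["label"]) is True

    def test_term_carried_by_no_neighbor_scores_zero(self, fixture):
        net, sets = fixture
        pred = gba_scores(net, sets).set_index(["gene_id", "term_id"])
        rec = pred.loc[("n4", "u")]  # n4's only annotated neighbor is g (term t)
        assert rec["score"] == 0.0 and bool(rec["label"]) is True

    def test_own_annotations_never_contribute(self, fixture):
        net, sets = fixture
        pred = gba_scores(net, sets).set_index(["gene_id", "term_id"])
        # n1's sole neighbor is g (carries t only) -> score for t is 1 even
        # though n1 itself also carries t
        assert pred.loc[("n1", "t")]["score"] == 1.0

    def test_unannotated_gene_emits_nothing(self, fixture):
        net, sets = fixture
        pred = gba_scores(net, sets)
        assert "n5" not in set(pred["gene_id"])

    def test_gene_without_annotated_neighbors_emits_nothing(self):
        net = CoexpressionNetwork(edges=[Edge("a", "b", 0.9, 1.0, "positive")])
        sets = _collection({"t": ["a", "x", "y", "z"]})
        assert len(gba_scores(net, sets)) == 0

    def test_empty_network_gives_empty_predictions(self):
        pred = gba_scores(CoexpressionNetwork(edges=[]), _collection({"t": list("abcd")}))
        assert len(pred) == 0


def _pred(scores, labels):
    return pd.DataFrame({"gene_id": "g", "term_id": [f"t{i}" for i in range(len(scores))],
                         "score": scores, "label": labels})


class TestROC:
    def test_hand_case(self):
        curve = roc_curve(_pred([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]))
        assert curve.auc == pytest.approx(0.75)  # 3 of 4 pos x neg pairs concordant

    def test_perfect_separation(self):
        assert roc_curve(_pred([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])).auc == 1.0

    def test_curve_runs_corner_to_corner_monotonically(self):
        rng = np.random.default_rng(0)
        curve = roc_curve(_pred(rng.random(50), rng.integers(0, 2, 50)))
        assert curve.fpr[0] == 0 and curve.tpr[0] == 0
        assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)

    def test_matches_concordance_oracle_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(4, 60))
            scores = rng.integers(0, 5, n) / 4.0  # heavy ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert roc_curve(_pred(scores, labels)).auc == pytest.approx(
                concordance_auc(scores, labels), abs=1e-10)

    def test_random_labels_auc_near_half(self):
        rng = np.random.default_rng(123)
        n = 10_000
        curve = roc_curve(_pred(rng.random(n), rng.integers(0, 2, n)))
        assert curve.auc == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("labels, word", [([1, 1, 1], "positive"),
                                              ([0, 0, 0], "negative")])
    def test_degenerate_labels_rejected(self, labels, word):
        with pytest.raises(InputError, match=word):
            roc_curve(_pred([0.1, 0.2, 0.3], labels))


class TestThresholdGrid:
    @pytest.fixture(scope="class")
    def grid(self, study_bundle):
        sel = select_eval_terms(study_bundle.gene_sets)
        return threshold_grid_auc(study_bundle.expression, sel,
                                  pcc_grid=(0.6, 0.7, 0.8, 0.9), mr_grid=(10, 30))

    def test_one_entry_per_grid_point(self, grid):
        assert len(grid.entries) == 8
        assert grid.entries["auc"].dropna().between(0, 1).all()

    def test_single_point_matches_direct_pipeline(self, study_bundle):
        sel = select_eval_terms(study_bundle.gene_sets)
        grid = threshold_grid_auc(study_bundle.expression, sel,
                                  pcc_grid=(0.6,), mr_grid=(30,))
        corr = compute_pcc_matrix(study_bundle.expression)
        mr = compute_mutual_rank(corr)
        net = build_network(corr, mr, NetworkThresholds(pcc_bound=0.6, mr_max=30))
        direct = roc_curve(gba_scores(net, sel)).auc
        entry = grid.entries.iloc[0]
        assert entry["auc"] == pytest.approx(direct)
        assert entry["edge_count"] == len(net)

    def test_planted_signal_beats_shuffled_labels_everywhere(self, study_bundle, grid):
        sel = select_eval_terms(study_bundle.gene_sets)
        null = threshold_grid_auc(study_bundle.expression,
                                  shuffle_labels(sel, 99),
                                  pcc_grid=(0.6, 0.9), mr_grid=(10, 30))
        assert grid.entries["auc"].min() > null.entries["auc"].max()

    def test_degenerate_grid_point_recorded_not_crashed(self, six_gene_expr):
        sets = _collection({"t": ["g1", "g2", "g5", "g4"]},
                           universe=six_gene_expr.gene_ids)
        grid = threshold_grid_auc(six_gene_expr, select_eval_terms(sets),
                                  pcc_grid=(0.99,), mr_grid=(1.5,))
        entry = grid.entries.iloc[0]
        assert np.isnan(entry["auc"]) and entry["note"]

    def test_auc_non_increasing_with_noise(self):
        """More expression noise can only degrade functional coherence."""
        means = []
        for sd in (0.1, 0.5, 2.0):
            aucs = []
            for seed in range(1, 11):
                b = generate_dataset(SyntheticConfig(seed=seed, noise_sd=sd))
                sel = select_eval_terms(b.gene_sets)
                corr = compute_pcc_matrix(b.expression)
                mr = compute_mutual_rank(corr)
                net = build_network(corr, mr, NetworkThresholds(pcc_bound=0.0, mr_max=30))
                aucs.append(roc_curve(gba_scores(net, sel)).auc)
            means.append(np.mean(aucs))
        assert means[0] >= means[1] >= means[2]


class TestSelectThresholds:
    def _grid(self, rows):
        entries = pd.DataFrame(rows, columns=["pcc_bound", "mr_max", "auc"])
        entries["edge_count"] = 0
        entries["evaluable_pairs"] = 0
        entries["note"] = ""
        return ThresholdGrid(sign="positive", entries=entries)

    def test_near_tie_prefers_inclusive_pcc(self):
        grid = self._grid([(0.6, 30, 0.80), (0.7, 30, 0.80),
                           (0.8, 30, 0.79), (0.9, 30, 0.78)])
        t = select_thresholds(grid)
        assert t.pcc_bound == 0.6 and t.mr_max == 30

    def test_clear_winner_beats_inclusiveness(self):
        grid = self._grid([(0.6, 30, 0.70), (0.9, 30, 0.90)])
        assert select_thresholds(grid).pcc_bound == 0.9

    def test_tie_prefers_larger_mr_ceiling(self):
        grid = self._grid([(0.6, 10, 0.85), (0.6, 30, 0.85)])
        assert select_thresholds(grid).mr_max == 30

    def test_permutation_invariant_and_idempotent(self):
        rows = [(0.6, 10, 0.81), (0.7, 30, 0.82), (0.8, 50, 0.80), (0.6, 30, 0.815)]
        picks = {
            (select_thresholds(self._grid([rows[i] for i in perm])).pcc_bound,
             select_thresholds(self._grid([rows[i] for i in perm])).mr_max)
            for perm in ((0, 1, 2, 3), (3, 2, 1, 0), (2, 0, 3, 1))
        }
        assert len(picks) == 1

    def test_all_missing_rejected(self):
        grid = self._grid([(0.6, 30, np.nan)])
        with pytest.raises(InputError):
            select_thresholds(grid)
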