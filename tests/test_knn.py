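"""Neighbour search, majority vote and cross-validated selection of k."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from toxknn import (
    ConfigurationError,
    Dataset,
    ChemicalRecord,
    FingerprintMatrix,
    KnnModel,
    Neighbor,
    NeighborList,
    find_neighbors,
    neighbor_table,
    predict_class,
    predict_set,
    select_k,
    venetian_blind_folds,
)


def _model(fp, classes, k):
    return KnnModel(fp.ids, classes, fp, k)


class TestFindNeighbors:
    def test_identical_reference_found_at_zero(self, tiny_fingerprints):
        model = _model(tiny_fingerprints, [1, 1, 1, 2, 2, 2], k=1)
        neigh = find_neighbors(model, tiny_fingerprints.bits[2], query_id="q", exclude_self=False)
        assert neigh.ids == ["a3"] and neigh.neighbors[0].distance == 0.0

    def test_rank_ties_broken_by_input_order(self):
        """Exhaustive-sort oracle on hand-placed distances (0.1, 0.2, 0.2, 0.3, 0.9)."""
        # query (1,1,1,1,1,0,...): craft rows with known Jaccard distances
        m = 10
        query = np.zeros(m, dtype=np.uint8)
        query[:5] = 1

        def row(n_shared, n_extra):
            r = np.zeros(m, dtype=np.uint8)
            r[:n_shared] = 1
            r[5:5 + n_extra] = 1
            return r

        # distances: 1 - shared/union
        rows = np.array([
            row(5, 0),  # d = 0
            row(4, 0),  # d = 0.2
            row(4, 0),  # d = 0.2 (tie with previous)
            row(3, 0),  # d = 0.4
            row(1, 4),  # d = 1 - 1/9
        ])
        fp = FingerprintMatrix([f"r{i}" for i in range(5)], [f"b{j}" for j in range(m)], rows)
        model = _model(fp, [1, 2, 1, 2, 1], k=3)
        neigh = find_neighbors(model, query, exclude_self=False)
        d = cdist(query[None].astype(bool), rows.astype(bool), "jaccard")[0]
        oracle = sorted(range(5), key=lambda i: (d[i], i))[:3]  # ties by input order
        assert neigh.ids == [f"r{i}" for i in oracle] == ["r0", "r1", "r2"]
        assert [n.distance for n in neigh.neighbors] == pytest.approx(sorted(d)[:3])

    def test_exclude_self_removes_query(self, tiny_fingerprints):
        model = _model(tiny_fingerprints, [1, 1, 1, 2, 2, 2], k=3)
        neigh = find_neighbors(model, tiny_fingerprints.row("a1"), query_id="a1", exclude_self=True)
        assert "a1" not in neigh.ids and len(neigh) == 3

    def test_k_exceeding_references_rejected(self, tiny_fingerprints):
        model = _model(tiny_fingerprints, [1, 1, 1, 2, 2, 2], k=6)
        with pytest.raises(ConfigurationError):
            find_neighbors(model, tiny_fingerprints.row("a1"), query_id="a1", exclude_self=True)


class TestPredictClass:
    @pytest.mark.parametrize(
        "classes, expected",
        [((2, 2, 1), 2), ((1, 1, 1), 1), ((1, 2, 2), 2), ((2,), 2)],
    )
    def test_majority_vote(self, classes, expected):
        neigh = NeighborList("q", [Neighbor(f"r{i}", 0.1 * (i + 1), c) for i, c in enumerate(classes)])
        assert predict_class(neigh) == expected

    def test_vote_tie_goes_to_smaller_summed_distance(self):
        # classes (1,1,2,2): summed distance class 1 = 0.3, class 2 = 0.8
        neigh = NeighborList("q", [
            Neighbor("r1", 0.1, 1), Neighbor("r2", 0.2, 1),
            Neighbor("r3", 0.3, 2), Neighbor("r4", 0.5, 2),
        ])
        assert predict_class(neigh) == 1

    def test_full_tie_defaults_to_toxic_class(self):
        neigh = NeighborList("q", [Neighbor("r1", 0.4, 2), Neighbor("r2", 0.4, 1)])
        assert predict_class(neigh) == 1

    def test_invariant_to_order_of_equidistant_same_class_neighbors(self):
        a = NeighborList("q", [Neighbor("r1", 0.2, 2), Neighbor("r2", 0.2, 2), Neighbor("r3", 0.5, 1)])
        b = NeighborList("q", [Neighbor("r2", 0.2, 2), Neighbor("r1", 0.2, 2), Neighbor("r3", 0.5, 1)])
        assert predict_class(a) == predict_class(b)


class TestPredictSet:
    def test_self_inclusion_reproduces_own_class(self, tiny_dataset, tiny_fingerprints):
        """k=1 without self-exclusion is a perfect-fitting sanity oracle."""
        classes = [r.ghs_class for r in tiny_dataset.records]
        model = _model(tiny_fingerprints, classes, k=1)
        results = predict_set(model, tiny_fingerprints, exclude_self=False)
        assert [p for _, p in results] == classes

    def test_neighbor_table_layout(self, tiny_dataset, tiny_fingerprints):
        classes = [r.ghs_class for r in tiny_dataset.records]
        model = _model(tiny_fingerprints, classes, k=2)
        table = neighbor_table(predict_set(model, tiny_fingerprints, exclude_self=True))
        assert list(table.columns) == [
            "query_id", "rank", "analog_id", "distance", "analog_class", "predicted_class"]
        assert len(table) == 12
        assert not (table["query_id"] == table["analog_id"]).any()


class TestVenetianBlindFolds:
    def test_stratified_round_robin(self):
        classes = [1] * 10 + [2] * 5
        fold = venetian_blind_folds(classes, folds=5, seed=0)
        for cls, n in ((1, 10), (2, 5)):
            counts = np.bincount(fold[np.asarray(classes) == cls], minlength=5)
            assert counts.max() - counts.min() <= 1 and counts.sum() == n

    def test_seed_determinism(self):
        classes = [1, 2] * 10
        np.testing.assert_array_equal(
            venetian_blind_folds(classes, 5, seed=9), venetian_blind_folds(classes, 5, seed=9))


class TestSelectK:
    def test_singleton_grid(self, tiny_dataset, tiny_fingerprints):
        k_star, table = select_k(tiny_dataset, tiny_fingerprints, k_grid=(3,), folds=3, seed=0)
        assert k_star == 3 and list(table["k"]) == [3]

    def test_tie_prefers_smaller_k(self, tiny_dataset, tiny_fingerprints):
        """The separated tiny instance is perfect for several k: smallest wins."""
        k_star, table = select_k(tiny_dataset, tiny_fingerprints, k_grid=(1, 2, 3), folds=3, seed=0)
        errs = table.set_index("k")["mean_class_error"]
        assert errs.loc[k_star] == errs.min()
        assert all(errs.loc[k] > errs.loc[k_star] for k in table["k"] if k < k_star)

    def test_cv_is_seed_reproducible(self, sim_default):
        _, ds, fp, _ = sim_default
        a = select_k(ds, fp, k_grid=(1, 3, 5), folds=5, seed=7)
        b = select_k(ds, fp, k_grid=(1, 3, 5), folds=5, seed=7)
        assert a[0] == b[0]
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_leave_one_out_matches_brute_force_oracle(self, tiny_dataset, tiny_fingerprints):
        """folds = n: every prediction recomputed independently with scipy."""
        n = len(tiny_dataset)
        k = 3
        k_star, table = select_k(tiny_dataset, tiny_fingerprints, k_grid=(k,), folds=n, seed=5)
        fold = venetian_blind_folds([r.ghs_class for r in tiny_dataset.records], n, seed=5)
        classes = np.array([r.ghs_class for r in tiny_dataset.records])
        bits = tiny_fingerprints.bits.astype(bool)
        correct = {1: [0, 0], 2: [0, 0]}  # class -> [hits, total]
        for i in range(n):
            ref = np.flatnonzero(fold != fold[i])
            d = cdist(bits[i][None], bits[ref], "jaccard")[0]
            order = np.argsort(d, kind="stable")[:k]
            votes = classes[ref][order]
            pred = 1 if (votes == 1).sum() > (votes == 2).sum() else 2
            if (votes == 1).sum() == (votes == 2).sum():
                pred = 1 if d[order][votes == 1].sum() <= d[order][votes == 2].sum() else 2
            correct[classes[i]][1] += 1
            correct[classes[i]][0] += int(pred == classes[i])
        expected_ner = np.mean([correct[c][0] / correct[c][1] for c in (1, 2)])
        assert table["ner"].iloc[0] == pytest.approx(expected_ner)

    def test_separated_pattern_recovers_high_ner_for_small_k(self):
        """Noiseless informative bits give near-perfect CV accuracy for k <= 5."""
        from toxknn import SimulationConfig, simulate

        cfg = SimulationConfig(n_chemicals=100, informative_bits=8, flip_noise=0.0, seed=21)
        ds, fp, _ = simulate(cfg)
        _, table = select_k(ds, fp, k_grid=(1, 2, 3, 4, 5), folds=5, seed=1)
        assert (table["ner"] > 0.9).all()


def test_model_json_round_trip(tmp_path, tiny_fingerprints):
    model = KnnModel(tiny_fingerprints.ids, [1, 1, 1, 2, 2, 2], tiny_fingerprints, k=3)
    path = tmp_path / "model.json"
    model.to_json(path)
    back = KnnModel.from_json(path)
    assert back.ref_ids == model.ref_ids
    assert back.ref_classes == model.ref_classes
    assert back.k == model.k
    np.testing.assert_array_equal(back.ref_fingerprints.bits, model.ref_fingerprints.bits)
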