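import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from ms2fp.metrics import (
    active_bit_analysis,
    confusion,
    evaluate_predictions,
    mds_embed,
    mds_from_distances,
    mds_stress,
    ner,
    rank_candidates,
)


class TestConfusion:
    def test_perfect_prediction(self, rng):
        Y = (rng.random((30, 6)) < 0.4).astype(int)
        for c in confusion(Y, Y):
            assert c.fp == 0 and c.fn == 0
            assert c.n == 30

    def test_complement_prediction(self, rng):
        Y = (rng.random((30, 6)) < 0.4).astype(int)
        for c in confusion(1 - Y, Y):
            assert c.tp == 0 and c.tn == 0

    def test_hand_example(self):
        truth = np.array([[1], [1], [0], [0]])
        pred = np.array([[1], [0], [0], [1]])
        c = confusion(pred, truth)[0]
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_shape_and_binary_validation(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((3, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            confusion(np.full((3, 2), 2), np.zeros((3, 2)))


class TestNer:
    def test_perfect_is_one(self, rng):
        Y = (rng.random((50, 8)) < 0.5).astype(int)
        overall, per_task, excluded = ner(confusion(Y, Y))
        assert overall == 1.0

    def test_sn_one_sp_zero_is_half(self):
        truth = np.array([[1], [0]])
        pred = np.array([[1], [1]])
        overall, per_task, _ = ner(confusion(pred, truth))
        assert overall == 0.5

    def test_random_predictions_score_near_half(self):
        rng = np.random.default_rng(77)
        truth = (rng.random((5000, 10)) < 0.5).astype(int)
        pred = (rng.random((5000, 10)) < 0.5).astype(int)
        overall, _, _ = ner(confusion(pred, truth))
        assert abs(overall - 0.5) < 0.02

    def test_single_class_tasks_excluded(self):
        truth = np.array([[1, 1], [1, 0]])  # task 0 has positives only
        pred = np.array([[1, 1], [0, 0]])
        overall, per_task, excluded = ner(confusion(pred, truth))
        assert excluded == [0]
        assert np.isnan(per_task[0])

    def test_no_defined_task_errors(self):
        truth = np.ones((4, 2), dtype=int)
        with pytest.raises(ValueError):
            ner(confusion(truth, truth))

    def test_complement_sums_to_one_per_task(self, rng):
        truth = (rng.random((40, 5)) < 0.5).astype(int)
        pred = (rng.random((40, 5)) < 0.5).astype(int)
        _, per_task, _ = ner(confusion(pred, truth))
        _, per_task_c, _ = ner(confusion(1 - pred, truth))
        assert np.allclose(per_task + per_task_c, 1.0)

    def test_task_order_invariance(self, rng):
        truth = (rng.random((40, 6)) < 0.5).astype(int)
        pred = (rng.random((40, 6)) < 0.5).astype(int)
        perm = rng.permutation(6)
        a, _, _ = ner(confusion(pred, truth))
        b, _, _ = ner(confusion(pred[:, perm], truth[:, perm]))
        assert a == pytest.approx(b)


class TestEvaluateReport:
    def test_report_consistency(self, rng):
        truth = (rng.random((25, 166)) < 0.23).astype(int)
        pred = (rng.random((25, 166)) < 0.23).astype(int)
        rep = evaluate_predictions(pred, truth)
        assert len(rep.jt_per_spectrum) == 25
        assert 0 <= rep.jt_mean <= 1
        defined = ~np.isnan(rep.ner_per_task)
        assert rep.ner_overall == pytest.approx(rep.ner_per_task[defined].mean())


class TestRanking:
    def test_true_fingerprint_ranks_first(self, rng):
        fp = (rng.random(166) < 0.3).astype(int)
        library = [("other", (rng.random(166) < 0.3).astype(int)), ("self", fp)]
        ranked, true_rank = rank_candidates(fp, library, true_compound_id="self")
        assert ranked[0][0] == "self"
        assert ranked[0][1] == 1.0
        assert true_rank == 1

    def test_ties_break_lexicographically(self):
        fp = np.zeros(166, dtype=int)
        fp[:4] = 1
        zero = np.zeros(166, dtype=int)
        library = [("b", zero.copy()), ("a", zero.copy()), ("c", zero.copy())]
        ranked, _ = rank_candidates(fp, library)
        assert [r[0] for r in ranked] == ["a", "b", "c"]
        assert all(r[1] == 0.0 for r in ranked)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            rank_candidates(np.zeros(166), [])


class TestMds:
    def test_equilateral_for_pairwise_equidistant(self):
        fps = np.array(
            [
                [1, 1, 0, 0, 0, 0],
                [0, 0, 1, 1, 0, 0],
                [0, 0, 0, 0, 1, 1],
            ]
        )
        coords = mds_embed(fps, n_dims=2)
        d = pdist(coords)
        assert np.allclose(d, d[0], atol=1e-6)

    def test_duplicated_fingerprint_coincident(self):
        fps = np.array([[1, 0, 0, 1], [1, 0, 0, 1], [0, 1, 1, 0]])
        coords = mds_embed(fps, n_dims=1)
        assert np.allclose(coords[0], coords[1], atol=1e-8)

    def test_planted_euclidean_distances_recovered(self, rng):
        pts = rng.random((12, 2)) * 3
        D = squareform(pdist(pts))
        coords = mds_from_distances(D, n_dims=2)
        assert np.abs(squareform(pdist(coords)) - D).max() < 1e-6

    def test_stress_non_increasing_in_dims(self, rng):
        pts = rng.random((10, 4))
        D = squareform(pdist(pts))
        stresses = [mds_stress(D, mds_from_distances(D, n_dims=k)) for k in (1, 2, 3, 4)]
        assert all(b <= a + 1e-9 for a, b in zip(stresses, stresses[1:]))

    def test_requesting_too_many_dims_warns(self):
        # three collinear points embed exactly in 1-D
        D = squareform(pdist(np.array([[0.0], [1.0], [2.0]])))
        with pytest.warns(UserWarning):
            coords = mds_from_distances(D, n_dims=3)
        assert coords.shape[1] < 3

    def test_deterministic_orientation(self, rng):
        pts = rng.random((8, 2))
        D = squareform(pdist(pts))
        a = mds_from_distances(D, 2)
        b = mds_from_distances(D, 2)
        assert np.array_equal(a, b)
        for j in range(2):
            assert a[np.argmax(np.abs(a[:, j])), j] > 0

    def test_agrees_with_principal_coordinates_oracle(self, rng):
        """Cross-check against an independent PCoA implementation."""
        pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa

        fps = (rng.random((10, 40)) < 0.3).astype(int)
        coords = mds_embed(fps, n_dims=2)
        from ms2fp.fingerprints import jt

        D = np.array([[1 - jt(a, b) for b in fps] for a in fps])
        ref = pcoa(D, number_of_dimensions=2).samples.to_numpy()
        for j in range(2):
            diff = min(
                np.abs(coords[:, j] - ref[:, j]).max(),
                np.abs(coords[:, j] + ref[:, j]).max(),
            )
            assert diff < 1e-6

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            mds_embed(np.zeros((2, 10)))


class TestActiveBitAnalysis:
    def test_all_accurate_leaves_low_group_empty(self):
        fps = {"a": np.ones(10, dtype=int)}
        out = active_bit_analysis({"a": 0.9}, fps)
        assert out["low"] is None
        assert out["high"]["median"] == 100.0

    def test_hand_built_two_compound_case(self):
        fps = {
            "poor": np.concatenate([np.ones(1), np.zeros(9)]).astype(int),
            "good": np.concatenate([np.ones(3), np.zeros(7)]).astype(int),
        }
        out = active_bit_analysis({"poor": 0.1, "good": 0.9}, fps)
        assert out["low"]["median"] == pytest.approx(10.0)
        assert out["high"]["median"] == pytest.approx(30.0)

    def test_boundary_values_fall_in_no_group(self):
        fps = {"m": np.ones(4, dtype=int)}
        out = active_bit_analysis({"m": 0.5}, fps)
        assert out["low"] is None and out["high"] is None
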