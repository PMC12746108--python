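import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from signmf import (
    FitSettings,
    cosine_flat,
    estimate_holdout,
    extract_fold,
    make_split,
    r_squared,
    rank_selection,
)


class TestMakeSplit:
    def test_exact_division(self):
        split = make_split(np.arange(81.0).reshape(9, 9), 3, 3, shuffle_seed=0)
        assert np.diff(split.row_breaks).tolist() == [3, 3, 3]
        assert np.diff(split.col_breaks).tolist() == [3, 3, 3]

    def test_remainder_to_earliest_blocks(self):
        split = make_split(np.ones((10, 11)), 3, 3, shuffle_seed=0)
        assert np.diff(split.row_breaks).tolist() == [4, 3, 3]
        assert np.diff(split.col_breaks).tolist() == [4, 4, 3]

    def test_seed_determinism(self):
        X = np.random.default_rng(0).uniform(size=(12, 12))
        a = make_split(X, 3, 3, shuffle_seed=7)
        b = make_split(X, 3, 3, shuffle_seed=7)
        assert np.array_equal(a.row_perm, b.row_perm)
        assert np.array_equal(a.X, b.X)

    def test_shuffle_preserves_entries(self):
        X = np.random.default_rng(1).uniform(size=(8, 7))
        split = make_split(X, 2, 2, shuffle_seed=3)
        np.testing.assert_allclose(np.sort(split.X.ravel()), np.sort(X.ravel()))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_split(np.ones((2, 9)), 3, 3, shuffle_seed=0)


class TestExtractFold:
    def test_first_fold_layout(self):
        X = np.arange(81.0).reshape(9, 9)
        split = make_split(X, 3, 3, shuffle_seed=0)
        fold = extract_fold(split, 0)
        np.testing.assert_array_equal(fold.A, split.X[0:3, 0:3])
        np.testing.assert_array_equal(fold.D, split.X[3:9, 3:9])

    @pytest.mark.parametrize("fold_index", range(9))
    def test_shapes_conformable(self, fold_index):
        split = make_split(np.random.default_rng(0).uniform(size=(10, 11)), 3, 3, shuffle_seed=1)
        f = extract_fold(split, fold_index)
        assert f.A.shape[0] == f.B.shape[0]
        assert f.A.shape[1] == f.C.shape[1]
        assert f.C.shape[0] == f.D.shape[0]
        assert f.B.shape[1] == f.D.shape[1]

    def test_parts_tile_matrix(self):
        split = make_split(np.random.default_rng(2).uniform(size=(10, 11)), 3, 3, shuffle_seed=1)
        total = sum(f.A.size for f in (extract_fold(split, i) for i in range(9)))
        assert total == split.X.size
        f = extract_fold(split, 4)  # middle block: A + B + C + D covers everything
        assert f.A.size + f.B.size + f.C.size + f.D.size == split.X.size

    def test_index_out_of_range(self):
        split = make_split(np.ones((9, 9)), 3, 3, shuffle_seed=0)
        with pytest.raises(IndexError):
            extract_fold(split, 9)


class TestEstimateHoldout:
    def test_noiseless_factorizable_recovers_holdout(self, noiseless_rank3):
        split = make_split(noiseless_rank3.X, 3, 3, shuffle_seed=5)
        settings = FitSettings(max_iter=1000, tol=1e-6)
        for fold_index in (0, 4):
            fold = extract_fold(split, fold_index)
            A_est = estimate_holdout(fold, 3, settings, seed=1)
            assert cosine_flat(fold.A, A_est) >= 0.99

    def test_shape_and_nonnegativity(self, noiseless_rank3):
        split = make_split(noiseless_rank3.X, 3, 3, shuffle_seed=2)
        fold = extract_fold(split, 3)
        A_est = estimate_holdout(fold, 2, seed=0)
        assert A_est.shape == fold.A.shape
        assert A_est.min() >= 0

    def test_rank_too_large_for_training_block(self, noiseless_rank3):
        split = make_split(noiseless_rank3.X, 3, 3, shuffle_seed=2)
        fold = extract_fold(split, 0)
        with pytest.raises(ValueError):
            estimate_holdout(fold, min(fold.D.shape) + 1)


class TestCosineFlat:
    def test_identity(self):
        A = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert cosine_flat(A, A) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal(self):
        A = np.array([[1.0, 0.0], [0.0, 0.0]])
        B = np.array([[0.0, 0.0], [0.0, 1.0]])
        assert cosine_flat(A, B) == 0.0

    def test_hand_computed(self):
        A = np.array([[1.0, 2.0], [3.0, 4.0]])
        B = np.array([[4.0, 3.0], [2.0, 1.0]])
        assert cosine_flat(A, B) == pytest.approx(20.0 / 30.0, abs=1e-12)

    def test_zero_matrix_policy(self):
        assert cosine_flat(np.zeros((2, 2)), np.ones((2, 2))) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_nonnegative_inputs_give_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.uniform(size=(3, 4))
        B = rng.uniform(size=(3, 4))
        assert 0.0 <= cosine_flat(A, B) <= 1.0 + 1e-12


class TestRSquared:
    def test_identity(self):
        A = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert r_squared(A, A) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_all_ones_estimate(self):
        A = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert r_squared(A, np.ones((2, 2))) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_row_vector(self):
        assert r_squared(np.array([[1.0, 3.0]]), np.array([[1.0, 2.0]])) == pytest.approx(0.6, abs=1e-12)

    def test_centering_switch(self):
        A = np.array([[1.0, 3.0]])
        B = np.array([[1.0, 2.0]])
        # holdout centering uses mean(A)=2: 1 - 1/2 = 0.5
        assert r_squared(A, B, center="holdout") == pytest.approx(0.5, abs=1e-12)

    def test_zero_denominator_is_missing(self):
        A = np.array([[2.0, 2.0]])
        B = np.array([[2.0, 2.0]])
        assert np.isnan(r_squared(A, B))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_never_exceeds_one(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.uniform(size=(3, 3))
        B = rng.uniform(size=(3, 3))
        val = r_squared(A, B)
        assert np.isnan(val) or val <= 1.0 + 1e-12


class TestRankSelection:
    def test_record_counting(self, noiseless_rank3):
        res = rank_selection(
            noiseless_rank3.X, [2], num_shuffles=2,
            settings=FitSettings(max_iter=50), master_seed=0,
        )
        counts = res.records.groupby("metric").size()
        assert counts["cosine"] == 18 and counts["r_squared"] == 18

    def test_master_seed_determinism(self, noiseless_rank3):
        kwargs = dict(num_shuffles=2, settings=FitSettings(max_iter=50), master_seed=11)
        a = rank_selection(noiseless_rank3.X, [2, 3], **kwargs)
        b = rank_selection(noiseless_rank3.X, [2, 3], **kwargs)
        assert a.records.equals(b.records)

    def test_true_rank_beats_lower_rank_noiseless(self, noiseless_rank3):
        res = rank_selection(
            noiseless_rank3.X, [2, 3], num_shuffles=3,
            settings=FitSettings(max_iter=300), master_seed=1,
        )
        med = res.medians()
        assert med.loc[3, "cosine"] > med.loc[2, "cosine"]
        assert med.loc[3, "cosine"] >= 0.99

    def test_shuffling_invariance_in_expectation(self, noiseless_rank3):
        """Medians on X and on a fixed row/column permutation of X agree
        within Monte-Carlo error at equal shuffle counts."""
        X = noiseless_rank3.X
        rng = np.random.default_rng(0)
        Xp = X[np.ix_(rng.permutation(X.shape[0]), rng.permutation(X.shape[1]))]
        kwargs = dict(num_shuffles=6, settings=FitSettings(max_iter=200), master_seed=2)
        med_a = rank_selection(X, [3], **kwargs).medians()
        med_b = rank_selection(Xp, [3], **kwargs).medians()
        assert abs(med_a.loc[3, "cosine"] - med_b.loc[3, "cosine"]) < 0.05

    def test_invalid_ranks_rejected(self, noiseless_rank3):
        with pytest.raises(ValueError):
            rank_selection(noiseless_rank3.X, [], num_shuffles=1)
        with pytest.raises(ValueError):
            rank_selection(noiseless_rank3.X, [25], num_shuffles=1)
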