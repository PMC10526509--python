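import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import mutual_info_score

from gradwise.data_io import DegenerateFeatureError
from gradwise.selectors import (
    LassoConfig,
    MrmrConfig,
    discretize_continuous,
    lasso_select,
    mrmr_select,
    mrmr_subset_size,
    mutual_information,
)


class TestSubsetSize:
    @pytest.mark.parametrize("p,expected", [(23, 5), (16, 4), (22, 5), (2, 1), (3, 2)])
    def test_ceiling_of_log2(self, p, expected):
        assert mrmr_subset_size(p) == expected

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError):
            mrmr_subset_size(1)


class TestMutualInformation:
    def test_identical_balanced_binary_is_one_bit(self):
        x = np.array([0, 0, 1, 1])
        assert mutual_information(x, x) == pytest.approx(1.0)

    def test_constant_vector_gives_zero(self):
        assert mutual_information(np.zeros(8), np.arange(8) % 2) == 0.0

    def test_hand_evaluated_2x2_joint(self):
        # joint counts {(0,0):4, (0,1):1, (1,0):1, (1,1):4}:
        # 2*0.4*log2(1.6) + 2*0.1*log2(0.4) = 0.2780719051
        x = np.array([0] * 5 + [1] * 5)
        y = np.array([0] * 4 + [1] + [0] + [1] * 4)
        assert mutual_information(x, y) == pytest.approx(0.2780719051, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information([0, 1], [0, 1, 0])

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.integers(0, 3), min_size=2, max_size=40),
           st.data())
    def test_symmetry_nonnegativity_and_self_entropy(self, xs, data):
        ys = data.draw(st.lists(st.integers(0, 3), min_size=len(xs), max_size=len(xs)))
        x, y = np.array(xs), np.array(ys)
        mxy, myx = mutual_information(x, y), mutual_information(y, x)
        assert mxy == pytest.approx(myx, abs=1e-12)
        assert mxy >= -1e-12
        # MI(x, x) equals the plug-in entropy of x
        _, counts = np.unique(x, return_counts=True)
        px = counts / counts.sum()
        entropy = -np.sum(px * np.log2(px))
        assert mutual_information(x, x) == pytest.approx(entropy, abs=1e-12)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_independent_library_estimator(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, 30)
        y = rng.integers(0, 3, 30)
        expected = mutual_info_score(x, y) / math.log(2)  # nats -> bits
        assert mutual_information(x, y) == pytest.approx(expected, abs=1e-10)


class TestDiscretize:
    def test_median_split(self):
        x = np.arange(1, 11, dtype=float)
        bins = discretize_continuous(x, 2)
        assert bins.tolist() == [0] * 5 + [1] * 5

    def test_binary_input_passes_through(self):
        x = np.array([0.0, 1, 1, 0, 1, 1, 1, 1])
        assert discretize_continuous(x, 2).tolist() == [0, 1, 1, 0, 1, 1, 1, 1]

    def test_ties_at_median_go_to_lower_bin_and_are_order_invariant(self):
        x = np.array([1.0, 5, 5, 5, 5, 5, 9, 10])
        bins = discretize_continuous(x, 2)
        # the 0.5-quantile equals the tie value 5, so every 5 lands in bin 0
        assert bins.tolist() == [0, 0, 0, 0, 0, 0, 1, 1]
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = rng.permutation(len(x))
            assert np.array_equal(discretize_continuous(x[perm], 2), bins[perm])

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateFeatureError):
            discretize_continuous(np.ones(10), 2)

    def test_labels_within_range(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        for n_bins in (2, 3, 4, 7):
            b = discretize_continuous(x, n_bins)
            assert set(np.unique(b)) <= set(range(n_bins))


def brute_force_mrmr(D, y, m, criterion="difference"):
    """Independent greedy re-evaluation using the library MI estimator."""
    p = D.shape[1]
    rel = [mutual_info_score(D[:, j], y) / math.log(2) for j in range(p)]
    selected = []
    while len(selected) < m:
        scores = {}
        for j in range(p):
            if j in selected:
                continue
            if not selected:
                scores[j] = rel[j]
            else:
                red = np.mean([mutual_info_score(D[:, j], D[:, s]) / math.log(2)
                               for s in selected])
                if criterion == "difference":
                    scores[j] = rel[j] - red
                else:
                    scores[j] = rel[j] / max(red, 1e-12)
        best = max(scores.values())
        # near-ties resolve to the lower feature index
        selected.append(min(j for j, s in scores.items() if s >= best - 1e-9))
    return selected


class TestMrmrSelect:
    def test_m_equals_one_is_pure_relevance(self, table_factory):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 100)
        X = np.column_stack([rng.integers(0, 2, 100), y, rng.integers(0, 2, 100)])
        t = table_factory(X, y)
        res = mrmr_select(t, MrmrConfig(m=1))
        assert res.selected == ("f1",)

    def test_redundant_copy_never_selected_second(self, table_factory):
        rng = np.random.default_rng(5)
        n = 200
        y = rng.integers(0, 2, n)
        a = np.where(rng.random(n) < 0.05, 1 - y, y)  # strong but imperfect
        b = np.where(rng.random(n) < 0.25, 1 - y, y)  # weaker, independent noise
        X = np.column_stack([a, a.copy(), b]).astype(float)
        t = table_factory(X, y, names=("A", "Acopy", "B"))
        res = mrmr_select(t, MrmrConfig(m=2))
        assert res.selected[0] == "A"
        # the exact duplicate carries redundancy MI(Acopy; A) = H(A), which
        # exceeds its relevance under the difference criterion, so the
        # weaker complementary feature wins step 2
        assert res.selected == ("A", "B")

    def test_returns_exactly_heuristic_count_for_23_features(self, table_factory):
        rng = np.random.default_rng(11)
        n = 80
        y = rng.integers(0, 2, n)
        X = rng.integers(0, 2, (n, 23)).astype(float)
        t = table_factory(X, y)
        res = mrmr_select(t)
        assert len(res.selected) == 5

    def test_m_larger_than_p_rejected(self, table_factory):
        t = table_factory([[0, 1], [1, 0], [0, 0], [1, 1]], [0, 1, 0, 1])
        with pytest.raises(ValueError):
            mrmr_select(t, MrmrConfig(m=3))

    @pytest.mark.parametrize("criterion", ["difference", "quotient"])
    def test_matches_brute_force_oracle(self, table_factory, criterion):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = 60
            p = rng.integers(4, 11)
            m = rng.integers(1, min(p, 5) + 1)
            y = rng.integers(0, 2, n)
            X = rng.integers(0, 2, (n, p)).astype(float)
            if len(np.unique(y)) < 2:
                continue
            t = table_factory(X, y)
            res = mrmr_select(t, MrmrConfig(m=int(m), criterion=criterion))
            expected = brute_force_mrmr(X.astype(int), y, int(m), criterion)
            assert res.selected == tuple(t.feature_names[j] for j in expected)

    def test_invariant_to_row_order(self, table_factory):
        rng = np.random.default_rng(23)
        n = 120
        y = rng.integers(0, 2, n)
        X = np.column_stack([rng.normal(size=n)] +
                            [rng.integers(0, 2, n) for _ in range(6)])
        kinds = ("continuous",) + ("binary",) * 6
        t = table_factory(X, y, kinds=kinds)
        perm = rng.permutation(n)
        t2 = table_factory(X[perm], y[perm], kinds=kinds)
        assert mrmr_select(t, MrmrConfig(m=3)).selected == \
            mrmr_select(t2, MrmrConfig(m=3)).selected


class TestLassoSelect:
    def test_huge_penalty_gives_empty_selection(self, table_factory):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 100)
        X = rng.normal(size=(100, 4))
        t = table_factory(X, y, kinds=("continuous",) * 4)
        res = lasso_select(t, LassoConfig(alpha_grid=(1e6,)), seed=0)
        assert res.selected == ()

    def test_perfect_feature_always_included(self, table_factory):
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            n = 200
            y = rng.integers(0, 2, n)
            X = np.column_stack([y.astype(float)] +
                                [rng.normal(size=n) for _ in range(20)])
            t = table_factory(X, y, kinds=("binary",) + ("continuous",) * 20)
            res = lasso_select(t, seed=seed)
            assert "f0" in res.selected

    def test_duplicate_informative_pair_at_least_one_selected(self, table_factory):
        rng = np.random.default_rng(6)
        n = 300
        y = rng.integers(0, 2, n)
        sig = np.where(rng.random(n) < 0.9, y, 1 - y).astype(float)
        X = np.column_stack([sig, sig.copy(), rng.normal(size=(n, 5))])
        t = table_factory(X, y, kinds=("binary", "binary") + ("continuous",) * 5)
        res = lasso_select(t, seed=0)
        # L1 splits exact duplicates arbitrarily; only the disjunction is stable
        assert "f0" in res.selected or "f1" in res.selected

    def test_selection_monotone_in_planted_effect_size(self, table_factory):
        # strengthening the planted signal never drops it from the selection
        n = 300
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, n)
        noise = rng.normal(size=(n, 8))
        flip_draw = rng.random(n)
        present_at = []
        for flip_prob in (0.4, 0.25, 0.1, 0.0):
            sig = np.where(flip_draw < flip_prob, 1 - y, y).astype(float)
            X = np.column_stack([sig, noise])
            t = table_factory(X, y, kinds=("binary",) + ("continuous",) * 8)
            res = lasso_select(t, seed=42)
            present_at.append("f0" in res.selected)
        # once included at some effect size, stays included at every larger one
        first = present_at.index(True) if True in present_at else len(present_at)
        assert all(present_at[first:])

    def test_diagnostics_record_chosen_alpha(self, table_factory):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 80)
        X = rng.normal(size=(80, 3))
        t = table_factory(X, y, kinds=("continuous",) * 3)
        res = lasso_select(t, seed=1)
        assert res.diagnostics["alpha"] in res.diagnostics["alpha_grid"]
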