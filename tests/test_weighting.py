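import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from depselect.weighting import (
    CATEGORICAL_ALGORITHMS,
    CONTINUOUS_ALGORITHMS,
    EnsembleAttributeWeighter,
    WeightTable,
    binarize_weights,
    compute_weight_table,
    ensemble_score,
    pool_weight_tables,
    select_top_k,
    weight_features,
)


def brute_force_relief(X, y01):
    """Independent Relief oracle: explicit loops over instances/neighbours."""
    X = np.asarray(X, dtype=float)
    lo, hi = X.min(axis=0), X.max(axis=0)
    rng = np.where(hi > lo, hi - lo, 1.0)
    Xs = np.where(hi > lo, (X - lo) / rng, 0.0)
    n, p = Xs.shape
    w = np.zeros(p)
    for i in range(n):
        best_hit, best_hit_d = None, np.inf
        best_miss, best_miss_d = None, np.inf
        for j in range(n):
            if j == i:
                continue
            d = sum(abs(Xs[i, f] - Xs[j, f]) for f in range(p))
            if y01[j] == y01[i] and d < best_hit_d:
                best_hit, best_hit_d = j, d
            if y01[j] != y01[i] and d < best_miss_d:
                best_miss, best_miss_d = j, d
        for f in range(p):
            w[f] += abs(Xs[i, f] - Xs[best_miss, f]) - abs(Xs[i, f] - Xs[best_hit, f])
    return w / n


def brute_force_best_split_ig(x, y01):
    """Enumerate every midpoint split and return the best information gain."""
    x = np.asarray(x, dtype=float)
    n = len(x)

    def h(labels):
        if len(labels) == 0:
            return 0.0
        p1 = np.mean(labels)
        if p1 in (0.0, 1.0):
            return 0.0
        return -p1 * np.log2(p1) - (1 - p1) * np.log2(1 - p1)

    best = 0.0
    for t in sorted(set(x))[:-1]:
        left = y01[x <= t]
        right = y01[x > t]
        ig = h(y01) - len(left) / n * h(left) - len(right) / n * h(right)
        best = max(best, ig)
    return best


@pytest.fixture
def perfect_and_constant():
    X = pd.DataFrame(
        {
            "perfect": [1.0, 2.0, 1.5, 1.2, 1.8, 9.0, 8.5, 9.5, 8.8, 9.2],
            "constant": [3.0] * 10,
        }
    )
    y = np.array(["ctl"] * 5 + ["trt"] * 5)
    return X, y


class TestCriterionValues:
    def test_perfect_separator_information_gain_is_one_bit(
        self, perfect_and_constant
    ):
        X, y = perfect_and_constant
        w = weight_features(X, y, "information_gain")
        assert w[0] == pytest.approx(1.0)

    def test_constant_feature_scores_zero_everywhere(self, perfect_and_constant):
        X, y = perfect_and_constant
        for alg in CONTINUOUS_ALGORITHMS:
            w = weight_features(X, y, alg)
            assert w[1] == pytest.approx(0.0, abs=1e-12), alg

    def test_chi_squared_matches_contingency_oracle(self):
        # fixed 6-sample feature: best split at 2.5 -> table [[2,1],[1,2]]
        x = np.array([1.0, 2.0, 3.0, 2.2, 4.0, 5.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        w = weight_features(x[:, None], y, "chi_squared")[0]
        best = 0.0
        for t in sorted(set(x))[:-1]:
            table = np.array(
                [
                    [np.sum((x <= t) & (y == 0)), np.sum((x <= t) & (y == 1))],
                    [np.sum((x > t) & (y == 0)), np.sum((x > t) & (y == 1))],
                ]
            )
            stat = chi2_contingency(table, correction=False).statistic
            best = max(best, stat)
        assert w == pytest.approx(best)

    def test_information_gain_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 5))
        y01 = np.array([0, 1, 0, 1, 1, 0, 1, 0])
        w = weight_features(X, y01, "information_gain")
        for f in range(5):
            assert w[f] == pytest.approx(brute_force_best_split_ig(X[:, f], y01))

    def test_relief_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(6, 2))
        y01 = np.array([0, 0, 0, 1, 1, 1])
        w = weight_features(X, y01, "relief")
        np.testing.assert_allclose(w, brute_force_relief(X, y01))

    def test_relief_overlap_on_categorical_codes(self):
        # 0/1 codes: Manhattan on raw codes equals the overlap metric
        X = np.array(
            [[0, 0], [0, 1], [0, 0], [1, 0], [1, 1], [1, 1]], dtype=float
        )
        y01 = np.array([0, 0, 0, 1, 1, 1])
        w = weight_features(X, y01, "relief")
        np.testing.assert_allclose(w, brute_force_relief(X, y01))
        assert w[0] > w[1]  # first code tracks the class exactly


class TestCriterionProperties:
    @pytest.mark.parametrize("alg", CONTINUOUS_ALGORITHMS)
    def test_class_relabeling_invariance(self, alg):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(10, 6))
        y = np.array(["A"] * 5 + ["B"] * 5)
        y_swapped = np.where(y == "A", "B", "A")
        # the margin solver's |coef| is invariant only up to its tolerance
        tol = {"rtol": 5e-2, "atol": 1e-3} if alg == "svm" else {"rtol": 1e-7}
        np.testing.assert_allclose(
            weight_features(X, y, alg), weight_features(X, y_swapped, alg), **tol
        )

    @pytest.mark.parametrize(
        "alg", ["information_gain", "gini_index", "chi_squared", "uncertainty", "rule"]
    )
    def test_monotone_transform_invariance_of_split_criteria(self, alg):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(10, 4))
        y = np.repeat([0, 1], 5)
        np.testing.assert_allclose(
            weight_features(X, y, alg),
            weight_features(np.exp(X), y, alg),
            atol=1e-12,
        )

    def test_uncertainty_bounded_and_ig_below_class_entropy(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(12, 30))
        y = np.repeat([0, 1], 6)
        su = weight_features(X, y, "uncertainty")
        ig = weight_features(X, y, "information_gain")
        assert np.all((su >= 0) & (su <= 1))
        assert np.all(ig <= 1.0 + 1e-12)  # H(Y) = 1 for balanced classes

    @pytest.mark.parametrize(
        "alg", [a for a in CONTINUOUS_ALGORITHMS if a != "pca"]
    )
    def test_separator_outweighs_random_feature(self, alg):
        wins = 0
        trials = 20
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            X = np.column_stack(
                [np.r_[rng.normal(0, 1, 10), rng.normal(6, 1, 10)],
                 rng.normal(0, 1, 20)]
            )
            y = np.repeat([0, 1], 10)
            w = weight_features(X, y, alg, random_state=seed)
            wins += w[0] > w[1]
        assert wins >= 19, f"{alg}: separator won only {wins}/{trials}"

    def test_pca_loads_class_axis_when_it_dominates(self):
        # PC1 of a standardized matrix tracks shared variance, so the class
        # axis must be carried by several correlated separators to surface
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            shift = np.repeat([0.0, 6.0], 10)
            seps = shift[:, None] + rng.normal(0, 1, (20, 3))
            noise = rng.normal(0, 1, (20, 5))
            X = np.hstack([seps, noise])
            w = weight_features(X, np.repeat([0, 1], 10), "pca")
            wins += w[:3].min() > w[3:].max()
        assert wins >= 19

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            weight_features(np.ones((4, 2)), np.zeros(4), "information_gain")

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown weighting"):
            weight_features(np.ones((4, 2)), [0, 0, 1, 1], "bogus")


class TestVotesAndSelection:
    def test_binarize_scales_then_thresholds(self):
        np.testing.assert_array_equal(
            binarize_weights(np.array([0.0, 5.0, 10.0]), 0.5), [0, 1, 1]
        )

    def test_all_equal_weights_give_no_votes(self):
        np.testing.assert_array_equal(
            binarize_weights(np.array([2.0, 2.0, 2.0]), 0.5), [0, 0, 0]
        )

    def test_threshold_one_selects_only_maximum(self):
        votes = binarize_weights(np.array([1.0, 3.0, 3.0, 2.0]), 1.0)
        np.testing.assert_array_equal(votes, [0, 1, 1, 0])

    def test_ensemble_score_is_row_sum(self):
        votes = pd.DataFrame(
            [[1] * 7 + [0] * 3, [0] * 10],
            index=["P1", "P2"],
            columns=[f"a{i}" for i in range(10)],
        )
        scores = ensemble_score(votes)
        assert scores["P1"] == 7 and scores["P2"] == 0

    def test_pooled_branches_can_reach_27(self):
        idx = pd.Index(["P1"], name="protein_id")
        tables = []
        for branch, algs in (
            ("mean", CONTINUOUS_ALGORITHMS),
            ("ratio", CONTINUOUS_ALGORITHMS),
            ("binomial", CATEGORICAL_ALGORITHMS),
        ):
            cols = [f"{branch}:{a}" for a in algs]
            tables.append(
                WeightTable(
                    pd.DataFrame(1.0, index=idx, columns=cols),
                    pd.DataFrame(1, index=idx, columns=cols, dtype=np.int8),
                )
            )
        pooled = pool_weight_tables(tables)
        assert pooled.n_algorithms == 27
        assert pooled.scores["P1"] == 27

    def test_top_k_exact_size_and_score_dominance(self):
        rng = np.random.default_rng(0)
        ids = [f"P{i:04d}" for i in range(500)]
        scores = pd.Series(rng.permutation(500), index=ids)
        top = select_top_k(scores, 200)
        assert len(top) == 200
        assert min(scores[p] for p in top) > max(
            scores[p] for p in set(ids) - set(top)
        )

    def test_top_k_is_identity_at_full_size(self):
        scores = pd.Series([3, 1, 2], index=["P1", "P2", "P3"])
        assert set(select_top_k(scores, 3)) == {"P1", "P2", "P3"}

    def test_boundary_tie_broken_by_weight_then_id(self):
        scores = pd.Series([5, 3, 3, 3], index=["P1", "P2", "P3", "P4"])
        tie = pd.Series([0.0, 0.1, 0.9, 0.1], index=scores.index)
        top = select_top_k(scores, 2, tie)
        assert top == ["P1", "P3"]
        # equal weights fall back to lexicographic id
        tie_flat = pd.Series(0.0, index=scores.index)
        assert select_top_k(scores, 2, tie_flat) == ["P1", "P2"]

    def test_k_above_protein_count_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            select_top_k(pd.Series([1], index=["P1"]), 2)


class TestEnsembleEstimator:
    def test_sklearn_selector_contract(self, perfect_and_constant):
        X, y = perfect_and_constant
        est = EnsembleAttributeWeighter(top_k=1).fit(X, y)
        assert est.scores_["perfect"] > est.scores_["constant"]
        assert est.get_support().sum() == 1
        reduced = est.transform(X)
        assert reduced.shape == (10, 1)
        params = est.get_params()
        assert params["top_k"] == 1

    def test_weight_table_round_numbers(self, perfect_and_constant):
        X, y = perfect_and_constant
        table = compute_weight_table(X, y, branch="mean")
        assert table.raw_weights.shape == (2, 10)
        assert set(table.votes.to_numpy().ravel()) <= {0, 1}
        assert list(table.raw_weights.columns)[0] == "mean:information_gain"
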