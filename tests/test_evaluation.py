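"""Rank tests, ROC/AUC, cutoffs, cross-validation, bootstrap, correlation,
and 2x2 categorical tests, checked against enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

import uromir as u
from uromir.errors import EvaluationError


def mw_oracle(x, y):
    """Independent Mann-Whitney oracle: U by pairwise comparison, two-sided
    p by explicit enumeration of all group assignments of the pooled data."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(a, b):
        return sum(
            1.0 if xi > yi else 0.5 if xi == yi else 0.0 for xi in a for yi in b
        )

    mu = n1 * (len(pooled) - n1) / 2.0
    dev = abs(u_stat(x, y) - mu)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in comb]
        b = [pooled[i] for i in range(len(pooled)) if i not in comb]
        total += 1
        if abs(u_stat(a, b) - mu) >= dev - 1e-9:
            hits += 1
    return u_stat(x, y), hits / total


class TestMannWhitney:
    def test_separated_three_vs_three(self):
        res = u.mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)  # 2 / C(6,3)
        assert res.statistic_value == 0.0

    def test_identical_multisets(self):
        res = u.mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0
        assert res.statistic_value == pytest.approx(9 / 2)  # n^2/2

    def test_ties_match_full_permutation_oracle(self):
        x, y = [1, 2, 2, 3], [2, 3, 4, 5]
        res = u.mann_whitney(x, y)
        u_exp, p_exp = mw_oracle(x, y)
        assert res.statistic_value == pytest.approx(u_exp)
        assert res.p_value == pytest.approx(p_exp)

    def test_exact_matches_oracle_on_random_small_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n1 = int(rng.integers(1, 6))
            n2 = int(rng.integers(1, 6))
            x = rng.integers(0, 6, n1).astype(float)
            y = rng.integers(0, 6, n2).astype(float)
            u_exp, p_exp = mw_oracle(x, y)
            res = u.mann_whitney(x, y)
            assert res.statistic_value == pytest.approx(u_exp)
            assert res.p_value == pytest.approx(p_exp)

    def test_empty_input_rejected(self):
        with pytest.raises(EvaluationError):
            u.mann_whitney([], [1.0])

    def test_large_sample_p_capped_and_two_sided(self):
        rng = np.random.default_rng(1)
        res = u.mann_whitney(rng.normal(0, 1, 50), rng.normal(0, 1, 60))
        assert res.method == "asymptotic"
        assert 0.0 <= res.p_value <= 1.0


class TestRocAuc:
    def test_perfect_separation(self):
        assert u.auc_from_scores([4, 5, 6], [1, 2, 3]) == 1.0

    def test_full_tie_mass(self):
        assert u.auc_from_scores([1, 2, 3], [1, 2, 3]) == 0.5

    def test_three_of_four_pairwise_wins(self):
        assert u.auc_from_scores([3, 5], [1, 4]) == 0.75

    def test_auc_u_identity(self):
        """AUC equals U/(n1*n2) on 1000 random instances to 1e-12."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n1 = int(rng.integers(1, 20))
            n2 = int(rng.integers(1, 20))
            case = np.round(rng.normal(0, 1, n1), 1)  # rounding induces ties
            ctrl = np.round(rng.normal(0, 1, n2), 1)
            ranks = rankdata(np.concatenate([case, ctrl]))
            u_stat = ranks[:n1].sum() - n1 * (n1 + 1) / 2
            assert abs(u.auc_from_scores(case, ctrl) - u_stat / (n1 * n2)) < 1e-12

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-50, 50).map(lambda x: round(x, 2)),
                 min_size=1, max_size=15),
        st.lists(st.floats(-50, 50).map(lambda x: round(x, 2)),
                 min_size=1, max_size=15),
    )
    def test_monotone_invariance_and_complement_symmetry(self, case, ctrl):
        a = u.auc_from_scores(case, ctrl)
        transform = lambda v: np.exp(np.asarray(v) / 25.0)
        assert u.auc_from_scores(transform(case), transform(ctrl)) == pytest.approx(
            a, abs=1e-12
        )
        assert u.auc_from_scores(ctrl, case) == pytest.approx(1 - a, abs=1e-12)

    def test_roc_result_invariants(self):
        rng = np.random.default_rng(3)
        res = u.roc_auc(rng.normal(1, 1, 30), rng.normal(0, 1, 40), n_boot=200)
        assert res.ci_low <= res.auc <= res.ci_high
        assert res.n_case == 30 and res.n_control == 40
        analytic = u.roc_auc(
            rng.normal(1, 1, 30), rng.normal(0, 1, 40), ci_method="hanley-mcneil"
        )
        assert analytic.ci_low <= analytic.auc <= analytic.ci_high


class TestOptimalCutoff:
    def test_perfect_separation_sens_spec_one(self):
        cutoff, sens, spec = u.optimal_cutoff([4, 5, 6], [1, 2, 3])
        assert sens == 1.0 and spec == 1.0
        assert 3 < cutoff < 4

    def test_matches_exhaustive_search(self):
        case, ctrl = [2.0, 3.0, 4.0], [1.0, 2.0, 3.0]
        cutoff, sens, spec = u.optimal_cutoff(case, ctrl)
        # independent sweep over a fine threshold grid
        best_j = max(
            np.mean(np.array(case) >= c) + np.mean(np.array(ctrl) < c) - 1
            for c in np.linspace(0, 5, 2001)
        )
        assert sens + spec - 1 == pytest.approx(best_j)
        assert (sens, spec) == (1.0, 1 / 3)
        assert cutoff == pytest.approx(1.5)

    def test_degenerate_all_equal(self):
        cutoff, sens, spec = u.optimal_cutoff([1.0, 1.0], [1.0, 1.0, 1.0])
        assert (sens, spec) == (1.0, 0.0)
        assert cutoff == 1.0

    def test_youden_never_beaten_by_any_threshold(self):
        """Property: the returned cutoff attains the maximal J over an
        exhaustive sweep, on 300 random instances."""
        rng = np.random.default_rng(11)
        for _ in range(300):
            case = np.round(rng.normal(0.5, 1, int(rng.integers(2, 12))), 1)
            ctrl = np.round(rng.normal(0, 1, int(rng.integers(2, 12))), 1)
            cutoff, sens, spec = u.optimal_cutoff(case, ctrl)
            j = sens + spec - 1
            grid = np.concatenate([np.unique(np.concatenate([case, ctrl])), [99.0]])
            for c in np.concatenate([grid - 1e-6, grid + 1e-6]):
                j_c = np.mean(case >= c) + np.mean(ctrl < c) - 1
                assert j_c <= j + 1e-12


class TestBootstrap:
    def test_constant_statistic_degenerate_interval(self):
        ci = u.bootstrap_ci(lambda *groups: 3.5, [[1, 2, 3]], B=200, seed=0)
        assert (ci.low, ci.high) == (3.5, 3.5)

    def test_seeded_determinism(self):
        data = [np.random.default_rng(0).normal(0, 1, 40)]
        a = u.bootstrap_ci(lambda g: float(np.mean(g)), data, B=300, seed=5)
        b = u.bootstrap_ci(lambda g: float(np.mean(g)), data, B=300, seed=5)
        assert (a.low, a.high) == (b.low, b.high)

    def test_undefined_resamples_redrawn_and_counted(self):
        calls = {"n": 0}

        def flaky(g):
            calls["n"] += 1
            if calls["n"] % 5 == 0:
                return math.nan
            return float(np.mean(g))

        ci = u.bootstrap_ci(flaky, [[1.0, 2.0, 3.0]], B=100, seed=1)
        assert ci.n_redrawn > 0
        assert np.isfinite(ci.low) and np.isfinite(ci.high)

    def test_endpoints_monotone_in_level(self):
        data = [np.random.default_rng(2).normal(0, 1, 50)]
        stat = lambda g: float(np.mean(g))
        narrow = u.bootstrap_ci(stat, data, B=500, level=0.80, seed=3)
        wide = u.bootstrap_ci(stat, data, B=500, level=0.99, seed=3)
        assert wide.low <= narrow.low and narrow.high <= wide.high


class TestKfold:
    def scores_labels(self, n_case=40, n_ctrl=60, delta=1.0, seed=0):
        rng = np.random.default_rng(seed)
        scores = np.concatenate(
            [rng.normal(delta, 1, n_case), rng.normal(0, 1, n_ctrl)]
        )
        labels = np.r_[np.ones(n_case), np.zeros(n_ctrl)]
        return scores, labels

    def test_perfect_separation_every_fold(self):
        scores = np.r_[np.ones(10) + 5, np.zeros(15)]
        labels = np.r_[np.ones(10), np.zeros(15)]
        cv = u.kfold_cross_validate(scores, labels, k=5, seed=1, n_boot=0)
        assert cv.fold_train_aucs == [1.0] * 5
        assert cv.fold_test_aucs == [1.0] * 5
        assert cv.mean_test_auc == 1.0

    def test_mean_is_arithmetic_mean_of_folds(self):
        cv = u.kfold_cross_validate(*self.scores_labels(), k=5, seed=2, n_boot=0)
        assert cv.mean_test_auc == pytest.approx(
            np.mean(cv.fold_test_aucs), abs=1e-12
        )
        assert cv.mean_train_auc == pytest.approx(
            np.mean(cv.fold_train_aucs), abs=1e-12
        )
        assert len(cv.fold_test_aucs) == 5

    def test_class_smaller_than_k_rejected(self):
        scores = np.r_[np.ones(3), np.zeros(30)]
        labels = np.r_[np.ones(3), np.zeros(30)]
        with pytest.raises(EvaluationError):
            u.kfold_cross_validate(scores, labels, k=5, seed=0, n_boot=0)

    def test_bootstrap_ci_brackets_point_estimate(self):
        cv = u.kfold_cross_validate(*self.scores_labels(), k=5, seed=4, n_boot=200)
        lo, hi = cv.boot_ci_test
        assert lo <= cv.mean_test_auc <= hi
        assert cv.n_boot == 200


class TestSpearman:
    def test_perfect_concordance_discordance(self):
        assert u.spearman([1, 2, 3, 4], [2, 4, 6, 8]).r == pytest.approx(1.0)
        assert u.spearman([1, 2, 3, 4], [8, 6, 4, 2]).r == pytest.approx(-1.0)

    def test_midrank_formula_hand_value(self):
        res = u.spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.r == pytest.approx(0.8)
        assert res.n == 4

    def test_zero_rank_variance_flagged(self):
        with pytest.raises(EvaluationError, match="rank variance"):
            u.spearman([1, 2, 3], [5, 5, 5])


class TestCategorical:
    def test_sex_table_fisher_mode(self):
        """A 15/135 vs 4/39 female/male split sits at the hypergeometric
        mode, so the two-sided exact p is 1.000."""
        res = u.categorical_test([[15, 135], [4, 39]])
        assert res.method == "fisher_exact"
        assert res.p_value == pytest.approx(1.0, abs=5e-4)

    def test_two_extreme_tables(self):
        res = u.categorical_test([[10, 0], [0, 10]])
        assert res.method == "fisher_exact"
        assert res.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_symmetric_table_no_association(self):
        assert u.categorical_test([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_chi_square_branch_when_expected_large(self):
        res = u.categorical_test([[30, 10], [12, 28]])
        assert res.method == "pearson_chi2"
        assert res.p_value < 0.01

    def test_all_zero_rejected(self):
        with pytest.raises(EvaluationError):
            u.categorical_test([[0, 0], [0, 0]])
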