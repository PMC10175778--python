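import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dwihist import stats as st


class TestKSNormality:
    def test_null_p_values_roughly_uniform(self):
        """Lilliefors p on normal samples: ecdf close to uniform."""
        rng = np.random.default_rng(0)
        pvals = [st.ks_normality(rng.normal(2, 3, 80)).p_value
                 for _ in range(400)]
        grid = np.linspace(0.1, 0.9, 9)
        ecdf = [(np.asarray(pvals) <= g).mean() for g in grid]
        # table-interpolated Lilliefors p is mildly conservative; the
        # bound still rules out the naive KS reference (deviation ~0.4)
        assert np.max(np.abs(np.asarray(ecdf) - grid)) < 0.12

    def test_power_against_heavy_tails(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            st.ks_normality(rng.standard_t(2, 500), alpha=0.05).p_value < 0.05
            for _ in range(60))
        assert rejections >= 57  # >= 95% power

    def test_small_and_constant_samples_rejected(self):
        with pytest.raises(ValueError):
            st.ks_normality([1.0, 2.0])
        with pytest.raises(ValueError):
            st.ks_normality([3.0] * 10)


class TestMannWhitney:
    def test_exact_enumeration_example(self):
        """{1,2,3} vs {4,5,6}: U=0 and exact two-sided p = 2/20 = 0.1."""
        res = st.mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        np.testing.assert_allclose(res.p_value, 0.1)
        # independent oracle: enumerate all 20 label assignments
        pooled = np.array([1, 2, 3, 4, 5, 6])
        u_obs = 0.0
        us = []
        for idx in itertools.combinations(range(6), 3):
            a = pooled[list(idx)]
            b = pooled[[i for i in range(6) if i not in idx]]
            u = sum((x > y) for x in a for y in b)
            us.append(min(u, 9 - u))
        p_exact = np.mean([u <= min(u_obs, 9 - u_obs) for u in us])
        np.testing.assert_allclose(res.p_value, p_exact)

    def test_identical_groups_symmetry_point(self):
        res = st.mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == 8.0  # n1*n2/2
        np.testing.assert_allclose(res.p_value, 1.0)

    def test_rank_invariance_under_monotone_transform(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 18)
        r1 = st.mann_whitney(a, b)
        r2 = st.mann_whitney(np.exp(a), np.exp(b))
        assert r1.statistic == r2.statistic
        np.testing.assert_allclose(r1.p_value, r2.p_value)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            st.mann_whitney([], [1.0])

    def test_type_i_error_near_alpha_under_null(self):
        """Rejection rate within alpha +/- 2*SE over 5000 null replicates."""
        rng = np.random.default_rng(42)
        alpha, n_rep = 0.05, 5000
        rejections = 0
        for _ in range(n_rep):
            a, b = rng.normal(size=12), rng.normal(size=12)
            rejections += st.mann_whitney(a, b, alpha=alpha).significant
        rate = rejections / n_rep
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rate - alpha) < 2.5 * se


class TestSpearman:
    def test_monotone_and_reversed(self):
        x = np.array([0.5, 1.0, 2.0, 3.5])
        assert st.spearman_correlation(x, x ** 3).statistic == 1.0
        assert st.spearman_correlation(x, -x).statistic == -1.0

    def test_binary_label_example_matches_rank_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([0, 0, 1, 1])
        res = st.spearman_correlation(x, y)
        # brute-force Pearson on midranks
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        np.testing.assert_allclose(res.statistic, expected, rtol=1e-12)

    def test_constant_inputs_rejected(self):
        with pytest.raises(ValueError):
            st.spearman_correlation([1, 1, 1], [0, 1, 0])


class TestROCAUC:
    def test_perfect_separation_and_flip(self):
        y = [0, 0, 1, 1]
        assert st.roc_auc_single([1, 2, 3, 4], y).auc == 1.0
        assert st.roc_auc_single([1, 2, 3, 4], [1, 1, 0, 0]).auc == 0.0

    def test_worked_pair_counting_example(self):
        res = st.roc_auc_single([1, 3, 2, 4], [0, 0, 1, 1])
        np.testing.assert_allclose(res.auc, 0.75)  # 3 of 4 concordant pairs

    def test_label_flip_symmetry(self, rng):
        x = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        a1 = st.roc_auc_single(x, y).auc
        a2 = st.roc_auc_single(x, 1 - y).auc
        np.testing.assert_allclose(a1 + a2, 1.0)

    def test_orientation_not_folded(self):
        """A marker running lower in positives reports AUC < 0.5 as-is."""
        res = st.roc_auc_single([1, 2, 3, 4], [1, 1, 0, 0])
        assert res.auc < 0.5
        flipped = st.roc_auc_single([1, 2, 3, 4], [1, 1, 0, 0],
                                    positive_direction="less")
        np.testing.assert_allclose(flipped.auc, 1 - res.auc)

    def test_auc_equals_u_over_n1n2(self, rng):
        """Mann-Whitney duality with half-weight ties, random instances."""
        for _ in range(50):
            n1, n2 = rng.integers(3, 20, 2)
            x = np.concatenate([rng.integers(0, 8, n1),
                                rng.integers(0, 8, n2)]).astype(float)
            y = np.concatenate([np.ones(n1, int), np.zeros(n2, int)])
            auc = st.roc_auc_single(x, y).auc
            u = sps.mannwhitneyu(x[y == 1], x[y == 0],
                                 alternative="two-sided").statistic
            np.testing.assert_allclose(auc, u / (n1 * n2), rtol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            st.roc_auc_single([1, 2, 3], [1, 1, 1])


class TestBestMetricSelection:
    @staticmethod
    def _table(values):
        return pd.DataFrame(values, index=list(st.TIE_ORDER))

    def test_unique_max_selected(self):
        tab = self._table({"ADC": [0.7, 0.76, 0.71, 0.7, 0.5, 0.51]})
        assert st.select_best_metric_per_parameter(tab)["ADC"] == "median"

    def test_tie_broken_by_fixed_order(self):
        tab = self._table({"D": [0.7, 0.7, 0.6, 0.6, 0.5, 0.5]})
        assert st.select_best_metric_per_parameter(tab)["D"] == "mean"
        tab2 = self._table({"D": [0.6, 0.6, 0.6, 0.7, 0.7, 0.7]})
        # tie between 75th / kurtosis / skewness -> 75th (earliest in order)
        assert st.select_best_metric_per_parameter(tab2)["D"] == "75th"

    def test_exhaustive_pairwise_ties(self):
        order = list(st.TIE_ORDER)
        for i, j in itertools.combinations(range(6), 2):
            col = [0.5] * 6
            col[i] = col[j] = 0.8
            tab = self._table({"X": col})
            assert st.select_best_metric_per_parameter(tab)["X"] == order[i]

    def test_missing_metric_rejected(self):
        tab = pd.DataFrame({"ADC": [0.6] * 5},
                           index=["mean", "median", "25th", "75th", "kurtosis"])
        with pytest.raises(ValueError):
            st.select_best_metric_per_parameter(tab)


class TestLogisticCombination:
    def test_single_predictor_preserves_auc(self, rng):
        x = rng.normal(size=100) + np.repeat([0, 1.0], 50)
        y = np.repeat([0, 1], 50)
        base = st.roc_auc_single(x, y).auc
        _, roc, _, _ = st.fit_logistic_combination(pd.DataFrame({"x": x}), y)
        np.testing.assert_allclose(roc.auc, base, rtol=1e-12)

    def test_jointly_informative_predictors(self):
        """Each predictor is ~chance alone; their sum separates almost
        perfectly, and the logistic combination finds it."""
        rng = np.random.default_rng(3)
        n = 400
        u = rng.normal(size=n)
        v = rng.normal(scale=4.0, size=n)
        y = (u > 0).astype(int)
        X = pd.DataFrame({"x1": u + v, "x2": -v})
        a1 = st.roc_auc_single(X["x1"], y).auc
        a2 = st.roc_auc_single(X["x2"], y).auc
        assert abs(a1 - 0.5) < 0.12 and abs(a2 - 0.5) < 0.12
        _, roc, _, _ = st.fit_logistic_combination(X, y)
        assert roc.auc > 0.9

    def test_recovers_generating_signs(self):
        rng = np.random.default_rng(8)
        n = 2000
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        beta = np.array([1.5, -2.0, 0.8])
        logits = X.to_numpy() @ beta - 0.3
        y = rng.random(n) < 1 / (1 + np.exp(-logits))
        _, _, params, sep = st.fit_logistic_combination(X, y.astype(int))
        assert not sep
        assert np.all(np.sign(params[list("abc")]) == np.sign(beta))

    def test_perfect_separation_flagged_not_silent(self):
        y = np.repeat([0, 1], 20)
        x = np.concatenate([np.linspace(0, 1, 20), np.linspace(2, 3, 20)])
        scores, roc, _, sep = st.fit_logistic_combination(
            pd.DataFrame({"x": x}), y)
        assert sep and roc.auc == 1.0

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            st.fit_logistic_combination(pd.DataFrame({"x": np.ones(10)}),
                                        np.repeat([0, 1], 5))

    def test_combined_at_least_single_when_one_model_has_signal(self):
        rng = np.random.default_rng(9)
        n = 300
        y = rng.integers(0, 2, n)
        signal = rng.normal(size=n) + 1.2 * y
        noise = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("uvw"))
        single = st.roc_auc_single(signal, y).auc
        X = pd.concat([pd.Series(signal, name="s"), noise], axis=1)
        _, roc, _, _ = st.fit_logistic_combination(X, y)
        assert roc.auc >= single - 0.01


def _rank_auc(x, y):
    r = sps.rankdata(x)
    m = (y == 1).sum()
    return (r[y == 1].sum() - m * (m + 1) / 2) / (m * (y == 0).sum())


class TestDeLong:
    def test_self_comparison_is_null(self, rng):
        x = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        res = st.delong_compare(x, x, y)
        assert res.difference == 0.0 and res.p_value == 1.0

    def test_variance_positive_for_distinct_scores(self, rng):
        y = np.repeat([0, 1], 30)
        a = rng.normal(size=60) + y
        b = rng.normal(size=60) + 0.5 * y
        res = st.delong_compare(a, b, y)
        assert res.z != 0.0 and 0.0 <= res.p_value <= 1.0

    def test_against_bootstrap_oracle(self):
        """DeLong p consistent with a paired-bootstrap z of the AUC diff."""
        rng = np.random.default_rng(14)
        n = 120
        y = np.repeat([0, 1], n // 2)
        a = rng.normal(size=n) + 1.0 * y
        b = rng.normal(size=n) + 0.6 * y
        res = st.delong_compare(a, b, y)
        diffs = []
        for _ in range(3000):
            idx = np.concatenate([
                rng.choice(np.where(y == 0)[0], n // 2),
                rng.choice(np.where(y == 1)[0], n // 2)])
            diffs.append(_rank_auc(a[idx], y) - _rank_auc(b[idx], y))
        z_boot = res.difference / np.std(diffs, ddof=1)
        p_boot = 2 * sps.norm.sf(abs(z_boot))
        assert abs(res.p_value - p_boot) < 0.06

    def test_mismatched_lengths_and_degenerate_classes_rejected(self):
        with pytest.raises(ValueError):
            st.delong_compare([1, 2], [1, 2, 3], [0, 1, 1])
        with pytest.raises(ValueError):
            st.delong_compare([1, 2, 3], [1, 2, 3], [0, 0, 1])  # 1 positive


class TestChiSquared:
    def test_margin_by_er_table(self):
        """Printed margin-by-ER counts give p rounding to 0.002."""
        res = st.chi_squared_morphology(table=[[52, 13, 15], [31, 4, 28]])
        assert res.dof == 2
        assert round(res.p_value, 3) == 0.002

    def test_shape_by_er_table(self):
        res = st.chi_squared_morphology(table=[[11, 37, 32], [13, 18, 32]])
        assert round(res.p_value, 3) == 0.092

    def test_homogeneous_rows_null(self):
        res = st.chi_squared_morphology(table=[[10, 20, 30], [20, 40, 60]])
        np.testing.assert_allclose(res.statistic, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.p_value, 1.0)

    def test_low_expected_cell_flagged(self):
        res = st.chi_squared_morphology(table=[[2, 30, 3], [3, 28, 2]])
        assert res.low_expected

    def test_matches_permutation_oracle_on_small_table(self):
        """Asymptotic p within Monte-Carlo error of a permutation p."""
        rng = np.random.default_rng(21)
        codes = np.array([1] * 20 + [2] * 25 + [3] * 15)
        contrast = (rng.random(60) < 0.4 + 0.3 * (codes == 3)).astype(int)
        res = st.chi_squared_morphology(codes, contrast)
        n_perm, hits = 4000, 0
        for _ in range(n_perm):
            perm = rng.permutation(contrast)
            stat = sps.chi2_contingency(
                pd.crosstab(perm, codes).to_numpy(), correction=False)[0]
            hits += stat >= res.statistic - 1e-12
        p_perm = hits / n_perm
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(res.p_value - p_perm) < max(4 * se, 0.02)

    def test_from_label_vectors(self):
        codes = [1, 1, 2, 2, 3, 3, 1, 2]
        contrast = [0, 1, 0, 1, 0, 1, 0, 1]
        res = st.chi_squared_morphology(codes, contrast)
        assert res.table.sum() == 8

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            st.chi_squared_morphology(table=[[0, 0, 0], [0, 0, 0]])


class TestICC:
    def test_identical_readers_excellent(self):
        x = np.linspace(0, 10, 30)
        res = st.icc_two_reader(x, x)
        np.testing.assert_allclose(res.icc, 1.0, atol=1e-9)
        assert res.band == "excellent"

    def test_variance_components_nine_to_one(self):
        """Subject var 9, reader-error var 1: ICC(2,1) ~ 0.9 (n=500)."""
        rng = np.random.default_rng(6)
        subjects = rng.normal(0, 3.0, 500)
        r1 = subjects + rng.normal(0, 1.0, 500)
        r2 = subjects + rng.normal(0, 1.0, 500)
        res = st.icc_two_reader(r1, r2)
        assert abs(res.icc - 0.9) < 0.03

    def test_band_thresholds(self):
        rng = np.random.default_rng(16)
        subjects = rng.normal(0, 1.0, 800)
        r1 = subjects + rng.normal(0, 1.0, 800)
        r2 = subjects + rng.normal(0, 1.0, 800)  # true ICC = 0.5
        res = st.icc_two_reader(r1, r2)
        assert res.band == "fair"
        # band edges per the fixed 0.40 / 0.60 / 0.75 thresholds
        assert st.ICCResult(0.39, (0, 1), 10).band == "poor"
        assert st.ICCResult(0.60, (0, 1), 10).band == "good"
        assert st.ICCResult(0.75, (0, 1), 10).band == "excellent"

    def test_constant_or_short_input_rejected(self):
        with pytest.raises(ValueError):
            st.icc_two_reader([1, 2, 3, 4], [1, 2, 3, 4])
        with pytest.raises(ValueError):
            st.icc_two_reader([2] * 10, [2] * 10)


class TestSignificanceThreshold:
    def test_default_alpha_is_bonferroni_over_eight(self):
        assert st.DEFAULT_ALPHA == 0.05 / 8 == 0.00625

    def test_strict_inequality_at_boundary(self):
        r_below = st.TestResult(0.0, 0.00624, (10,))
        r_at = st.TestResult(0.0, 0.00625, (10,))
        assert r_below.significant
        assert not r_at.significant

    def test_reflagging_at_custom_alpha(self):
        r = st.TestResult(0.0, 0.03, (10,))
        assert not r.significant
        assert st.apply_significance_threshold(r, alpha=0.05).significant
        with pytest.raises(ValueError):
            st.apply_significance_threshold(r, alpha=1.5)

    def test_contrast_labels_cover_all_eight(self):
        from dwihist.phantom import CohortConfig, cohort_to_frame, sample_cohort
        frame = cohort_to_frame(sample_cohort(CohortConfig(n_screened=60),
                                              seed=0))
        labels = st.contrast_labels(frame)
        assert list(labels.columns) == list(st.CONTRASTS)
        assert ((labels == 0) | (labels == 1)).all().all()
        # Luminal + TN + HER2type partition checks
        assert (labels["Luminal"] + labels["TN"] + labels["HER2type"] == 1).all()
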