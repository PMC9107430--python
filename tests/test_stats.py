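"""Group statistics: GLM comparisons, paired tests, mixed model, correlations."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from fcreact.stats import (adjusted_group_comparison, bonferroni_threshold,
                           demographic_comparison, mixed_interaction,
                           network_summary_report, paired_comparison,
                           partial_correlation)


def _covariates(rng, n):
    return pd.DataFrame({
        "age": rng.normal(60, 9, n),
        "gender": (rng.random(n) < 0.6).astype(float),
        "education": rng.normal(9, 4, n),
    })


class TestAdjustedGroupComparison:
    def test_reduces_to_pooled_t_test_without_covariates(self, rng):
        y = rng.standard_normal(40)
        g = np.repeat(["a", "b"], 20)
        res = adjusted_group_comparison(y, g, None)
        t, p = sps.ttest_ind(y[g == "b"], y[g == "a"], equal_var=True)
        assert res.statistic == pytest.approx(t, abs=1e-8)
        assert res.p == pytest.approx(p, abs=1e-8)

    def test_zero_variance_covariate_dropped_then_reduces_to_t(self, rng):
        y = rng.standard_normal(30)
        g = np.repeat(["a", "b"], 15)
        cov = pd.DataFrame({"age": np.zeros(30)})
        with pytest.warns(UserWarning, match="zero-variance"):
            res = adjusted_group_comparison(y, g, cov)
        t, _ = sps.ttest_ind(y[g == "b"], y[g == "a"], equal_var=True)
        assert res.statistic == pytest.approx(t, abs=1e-8)

    def test_power_for_one_sd_shift(self):
        hits = 0
        for s in range(200):
            rng = np.random.default_rng(s)
            y = rng.standard_normal(52)
            g = np.repeat(["a", "b"], 26)
            y[g == "b"] += 1.0
            res = adjusted_group_comparison(y, g, _covariates(rng, 52))
            hits += res.significant
        assert hits >= 0.9 * 200

    def test_type_one_error_calibrated_under_permutation(self):
        hits = 0
        n_sim = 1000
        for s in range(n_sim):
            rng = np.random.default_rng(10_000 + s)
            y = rng.standard_normal(40)
            g = rng.permutation(np.repeat(["a", "b"], 20))
            res = adjusted_group_comparison(y, g, None)
            hits += res.p < 0.05
        assert 0.03 <= hits / n_sim <= 0.07

    def test_collinear_design_names_column(self, rng):
        y = rng.standard_normal(20)
        g = np.repeat(["a", "b"], 10)
        cov = pd.DataFrame({"age": np.repeat([0.0, 1.0], 10)})  # aliases group
        with pytest.raises(ValueError, match="aliased"):
            adjusted_group_comparison(y, g, cov)


class TestPairedComparison:
    def test_identical_sessions_degenerate(self):
        x = np.arange(10.0)
        res = paired_comparison(x, x)
        assert res.p == 1.0 and res.branch == "degenerate"

    def test_normal_differences_use_paired_t_and_reject(self):
        branches, hits = [], 0
        for s in range(200):
            rng = np.random.default_rng(s)
            off = rng.standard_normal(28)
            on = off + rng.normal(0.5, 1.0, 28)
            res = paired_comparison(off, on)
            branches.append(res.branch)
            hits += res.significant
        assert branches.count("paired_t") > 100
        assert hits >= 0.6 * 200

    def test_heavy_tailed_differences_prefer_wilcoxon(self):
        wilcoxon = 0
        for s in range(200):
            rng = np.random.default_rng(1000 + s)
            off = rng.standard_normal(28)
            on = off + rng.standard_t(2, 28)
            wilcoxon += paired_comparison(off, on).branch == "wilcoxon"
        assert wilcoxon > 100


class TestDemographicComparison:
    def test_gender_table_chi_square_hand_value(self):
        # 2x2 counts [[14, 10], [19, 9]]: chi2 = 0.506, p = 0.477
        gender = ["M"] * 14 + ["F"] * 10 + ["M"] * 19 + ["F"] * 9
        group = ["resistant"] * 24 + ["responsive"] * 28
        res = demographic_comparison(gender, group, "categorical")
        assert res.statistic == pytest.approx(0.506, abs=5e-4)
        assert res.p == pytest.approx(0.477, abs=5e-4)

    def test_identical_samples_give_p_one_in_t_branch(self, rng):
        x = rng.normal(10, 2, 25)
        vals = np.r_[x, x]
        grp = np.repeat(["a", "b"], 25)
        res = demographic_comparison(vals, grp, "continuous")
        assert res.branch == "t_test"
        assert res.p == pytest.approx(1.0)

    def test_unit_shift_detected(self):
        hits = 0
        for s in range(200):
            rng = np.random.default_rng(s)
            vals = np.r_[rng.normal(0, 1, 25), rng.normal(1, 1, 25)]
            grp = np.repeat(["a", "b"], 25)
            hits += demographic_comparison(vals, grp, "continuous").significant
        assert hits >= 0.9 * 200

    def test_three_groups_use_kruskal_wallis(self, rng):
        vals = rng.standard_normal(60)
        grp = np.repeat(["a", "b", "c"], 20)
        res = demographic_comparison(vals, grp, "continuous")
        assert res.branch == "kruskal_wallis"

    def test_empty_group_rejected(self, rng):
        with pytest.raises(ValueError):
            demographic_comparison([1.0, 2.0], ["a", "a"], "continuous")


class TestMixedInteraction:
    def test_estimate_equals_difference_of_differences(self, rng):
        n = 20
        g = np.repeat(["a", "b"], n // 2)
        off = rng.standard_normal(n)
        on = off + rng.standard_normal(n) * 0.3
        on[g == "b"] += 0.4
        res = mixed_interaction(off, on, g)
        dod = (np.mean(on[g == "b"] - off[g == "b"])
               - np.mean(on[g == "a"] - off[g == "a"]))
        assert res.estimate == pytest.approx(dod, abs=1e-8)

    def test_group_specific_shift_detected(self, rng):
        g = np.r_[np.repeat(["resistant"], 24), np.repeat(["responsive"], 28)]
        subj = rng.normal(0.16, 0.17, 52)
        off = subj + rng.normal(0, 0.10, 52)
        on = subj + rng.normal(0, 0.10, 52)
        on[g == "responsive"] -= 0.15
        res = mixed_interaction(off, on, g, _covariates(rng, 52))
        assert res.branch in ("mixed_model", "fallback_t_on_differences")
        assert res.significant


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        x = rng.standard_normal(50)
        y = 0.4 * x + rng.standard_normal(50)
        r, p = partial_correlation(x, y)
        rr, pp = sps.pearsonr(x, y)
        assert r == pytest.approx(rr, abs=1e-10)
        assert p == pytest.approx(pp, abs=1e-8)

    def test_known_partial_correlation_recovered(self):
        # x and y share a confounder c; after removing c the partial corr is 0.5
        rng = np.random.default_rng(7)
        n = 5000
        c = rng.standard_normal(n)
        e1 = rng.standard_normal(n)
        e2 = 0.5 * e1 + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        x = 0.8 * c + e1
        y = 0.8 * c + e2
        r, _ = partial_correlation(x, y, pd.DataFrame({"c": c}))
        assert r == pytest.approx(0.5, abs=0.03)

    def test_symmetry(self, rng):
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        cov = _covariates(rng, 40)
        assert partial_correlation(x, y, cov)[0] == \
            pytest.approx(partial_correlation(y, x, cov)[0], abs=1e-12)

    def test_matches_pingouin_reference(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.standard_normal(60)
        y = 0.3 * x + rng.standard_normal(60)
        cov = _covariates(rng, 60)
        df = cov.assign(x=x, y=y)
        ref = pingouin.partial_corr(df, x="x", y="y",
                                    covar=["age", "gender", "education"])
        r, p = partial_correlation(x, y, cov)
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_perfect_residual_correlation(self, rng):
        x = rng.standard_normal(30)
        r, p = partial_correlation(x, x.copy())
        assert r == pytest.approx(1.0)


class TestBonferroni:
    @pytest.mark.parametrize("alpha, m, expected",
                             [(0.05, 2, 0.025), (0.05, 1, 0.05), (0.05, 5, 0.01)])
    def test_threshold(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestNetworkSummary:
    def _frames(self, rng, da_shift_off=0.0):
        rows_p, rows_c = [], []
        for i in range(30):
            da_off = rng.normal(0.25 + da_shift_off, 0.1)
            rows_p.append((f"p{i}", "OFF", da_off, rng.normal(0.18, 0.1)))
            rows_p.append((f"p{i}", "ON", rng.normal(0.29, 0.1),
                           rng.normal(0.18, 0.1)))
        for i in range(40):
            rows_c.append((f"c{i}", "OFF", rng.normal(0.32, 0.1),
                           rng.normal(0.21, 0.1)))
            rows_c.append((f"c{i}", "ON", rng.normal(0.32, 0.1),
                           rng.normal(0.21, 0.1)))
        cols = ["subject_id", "session", "da", "ach"]
        return pd.DataFrame(rows_p, columns=cols), pd.DataFrame(rows_c, columns=cols)

    def test_attenuated_da_off_detected(self, rng):
        pat, con = self._frames(rng, da_shift_off=-0.08)
        out = network_summary_report(pat, con)
        assert "da_OFF" in out and "difference_OFF" in out
        assert out["da_OFF"].threshold == pytest.approx(0.025)

    def test_missing_controls_warns_and_skips(self, rng):
        pat, _ = self._frames(rng)
        with pytest.warns(UserWarning, match="skipped"):
            out = network_summary_report(pat, None)
        assert out == {}
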