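import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lgcmtrial.effect_stats import (
    GroupSummary,
    change_correlations,
    change_scores,
    chisq_2x2,
    cohen_d_cross,
    format_correlations,
    phi_from_chi2,
    smd_change,
    smd_from_summaries,
    two_sample_t,
)
from lgcmtrial.synthetic import GeneratorConfig, generate

finite = st.floats(min_value=-50, max_value=50, allow_nan=False)


class TestSmdChange:
    def test_identical_distributions_give_zero(self):
        assert smd_change([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_computation(self):
        # (2 - 0) / sqrt(((1)(2) + (1)(0)) / 2) = 2.0
        assert smd_change([1.0, 3.0], [0.0, 0.0]) == pytest.approx(2.0)

    @given(c=st.floats(min_value=0.1, max_value=20))
    def test_scale_invariance(self, c):
        e, w = [1.0, 3.0, 2.0], [0.5, 0.0, 1.5]
        base = smd_change(e, w)
        assert smd_change([c * x for x in e], [c * x for x in w]) == pytest.approx(base, rel=1e-9)
        assert smd_change([-c * x for x in e], [-c * x for x in w]) == pytest.approx(-base, rel=1e-9)

    @given(shift=finite)
    def test_shift_invariance(self, shift):
        e, w = [1.0, 3.0, 2.0], [0.5, 0.0, 1.5]
        assert smd_change([x + shift for x in e], [x + shift for x in w]) == pytest.approx(
            smd_change(e, w), abs=1e-8
        )

    def test_zero_pooled_sd_degenerate(self):
        assert smd_change([1.0, 1.0], [0.0, 0.0]) == math.inf

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            smd_change([1.0], [0.0, 1.0])

    def test_raw_changes_equal_summary_formula(self, small_trial):
        """On complete data the raw-change SMD equals the summary-statistic
        form of the same estimator to machine precision."""
        ch = change_scores(small_trial.wide)
        e = ch.loc[ch["arm"] == "exp", "diff_qids"].to_numpy()
        w = ch.loc[ch["arm"] == "wait", "diff_qids"].to_numpy()
        direct = smd_change(e, w)
        viasumm = smd_from_summaries(
            GroupSummary(len(e), e.mean(), e.std(ddof=1)),
            GroupSummary(len(w), w.mean(), w.std(ddof=1)),
        )
        assert direct == pytest.approx(viasumm, abs=1e-12)


class TestCohenD:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            # printed baseline summaries of the emulated trial
            ((548, 24.151, 10.528), (557, 23.226, 10.347), 0.089),
            ((548, 28.95, 18.97), (557, 28.39, 19.07), 0.029),
            ((548, 46.81, 23.49), (557, 45.66, 23.22), 0.049),
        ],
    )
    def test_baseline_table_values(self, a, b, expected):
        d = cohen_d_cross(GroupSummary(*a), GroupSummary(*b))
        assert round(d, 3) == expected

    def test_equal_means_give_zero(self):
        g = GroupSummary(10, 5.0, 2.0)
        assert cohen_d_cross(g, g) == 0.0

    def test_signed_variant(self):
        a, b = GroupSummary(10, 4.0, 2.0), GroupSummary(10, 5.0, 2.0)
        assert cohen_d_cross(a, b, signed=True) == -cohen_d_cross(a, b)


class TestTwoSampleT:
    def test_identical_groups(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        """Pooled t computed from first principles on a hand dataset."""
        a = np.array([4.0, 5.0, 6.0, 7.0])
        b = np.array([2.0, 3.0, 5.0, 4.0])
        sp2 = ((3 * a.var(ddof=1)) + (3 * b.var(ddof=1))) / 6
        t_hand = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 4 + 1 / 4))
        res = two_sample_t(a, b)
        assert res.t == pytest.approx(t_hand, rel=1e-12)
        assert res.df == 6

    @given(
        a=st.lists(finite, min_size=3, max_size=12),
        b=st.lists(finite, min_size=3, max_size=12),
    )
    def test_welch_df_never_exceeds_pooled_df(self, a, b):
        if np.var(a, ddof=1) == 0 or np.var(b, ddof=1) == 0:
            return
        pooled = two_sample_t(a, b, welch=False)
        welch = two_sample_t(a, b, welch=True)
        assert welch.df <= pooled.df + 1e-9


class TestChiSquare:
    def test_phi_from_printed_chi2(self):
        assert round(phi_from_chi2(4.394, 1105), 3) == 0.063

    def test_proportional_table_is_null(self):
        res = chisq_2x2([[10, 20], [30, 60]])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.phi == pytest.approx(0.0, abs=1e-9)

    def test_matches_expected_count_oracle(self):
        """Female-by-arm counts: chi-square recomputed from expected counts."""
        table = np.array([[394.0, 154.0], [432.0, 125.0]])
        n = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
        plain = ((table - expected) ** 2 / expected).sum()
        corrected = ((np.abs(table - expected) - 0.5) ** 2 / expected).sum()
        assert chisq_2x2(table).chi2 == pytest.approx(plain, rel=1e-12)
        assert chisq_2x2(table, yates=True).chi2 == pytest.approx(corrected, rel=1e-12)

    def test_phi_squared_times_n_equals_chi2(self):
        table = [[30, 70], [55, 45]]
        res = chisq_2x2(table)
        assert res.phi**2 * 200 == pytest.approx(res.chi2, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_2x2([[0, 0], [5, 5]])


class TestChangeCorrelations:
    def _tiny_wide(self):
        n = 6
        base = {
            "pid": range(1, n + 1), "arm": ["exp"] * n, "female": [0] * n,
            "age": [20.0] * n, "bonus_months": [1] * n, "compensation_jpy": [900] * n,
        }
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        for w in (1, 2, 3, 4):
            base[f"qids_w{w}"] = x * w
            base[f"lsas_v_w{w}"] = -x * w          # antithetic to qids changes
            base[f"lsas_p_w{w}"] = x + w
            base[f"bell_w{w}"] = (2 ** (x + w)).astype(int)
            base[f"custom_w{w}"] = (2 ** x).astype(int)
        return pd.DataFrame(base)

    def test_unit_diagonal_and_symmetry(self, small_trial):
        corr = change_correlations(small_trial.wide, "exp")
        r = corr.r.to_numpy()
        assert np.allclose(np.diag(r), 1.0)
        assert np.array_equal(r, r.T)

    def test_antithetic_pair(self):
        corr = change_correlations(self._tiny_wide(), "exp")
        assert corr.r.loc["diff_qids", "diff_lsas_v"] == pytest.approx(-1.0)

    def test_constant_cells_marked_unavailable(self):
        corr = change_correlations(self._tiny_wide(), "exp")
        # total_reward is constant: correlation undefined
        assert np.isnan(corr.r.loc["diff_qids", "total_reward"])

    def test_built_in_correlation_recovered(self, basis):
        rho = 0.5
        cfg = GeneratorConfig(
            n_exp=2000, n_wait=2000, dropout=(0, 0, 0, 0),
            behavior_outcome_corr=rho, corr_behavior="bell", corr_outcome="lsas_v",
        )
        ds = generate(cfg, seed=77)
        corr = change_correlations(ds.wide, "exp")
        r = corr.r.loc["diff_bell_log2", "diff_lsas_v"]
        mc_se = (1 - rho**2) / math.sqrt(2000)
        assert r == pytest.approx(rho, abs=3 * mc_se)

    def test_star_formatting(self, small_trial):
        corr = change_correlations(small_trial.wide, "wait")
        table = format_correlations(corr)
        assert table.loc["diff_qids", "diff_qids"].startswith("1.00")
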