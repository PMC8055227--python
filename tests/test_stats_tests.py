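"""Significance machinery: BH adjustment, the peptide-level linear model,
the hybrid global-threshold + Welch test — each checked against an
independent oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from hdxdiff import stats_tests, uptake_core, differential
from hdxdiff.stats_tests import (StatsError, benjamini_hochberg,
                                 fit_peptide_model, linear_model_test,
                                 classify_linear, global_threshold,
                                 welch_t_test, hybrid_classify,
                                 hybrid_peptide_rollup)
from hdxdiff import synthetic_fixtures as synth


# ---------------------------------------------------------------------------
# oracles


def bh_oracle(p, m=None):
    """Brute-force step-up: sort, scale by m/i, cumulative min from the
    largest rank down, clip, unsort — written with plain Python loops."""
    m = m if m is not None else len(p)
    indexed = sorted(range(len(p)), key=lambda i: p[i])
    scaled = [p[idx] * m / (rank + 1) for rank, idx in enumerate(indexed)]
    running = 1.0
    adjusted = [0.0] * len(p)
    for rank in range(len(p) - 1, -1, -1):
        running = min(running, scaled[rank], 1.0)
        adjusted[indexed[rank]] = running
    return adjusted


def anova_oracle(y, state, time):
    """Classical balanced two-way ANOVA from group means and sums of
    squares; returns (p_state, p_time, p_interaction)."""
    df = pd.DataFrame({"y": y, "s": state, "t": time})
    S = df["s"].nunique()
    T = df["t"].nunique()
    r = len(df) // (S * T)
    grand = df["y"].mean()
    cell = df.groupby(["s", "t"])["y"].mean()
    row = df.groupby("s")["y"].mean()
    col = df.groupby("t")["y"].mean()
    ss_a = r * T * ((row - grand) ** 2).sum()
    ss_b = r * S * ((col - grand) ** 2).sum()
    ss_ab = r * sum((cell[(s, t)] - row[s] - col[t] + grand) ** 2
                    for s in row.index for t in col.index)
    sse = sum((v - cell[(s, t)]) ** 2
              for v, s, t in zip(df["y"], df["s"], df["t"]))
    df_e = S * T * (r - 1)
    mse = sse / df_e
    def p(ss, dof):
        return float(sps.f.sf(ss / dof / mse, dof, df_e))
    return (p(ss_a, S - 1), p(ss_b, T - 1), p(ss_ab, (S - 1) * (T - 1)))


def _balanced_reps(y, states, times):
    return pd.DataFrame({"state": states, "exposure": times, "uptake": y})


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


class TestBenjaminiHochberg:
    def test_hand_example(self):
        # p*m/i = [.03, .03, .03]; step-up leaves them unchanged
        assert np.allclose(benjamini_hochberg([0.01, 0.02, 0.03]),
                           [0.03, 0.03, 0.03])

    def test_all_identical(self):
        assert np.allclose(benjamini_hochberg([0.2, 0.2, 0.2]),
                           [0.2, 0.2, 0.2])

    def test_single_p_identity(self):
        assert benjamini_hochberg([0.037])[0] == pytest.approx(0.037)

    def test_m_larger_than_list(self):
        assert benjamini_hochberg([0.01], m=10)[0] == pytest.approx(0.1)

    def test_invalid_p_fatal(self):
        with pytest.raises(StatsError):
            benjamini_hochberg([0.5, 1.2])
        with pytest.raises(StatsError):
            benjamini_hochberg([0.5], m=0)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_brute_force_oracle(self, p):
        assert np.allclose(benjamini_hochberg(p), bh_oracle(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 80))
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(benjamini_hochberg(p), expected, atol=1e-12)


# ---------------------------------------------------------------------------
# linear model


class TestLinearModel:
    def test_matches_anova_oracle_on_balanced_design(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            states = np.repeat(["A", "B"], 9)
            times = np.tile(np.repeat([0.5, 5.0, 30.0], 3), 2)
            y = rng.normal(size=18) + 0.3 * (states == "B")
            fit = fit_peptide_model(_balanced_reps(y, states, times))
            ps, pt, pi = anova_oracle(y, states, times)
            assert fit.p_state == pytest.approx(ps, abs=1e-10)
            assert fit.p_time == pytest.approx(pt, abs=1e-10)
            assert fit.p_interaction == pytest.approx(pi, abs=1e-10)

    def test_matches_statsmodels_anova(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(9)
        states = np.repeat(["A", "B"], 9)
        times = np.tile(np.repeat([0.5, 5.0, 30.0], 3), 2)
        y = rng.normal(size=18) + 0.5 * (states == "B")
        fit = fit_peptide_model(_balanced_reps(y, states, times))
        df = pd.DataFrame({"y": y, "s": states, "t": times.astype(str)})
        model = smf.ols("y ~ C(s) * C(t)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        assert fit.p_state == pytest.approx(table.loc["C(s)", "PR(>F)"],
                                            abs=1e-10)
        assert fit.p_time == pytest.approx(table.loc["C(t)", "PR(>F)"],
                                           abs=1e-10)
        assert fit.p_interaction == pytest.approx(
            table.loc["C(s):C(t)", "PR(>F)"], abs=1e-10)

    def test_strong_effect_is_overwhelming(self):
        rng = np.random.default_rng(2)
        states = np.repeat(["A", "B"], 9)
        times = np.tile(np.repeat([0.5, 5.0, 30.0], 3), 2)
        y = rng.normal(0, 0.05, size=18) + 1.0 * (states == "B")
        fit = fit_peptide_model(_balanced_reps(y, states, times))
        assert fit.p_state < 1e-6
        assert fit.beta_state == pytest.approx(1.0, abs=0.1)

    def test_saturated_design_falls_back_to_additive(self):
        states = np.repeat(["A", "B"], 2)
        times = np.tile([0.5, 5.0], 2)
        fit = fit_peptide_model(
            _balanced_reps([1.0, 2.0, 1.5, 2.6], states, times))
        assert np.isnan(fit.p_interaction)
        assert fit.interaction_dropped
        assert 0 <= fit.p_state <= 1

    def test_too_few_timepoints_errors(self):
        with pytest.raises(StatsError, match="timepoints"):
            fit_peptide_model(_balanced_reps(
                [1.0, 1.1, 2.0, 2.1], ["A", "A", "B", "B"],
                [5.0, 5.0, 5.0, 5.0]))
        with pytest.raises(StatsError, match="two states"):
            fit_peptide_model(_balanced_reps(
                [1.0, 1.1, 2.0, 2.1], ["A", "A", "A", "A"],
                [5.0, 5.0, 30.0, 30.0]))

    def test_invariant_under_exposure_relabelling(self):
        # time is categorical: any injective relabelling of the exposure
        # values leaves the p-values unchanged
        rng = np.random.default_rng(13)
        states = np.repeat(["A", "B"], 9)
        times = np.tile(np.repeat([0.5, 5.0, 30.0], 3), 2)
        y = rng.normal(size=18)
        fit1 = fit_peptide_model(_balanced_reps(y, states, times))
        relabel = {0.5: 7.0, 5.0: 1.0, 30.0: 2.5}
        fit2 = fit_peptide_model(_balanced_reps(
            y, states, np.vectorize(relabel.get)(times)))
        assert fit1.p_state == pytest.approx(fit2.p_state, abs=1e-12)
        assert fit1.p_interaction == pytest.approx(fit2.p_interaction,
                                                   abs=1e-12)

    def test_parameter_recovery_with_known_offset(self):
        # simulated state offsets recover sign and magnitude of beta_state
        rng = np.random.default_rng(31)
        hits = 0
        runs = 60
        beta = 0.4
        for _ in range(runs):
            states = np.repeat(["A", "B"], 9)
            times = np.tile(np.repeat([0.5, 5.0, 30.0], 3), 2)
            y = rng.normal(0, 0.1, 18) + beta * (states == "B")
            fit = fit_peptide_model(_balanced_reps(y, states, times))
            se = np.sqrt(fit.sse_full / fit.df_resid * 2 / 9)
            if abs(fit.beta_state - beta) < 3 * se:
                hits += 1
        assert hits / runs >= 0.95


class TestClassifyLinear:
    def _results(self, q_state, q_int, sum_delta):
        return pd.DataFrame({
            "start": [1], "end": [6], "sequence": ["AAAAAA"],
            "modification": [""], "p_state": [q_state], "q_state": [q_state],
            "q_interaction": [q_int], "sum_delta": [sum_delta]})

    def test_state_family_drives_significance(self):
        out = classify_linear(self._results(0.04, 0.2, 1.2), alpha=0.05)
        assert bool(out["significant"].iloc[0])
        assert out["direction"].iloc[0] == "deprotected"

    def test_both_families_above_alpha_not_significant(self):
        out = classify_linear(self._results(0.06, 0.06, 1.2), alpha=0.05)
        assert not bool(out["significant"].iloc[0])
        assert out["direction"].iloc[0] == "none"

    def test_negative_delta_is_protected(self):
        out = classify_linear(self._results(0.01, 0.5, -0.8), alpha=0.05)
        assert out["direction"].iloc[0] == "protected"


# ---------------------------------------------------------------------------
# hybrid test


class TestGlobalThreshold:
    def _diffs(self, sd=0.17, n=3, n_records=10):
        return pd.DataFrame({
            "start": np.arange(n_records), "end": np.arange(n_records) + 5,
            "sequence": "AAAAA", "modification": "",
            "exposure": 5.0, "d_a": 1.0, "d_b": 1.1, "delta_d": 0.1,
            "sd_a": sd, "sd_b": sd, "n_a": n, "n_b": n,
            "se_delta": 0.1, "exposure_zero": False})

    def test_hand_computed_threshold(self):
        # pooled sd 0.17 both states, n=3, alpha 0.05 -> df 4, t 2.776
        thr = global_threshold(self._diffs(), alpha=0.05)
        assert thr == pytest.approx(2.7764 * np.sqrt(2 * 0.0289 / 3),
                                    abs=2e-4)
        assert thr == pytest.approx(0.3855, abs=5e-4)

    def test_degenerate_zero_variance(self):
        assert global_threshold(self._diffs(sd=0.0)) == 0.0

    def test_monotone_in_alpha_and_n(self):
        thresholds_alpha = [global_threshold(self._diffs(), alpha=a)
                            for a in (0.01, 0.05, 0.1)]
        assert thresholds_alpha[0] > thresholds_alpha[1] > thresholds_alpha[2]
        thresholds_n = [global_threshold(self._diffs(n=n))
                        for n in (2, 3, 5, 8)]
        assert all(np.diff(thresholds_n) < 0)

    def test_needs_enough_cells(self):
        with pytest.raises(StatsError):
            global_threshold(self._diffs(n_records=1))


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t_test(2.0, 0.3, 3, 2.0, 0.3, 3)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_case(self):
        t, df, p = welch_t_test(2.0, 0.3, 3, 3.0, 0.3, 3)
        assert t == pytest.approx(4.082, abs=1e-3)
        assert df == pytest.approx(4.0, abs=1e-9)
        assert p == pytest.approx(0.015, abs=1e-3)

    def test_matches_scipy(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            a = rng.normal(0, 1, size=int(rng.integers(3, 9)))
            b = rng.normal(0.5, 2, size=int(rng.integers(3, 9)))
            t, df, p = welch_t_test(a.mean(), a.std(ddof=1), len(a),
                                    b.mean(), b.std(ddof=1), len(b))
            ref = sps.ttest_ind(b, a, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_equal_variance_reproduces_student_df(self):
        _, df, _ = welch_t_test(1.0, 0.5, 4, 2.0, 0.5, 4)
        assert df == pytest.approx(6.0, abs=1e-9)

    def test_degenerate_zero_variances(self):
        assert welch_t_test(1.0, 0.0, 3, 1.0, 0.0, 3)[2] == 1.0
        assert welch_t_test(1.0, 0.0, 3, 2.0, 0.0, 3)[2] == 0.0


class TestHybrid:
    def test_one_prong_failure_not_significant(self):
        # |delta| above threshold but Welch p too large
        diffs = pd.DataFrame({
            "start": [1, 2, 3], "end": [6, 7, 8], "sequence": "AAAAA",
            "modification": "", "exposure": 5.0,
            "d_a": [1.0, 1.0, 1.0], "d_b": [3.0, 1.02, 0.99],
            "delta_d": [2.0, 0.02, -0.01],
            "sd_a": [1.1, 0.05, 0.05], "sd_b": [1.1, 0.05, 0.05],
            "n_a": 3, "n_b": 3, "se_delta": 0.5, "exposure_zero": False})
        res = hybrid_classify(diffs, alpha=0.05)
        big = res[res["start"] == 1].iloc[0]
        assert abs(big["delta_d"]) > big["threshold"]
        assert big["p_value"] > 0.05
        assert not big["significant"]

    def test_significant_set_subset_of_welch_prong(self, effect_pipeline):
        res = hybrid_classify(effect_pipeline["diffs"], alpha=0.05)
        assert (res.loc[res["significant"], "p_value"] < 0.05).all()
        assert (res.loc[res["significant"], "delta_d"].abs()
                > res.loc[res["significant"], "threshold"]).all()

    def test_rollup_any_exposure(self, effect_pipeline):
        res = hybrid_classify(effect_pipeline["diffs"], alpha=0.05)
        roll = hybrid_peptide_rollup(res)
        by_key = res.groupby(["start", "end", "sequence", "modification"])[
            "significant"].any()
        merged = roll.set_index(["start", "end", "sequence",
                                 "modification"])["significant"]
        assert (merged == by_key).all()


# ---------------------------------------------------------------------------
# null calibration / recovery on simulated peptides


def test_null_rejection_rates_controlled():
    """Both tests hold the peptide-level false-positive rate below 2*alpha
    on iid null peptides."""
    table = synth.simulate_replicate_table(n_peptides=300, seed=17)
    lin = linear_model_test(table, "APO", "HOLO", alpha=0.05)
    assert lin["significant"].mean() <= 0.10

    up = uptake_core.aggregate_uptake(table)
    diffs = differential.uptake_difference(up[up["state"] == "APO"],
                                           up[up["state"] == "HOLO"])
    roll = hybrid_peptide_rollup(hybrid_classify(diffs, alpha=0.05))
    assert roll["significant"].mean() <= 0.10


def test_null_p_state_is_uniform():
    table = synth.simulate_replicate_table(n_peptides=400, seed=19)
    lin = linear_model_test(table, "APO", "HOLO", alpha=0.05)
    d, _ = sps.kstest(lin["p_state"], "uniform")
    assert d < 0.08
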