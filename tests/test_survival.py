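import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import multivariate_logrank_test

from gbmpipe.survival import (
    administrative_censor,
    discretize_fold_change,
    expression_survival_screen,
    kaplan_meier,
    logrank_test,
    minor_allele_frequency,
    snp_survival_screen,
)

from conftest import clinical_frame


class TestKaplanMeier:
    def test_three_events_no_censoring(self):
        km = kaplan_meier(clinical_frame([1, 2, 3], [1, 1, 1]))
        np.testing.assert_allclose(km.loc[[1, 2, 3], "S"], [2 / 3, 1 / 3, 0.0], atol=1e-12)

    def test_single_censored_patient(self):
        km = kaplan_meier(clinical_frame([5.0], [0]))
        assert (km["S"] == 1.0).all()

    def test_mixed_events_and_censoring(self):
        # events at 1 and 3, censored at 2: S(1)=2/3, risk set at 3 is one -> S(3)=0
        km = kaplan_meier(clinical_frame([1, 2, 3], [1, 0, 1]))
        assert km.loc[1, "S"] == pytest.approx(2 / 3)
        assert km.loc[3, "S"] == pytest.approx(0.0)

    def test_final_step_equals_empirical_fraction_without_censoring(self, rng):
        times = rng.exponential(10, size=40).round(1)
        km = kaplan_meier(clinical_frame(times, np.ones(40, int)))
        t_last_event = times.max()
        assert km.loc[t_last_event, "S"] == pytest.approx((times > t_last_event).mean(), abs=1e-12)

    def test_all_missing_times_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier(clinical_frame([np.nan, np.nan], [1, 1]))


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 1, 1, 0, 1, 1, 1, 0]
        groups = list("AAAABBBB")
        res = logrank_test(times, events, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_four_patient_example(self):
        # O/E/V table built by hand over event times 1..4 gives chi-square 0.6154
        res = logrank_test([1, 3, 2, 4], [1, 1, 1, 1], ["A", "A", "B", "B"])
        assert res.statistic == pytest.approx(0.6154, abs=1e-3)
        assert res.df == 1

    @pytest.mark.parametrize("k_groups", [2, 3])
    def test_agrees_with_lifelines(self, rng, k_groups):
        n = 60
        times = rng.exponential(12, size=n)
        events = (rng.random(n) < 0.7).astype(int)
        groups = rng.integers(0, k_groups, size=n)
        ours = logrank_test(times, events, groups)
        ref = multivariate_logrank_test(times, groups, events)
        assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert ours.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_invariant_under_time_rescaling(self, rng):
        times = rng.exponential(10, size=50)
        events = (rng.random(50) < 0.8).astype(int)
        groups = rng.integers(0, 2, size=50)
        a = logrank_test(times, events, groups)
        b = logrank_test(times * 37.5, events, groups)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], ["A", "A"])


class TestExpressionScreen:
    def test_fold_change_discretization(self):
        np.testing.assert_array_equal(discretize_fold_change([0.4, 2.5, 1.0, 0.5, 2.0]), [-1, 1, 0, 0, 0])

    def test_small_class_excluded_and_feature_skipped(self, rng):
        # 19 overexpressed + 200 stable: overexpression class dropped -> one class left
        n = 219
        fc = np.ones(n)
        fc[:19] = 3.0
        clin = clinical_frame(rng.exponential(12, n), np.ones(n, int))
        screen = expression_survival_screen(
            pd.DataFrame([fc], index=["f1"], columns=clin.index), clin
        )
        assert screen.loc["f1", "n_over"] == 19
        assert screen.loc["f1", "n_groups"] == 1
        assert np.isnan(screen.loc["f1", "p"])

    def test_detects_planted_risk_group(self, rng):
        n = 200
        fc = np.ones(n)
        fc[:80] = 4.0
        hazard = np.where(fc > 2, 0.15, 0.05)
        clin = clinical_frame(rng.exponential(1 / hazard), np.ones(n, int))
        screen = expression_survival_screen(
            pd.DataFrame([fc], index=["f1"], columns=clin.index), clin
        )
        assert screen.loc["f1", "p"] < 0.01


class TestSnpScreen:
    @staticmethod
    def _screen(calls_row, times, events, **kw):
        patients = [f"P{i}" for i in range(len(calls_row))]
        calls = pd.DataFrame([calls_row], index=["m1"], columns=patients)
        prob = pd.DataFrame(0.99, index=["m1"], columns=patients)
        snr = pd.Series(10.0, index=patients)
        clin = pd.DataFrame({"months": times, "event": events}, index=patients)
        return snp_survival_screen(calls, prob, snr, clin, **kw)

    def test_rare_homozygote_merged_into_heterozygotes(self, rng):
        calls = ["AA"] * 100 + ["AB"] * 50 + ["BB"] * 10  # BB count < 15 -> merged
        res = self._screen(calls, rng.exponential(12, 160), np.ones(160, int))
        assert bool(res.loc["m1", "merged"])
        assert res.loc["m1", "n_groups"] == 2

    def test_low_maf_marker_excluded(self, rng):
        calls = ["AA"] * 180 + ["AB"] * 18 + ["BB"] * 2  # MAF = 0.055
        res = self._screen(calls, rng.exponential(12, 200), np.ones(200, int))
        assert res.loc["m1", "maf"] == pytest.approx(0.055)
        assert res.loc["m1", "status"] == "maf_excluded"
        assert np.isnan(res.loc["m1", "p"])

    def test_late_event_administratively_censored(self):
        clin = clinical_frame([48.0, 20.0], [1, 1])
        out = administrative_censor(clin, 36.0)
        assert out.iloc[0]["months"] == 36.0 and out.iloc[0]["event"] == 0
        assert out.iloc[1]["months"] == 20.0 and out.iloc[1]["event"] == 1

    def test_low_snr_samples_and_low_prob_calls_dropped(self, rng):
        patients = [f"P{i}" for i in range(60)]
        calls = pd.DataFrame([["AA"] * 30 + ["AB"] * 30], index=["m1"], columns=patients)
        prob = pd.DataFrame(0.99, index=["m1"], columns=patients)
        prob.iloc[0, :5] = 0.5  # discarded calls
        snr = pd.Series([3.0] * 10 + [10.0] * 50, index=patients)  # first 10 samples dropped
        clin = pd.DataFrame({"months": rng.exponential(12, 60), "event": 1}, index=patients)
        res = snp_survival_screen(calls, prob, snr, clin)
        # groups: AA only from samples 10..29 (20 kept), AB 30..59
        assert res.loc["m1", "n_groups"] == 2

    def test_null_markers_rarely_pass_strict_p_limit(self):
        rng = np.random.default_rng(42)
        n, n_markers = 200, 5000
        patients = [f"P{i}" for i in range(n)]
        mafs = rng.uniform(0.15, 0.5, n_markers)
        u = rng.random((n_markers, n))
        p0 = (1 - mafs[:, None]) ** 2
        p1 = 2 * mafs[:, None] * (1 - mafs[:, None])
        code = (u > p0).astype(int) + (u > p0 + p1).astype(int)
        calls = pd.DataFrame(np.array(["AA", "AB", "BB"])[code], columns=patients)
        calls.index = [f"m{i}" for i in range(n_markers)]
        prob = pd.DataFrame(0.99, index=calls.index, columns=patients)
        snr = pd.Series(10.0, index=patients)
        clin = pd.DataFrame(
            {"months": rng.exponential(14, n), "event": (rng.random(n) < 0.8).astype(int)},
            index=patients,
        )
        res = snp_survival_screen(calls, prob, snr, clin)
        # expected passes at P<1e-4 is ~0.5; a Poisson bound keeps the count tiny
        assert int(res["selected"].sum()) <= 3


def test_minor_allele_frequency_counts_alleles():
    calls = pd.Series(["AA"] * 6 + ["AB"] * 3 + ["BB"] * 1)
    # B alleles: 3 + 2 = 5 of 20
    assert minor_allele_frequency(calls) == pytest.approx(0.25)
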