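import numpy as np
import pandas as pd
import pytest

from gbmpipe.copynumber import (
    AberrationThresholds,
    aberration_frequencies,
    aberration_matrix,
    call_aberrations,
    estimate_thresholds,
    segment_profile,
)


def profile_frame(values, sample="S1", chrom="chr1"):
    return pd.DataFrame(
        {"sample": sample, "chrom": chrom, "pos": np.arange(len(values)) * 100, "logratio": values}
    )


class TestThresholds:
    def test_two_sd_arithmetic(self):
        thr = estimate_thresholds(np.array([-0.3, -0.1, 0.1, 0.3]))
        sd = np.std([-0.3, -0.1, 0.1, 0.3], ddof=1)
        assert thr.upper == pytest.approx(2 * sd) == pytest.approx(0.5164, abs=1e-4)
        assert thr.lower == pytest.approx(-2 * sd)

    def test_degenerate_controls_fall_back_to_defaults(self):
        thr = estimate_thresholds(np.zeros(100))
        assert thr.upper == 0.632 and thr.lower == -0.632

    def test_no_controls_uses_defaults(self):
        thr = estimate_thresholds(None)
        assert thr.upper == 0.632 and thr.lower == -0.632

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            AberrationThresholds(upper=-0.1, lower=-0.5)


class TestCalling:
    @pytest.mark.parametrize(
        "mean, call",
        [(0.7, "gain"), (-0.7, "loss"), (0.0, "neutral"), (0.632, "neutral"), (-0.632, "neutral")],
    )
    def test_strict_threshold_rule(self, mean, call):
        segs = pd.DataFrame(
            {"sample": ["S1"], "chrom": ["chr1"], "start": [0], "end": [100], "n_probes": [10], "seg_mean": [mean]}
        )
        assert call_aberrations(segs, AberrationThresholds())["call"].iloc[0] == call

    def test_calling_monotone_in_upper_threshold(self, rng):
        means = rng.normal(0, 0.6, size=200)
        segs = pd.DataFrame(
            {"sample": "S1", "chrom": "chr1", "start": np.arange(200), "end": np.arange(200) + 1,
             "n_probes": 5, "seg_mean": means}
        )
        counts = [
            (call_aberrations(segs, AberrationThresholds(upper=u, lower=-0.632))["call"] == "gain").sum()
            for u in (0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)


class TestSegmentation:
    def test_constant_profile_single_segment(self):
        segs = segment_profile(profile_frame(np.full(60, 0.25)))
        assert len(segs) == 1
        assert segs["n_probes"].iloc[0] == 60
        assert segs["seg_mean"].iloc[0] == pytest.approx(0.25)

    def test_noiseless_step_breakpoint_exact(self):
        x = np.zeros(100)
        x[50:] = 1.0
        segs = segment_profile(profile_frame(x), seed=5)
        assert len(segs) == 2
        assert segs["n_probes"].tolist() == [50, 50]
        np.testing.assert_allclose(segs["seg_mean"], [0.0, 1.0], atol=1e-12)

    def test_profile_mean_conserved_by_segments(self, rng):
        x = rng.normal(0, 0.3, size=120)
        x[30:50] += 1.5
        segs = segment_profile(profile_frame(x), seed=2)
        weighted = (segs["seg_mean"] * segs["n_probes"]).sum() / segs["n_probes"].sum()
        assert weighted == pytest.approx(x.mean(), abs=1e-10)

    def test_unsorted_positions_rejected(self):
        bad = profile_frame(np.zeros(10))
        bad.loc[3, "pos"] = 5000
        with pytest.raises(ValueError, match="sorted"):
            segment_profile(bad)

    def test_null_profile_rarely_split(self, rng):
        aberrant_probes = 0
        total = 0
        for i in range(5):
            x = rng.normal(0, 0.25, size=80)
            segs = call_aberrations(segment_profile(profile_frame(x), seed=i), AberrationThresholds())
            aberrant_probes += segs.loc[segs["call"] != "neutral", "n_probes"].sum()
            total += 80
        assert aberrant_probes / total < 0.05


class TestFrequencies:
    @staticmethod
    def _segments(calls_by_sample):
        rows = []
        for sample, call in calls_by_sample.items():
            rows.append({"sample": sample, "chrom": "chr1", "start": 0, "end": 1000,
                         "n_probes": 10, "seg_mean": 1.0, "call": call})
        return pd.DataFrame(rows)

    def test_simple_counting(self):
        segs = self._segments({f"S{i}": ("gain" if i < 54 else "neutral") for i in range(100)})
        feats = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]}, index=["G1"])
        freqs = aberration_frequencies(segs, feats)
        assert freqs.loc["G1", "gain_freq"] == pytest.approx(0.54)
        assert freqs.loc["G1", "loss_freq"] == 0.0

    def test_no_aberrations(self):
        segs = self._segments({"S1": "neutral", "S2": "neutral"})
        feats = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [50]}, index=["G1"])
        freqs = aberration_frequencies(segs, feats)
        assert freqs.loc["G1", "gain_freq"] == 0.0 and freqs.loc["G1", "loss_freq"] == 0.0

    def test_feature_spanning_gain_and_neutral_counts_gain(self):
        segs = pd.DataFrame(
            [
                {"sample": "S1", "chrom": "chr1", "start": 0, "end": 500, "n_probes": 5, "seg_mean": 1.0, "call": "gain"},
                {"sample": "S1", "chrom": "chr1", "start": 500, "end": 1000, "n_probes": 5, "seg_mean": 0.0, "call": "neutral"},
            ]
        )
        feats = pd.DataFrame({"chrom": ["chr1"], "start": [400], "end": [600]}, index=["G1"])
        assert aberration_matrix(segs, feats).loc["G1", "S1"] == "gain"
        assert aberration_frequencies(segs, feats).loc["G1", "gain_freq"] == 1.0

    def test_gain_plus_loss_overlap_is_ambiguous_and_excluded(self):
        segs = pd.DataFrame(
            [
                {"sample": "S1", "chrom": "chr1", "start": 0, "end": 500, "n_probes": 5, "seg_mean": 1.0, "call": "gain"},
                {"sample": "S1", "chrom": "chr1", "start": 500, "end": 1000, "n_probes": 5, "seg_mean": -1.0, "call": "loss"},
            ]
        )
        feats = pd.DataFrame({"chrom": ["chr1"], "start": [400], "end": [600]}, index=["G1"])
        freqs = aberration_frequencies(segs, feats)
        assert aberration_matrix(segs, feats).loc["G1", "S1"] == "ambiguous"
        assert freqs.loc["G1", "gain_freq"] == 0.0 and freqs.loc["G1", "loss_freq"] == 0.0
        assert freqs.loc["G1", "n_ambiguous"] == 1
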