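"""HRV time, frequency and Poincare features against closed forms."""

import numpy as np
import pytest

from ecgemotion import (
    CorruptionParams,
    DEFAULT_TEMPLATE,
    HRV_FEATURE_NAMES,
    RhythmParams,
    RRSeries,
    WelchConfig,
    band_power,
    generate_window,
    hrv_features,
    hrv_frequency_features,
    hrv_geometric_features,
    hrv_time_features,
    interpolate_hrv,
    rr_from_peaks,
    welch_psd,
)


def _series(intervals_ms):
    intervals_ms = np.asarray(intervals_ms, dtype=float)
    return RRSeries(intervals_ms, np.cumsum(intervals_ms) / 1000.0)


class TestRRConstruction:
    def test_interval_arithmetic(self):
        rr = rr_from_peaks([0, 1000, 2000], fs=1000)
        assert np.allclose(rr.rr_intervals, [1000, 1000])
        assert np.allclose(rr.rr_times, [1.0, 2.0])

    def test_uneven_intervals(self):
        rr = rr_from_peaks([0, 800, 1700], fs=1000)
        assert np.allclose(rr.rr_intervals, [800, 900])

    def test_non_increasing_rejected(self):
        with pytest.raises(ValueError):
            rr_from_peaks([0, 1000, 900], fs=1000)

    def test_too_few_peaks(self):
        with pytest.raises(ValueError, match="insufficient"):
            rr_from_peaks([0, 1000], fs=1000)


class TestInterpolation:
    def test_constant_series_stays_constant(self):
        _, series = interpolate_hrv(_series([800] * 10))
        assert np.allclose(series, 800, atol=1e-9)

    def test_linear_trend_reproduced(self):
        # knots collinear in time -> the natural cubic interpolant IS the line
        base = np.full(12, 820.0)
        times = np.cumsum(base) / 1000.0
        intervals = 800.0 + 5.0 * times
        t, series = interpolate_hrv(RRSeries(intervals, times))
        assert np.allclose(series, 800.0 + 5.0 * t, atol=1e-6)

    def test_modulated_rhythm_peak_in_lf_band(self):
        rhythm = RhythmParams(mean_rr=1.0, rr_modulations=[(0.1, 0.05)], seed=0)
        _, beats = generate_window(
            DEFAULT_TEMPLATE, rhythm, CorruptionParams(), 1000, 90
        )
        rr = rr_from_peaks((np.asarray(beats) * 1000).round().astype(int), 1000)
        _, series = interpolate_hrv(rr, 4.0)
        psd = welch_psd(series - series.mean(), 4.0, WelchConfig(lseg=series.size, lover=series.size // 2))
        peak = psd.freqs[np.argmax(psd.power)]
        assert 0.04 <= peak < 0.15


class TestTimeFeatures:
    def test_constant_intervals(self):
        f = hrv_time_features(_series([800, 800, 800]))
        assert f["sdnn"] == 0 and f["rmssd"] == 0 and f["nn50"] == 0
        assert f["pnn50"] == 0 and f["mn_nn"] == 800 and f["m_nn"] == 800

    def test_two_interval_hand_computation(self):
        f = hrv_time_features(_series([800, 860]))
        assert f["rmssd"] == pytest.approx(60)
        assert f["nn50"] == 1 and f["pnn50"] == pytest.approx(100)
        assert f["mn_nn"] == pytest.approx(830) and f["m_nn"] == 860
        assert f["sdnn"] == pytest.approx(np.std([800, 860], ddof=1))  # ~42.43

    def test_difference_of_exactly_50ms_not_counted(self):
        f = hrv_time_features(_series([800, 850, 800]))
        assert f["nn50"] == 0


class TestFrequencyFeatures:
    def test_constant_series_all_zero(self):
        f = hrv_frequency_features(np.full(200, 800.0))
        assert f["lf"] == 0 and f["vlf"] == 0 and f["total_power"] == 0
        assert np.isnan(f["lf_hf"])

    def test_lf_modulation_dominates(self):
        t = np.arange(0, 120, 0.25)
        series = 900 + 50 * np.sin(2 * np.pi * 0.1 * t)
        f = hrv_frequency_features(series, 4.0)
        assert f["lfnu"] > 90

    def test_hf_modulation_dominates(self):
        t = np.arange(0, 120, 0.25)
        series = 900 + 50 * np.sin(2 * np.pi * 0.3 * t)
        f = hrv_frequency_features(series, 4.0)
        assert f["hfnu"] > 90

    def test_normalized_units_sum_to_100(self):
        rng = np.random.default_rng(5)
        series = 900 + 30 * rng.normal(size=300)
        f = hrv_frequency_features(series, 4.0)
        assert f["lfnu"] + f["hfnu"] == pytest.approx(100)


class TestGeometric:
    def test_constant_intervals_zero(self):
        f = hrv_geometric_features(_series([800] * 5))
        assert f["sd1"] == 0 and f["sd2"] == 0

    def test_alternating_series(self):
        f = hrv_geometric_features(_series([800, 900] * 6))
        assert f["sd1"] > 10 * max(f["sd2"], 1e-12)

    def test_sd1_matches_rmssd_identity(self):
        rng = np.random.default_rng(9)
        intervals = 800 + 40 * rng.normal(size=50)
        rr = _series(intervals)
        t = hrv_time_features(rr)
        g = hrv_geometric_features(rr)
        assert g["sd1"] == pytest.approx(t["rmssd"] / np.sqrt(2), rel=0.02)


class TestFullBlock:
    def test_canonical_names_and_count(self, annotated_realistic):
        _, ann, _ = annotated_realistic
        feats = hrv_features(rr_from_peaks(ann.r_idx, 1000))
        assert list(feats) == HRV_FEATURE_NAMES
        assert len(feats) == 14

    def test_jitter_sd_recovered_by_sdnn(self):
        rhythm = RhythmParams(mean_rr=1.0, rr_jitter_sd=0.03, seed=21)
        _, beats = generate_window(
            DEFAULT_TEMPLATE, rhythm, CorruptionParams(), 1000, 65
        )
        rr = rr_from_peaks((np.asarray(beats) * 1000).round().astype(int), 1000)
        assert rr.n_intervals >= 55
        assert hrv_time_features(rr)["sdnn"] == pytest.approx(30.0, rel=0.15)

    def test_band_dominance_follows_modulator(self):
        for f_mod, dominant in ((0.1, "lf"), (0.3, "hf")):
            rhythm = RhythmParams(mean_rr=0.8, rr_modulations=[(f_mod, 0.04)], seed=3)
            _, beats = generate_window(
                DEFAULT_TEMPLATE, rhythm, CorruptionParams(), 1000, 80
            )
            rr = rr_from_peaks((np.asarray(beats) * 1000).round().astype(int), 1000)
            _, series = interpolate_hrv(rr)
            f = hrv_frequency_features(series)
            other = "hf" if dominant == "lf" else "lf"
            assert f[dominant] > f[other]
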