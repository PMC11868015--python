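"""HRV metrics: window extraction, time-domain oracles, resampling and
spectral band powers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from exhrv.core import RRSeries
from exhrv import hrv

from conftest import constant_series


def rmssd_oracle(x):
    acc = 0.0
    for a, b in zip(x[:-1], x[1:]):
        acc += (b - a) ** 2
    return (acc / (len(x) - 1)) ** 0.5


def sdnn_oracle(x):
    m = sum(x) / len(x)
    return (sum((v - m) ** 2 for v in x) / (len(x) - 1)) ** 0.5


def sinusoid_series(freq, amp_ms, duration_s, base_ms=800.0):
    """Self-consistent tachogram whose RR value oscillates sinusoidally."""
    t, rr, ts = 0.0, [], []
    while t < duration_s * 1000.0:
        v = base_ms + amp_ms * np.sin(2 * np.pi * freq * t / 1000.0)
        t += v
        rr.append(v)
        ts.append(t)
    return RRSeries(rr=np.array(rr), t=np.array(ts))


class TestExtractWindow:
    def test_full_window_identity(self, const800):
        win = hrv.AnalysisWindow(0.0, 1e6)
        out = hrv.extract_window(const800, win)
        assert np.array_equal(out.rr, const800.rr)

    def test_counts_beats_in_half_open_window(self):
        rr = constant_series(1000.0, 600)  # 600 s at 1 Hz
        out = hrv.extract_window(rr, hrv.AnalysisWindow(300.0, 300.0))
        assert len(out) == 300

    def test_empty_window_rejected(self, const800):
        with pytest.raises(ValueError):
            hrv.extract_window(const800, hrv.AnalysisWindow(1e7, 10.0))


class TestTimeDomain:
    def test_constant_series_zero(self, const800):
        assert hrv.rmssd(const800) == 0.0
        assert hrv.sdnn(const800) == 0.0

    def test_hand_computed_examples(self):
        assert hrv.rmssd(np.array([800, 810, 800, 810.0])) == pytest.approx(10.0)
        assert hrv.sdnn(np.array([750, 850.0])) == pytest.approx(70.7107, abs=1e-4)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            hrv.rmssd(np.array([800.0]))
        with pytest.raises(ValueError):
            hrv.sdnn(np.array([800.0]))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(300, 2000), min_size=2, max_size=100))
    def test_matches_brute_force_oracles(self, vals):
        x = np.array(vals)
        assert hrv.rmssd(x) == pytest.approx(rmssd_oracle(vals), abs=1e-9)
        assert hrv.sdnn(x) == pytest.approx(sdnn_oracle(vals), abs=1e-9)

    def test_invariant_to_window_start(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(700, 900, 200)
        a = RRSeries.from_intervals(vals, t0=0.0)
        b = RRSeries.from_intervals(vals, t0=5e5)
        assert hrv.rmssd(a) == hrv.rmssd(b)
        assert hrv.sdnn(a) == hrv.sdnn(b)


class TestResampling:
    def test_constant_series_constant_grid(self, const800):
        _, vals = hrv.resample_tachogram(const800)
        assert np.allclose(vals, 800.0)

    def test_linear_trend_preserved(self):
        n = 200
        rr = 800 + 0.5 * np.arange(n)  # slow linear drift
        series = RRSeries.from_intervals(rr)
        t, vals = hrv.resample_tachogram(series)
        # closed form: rr as a function of beat time is nearly linear
        fit = np.polyfit(series.t / 1000.0, series.rr, 1)
        assert np.max(np.abs(vals - np.polyval(fit, t))) < 1.0

    def test_sinusoid_correlation(self):
        series = sinusoid_series(0.1, 40.0, 300.0)
        t, vals = hrv.resample_tachogram(series, 4.0)
        # each RR value is anchored at its interval's END time, so the
        # resampled trace is the modulation delayed by one mean interval
        truth = 800.0 + 40.0 * np.sin(2 * np.pi * 0.1 * (t - 0.8))
        r = np.corrcoef(vals, truth)[0, 1]
        assert r >= 0.999

    def test_too_few_beats_rejected(self):
        with pytest.raises(ValueError):
            hrv.resample_tachogram(constant_series(800, 3))


class TestSpectra:
    def test_constant_series_zero_power(self):
        p = hrv.spectral_band_powers(np.full(1200, 800.0))
        assert p["tp"] == pytest.approx(0.0, abs=1e-12)

    def test_sinusoid_band_power_and_leakage(self):
        t = np.arange(0, 300, 0.25)
        x = 40.0 * np.sin(2 * np.pi * 0.10 * t)
        p = hrv.spectral_band_powers(x, 4.0)
        assert p["lf"] == pytest.approx(800.0, rel=0.10)
        assert p["vlf"] + p["hf"] < 0.05 * p["tp"]

    def test_superposition_separates_bands(self):
        t = np.arange(0, 300, 0.25)
        x = 30.0 * np.sin(2 * np.pi * 0.02 * t) + 20.0 * np.sin(2 * np.pi * 0.3 * t)
        p = hrv.spectral_band_powers(x, 4.0)
        assert p["vlf"] == pytest.approx(450.0, rel=0.15)
        assert p["hf"] == pytest.approx(200.0, rel=0.15)
        assert p["lf"] < 0.05 * p["tp"]

    def test_band_boundary_moves_power(self):
        t = np.arange(0, 300, 0.25)
        for f, band in ((0.13, "lf"), (0.17, "hf")):
            p = hrv.spectral_band_powers(40 * np.sin(2 * np.pi * f * t), 4.0)
            assert p[band] > 0.9 * p["tp"]

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            hrv.spectral_band_powers(np.zeros(100), 4.0)

    def test_parseval_band_sum(self):
        """For band-limited signals (all energy below 0.4 Hz) the three-band
        sum recovers the detrended variance."""
        from scipy.signal import detrend
        rng = np.random.default_rng(4)
        t = np.arange(0, 300, 0.25)
        for _ in range(10):
            x = np.zeros_like(t)
            for _ in range(5):
                f = rng.uniform(0.01, 0.39)
                a = rng.uniform(5, 40)
                x += a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            p = hrv.spectral_band_powers(x, 4.0)
            var = np.mean(detrend(x, type="linear") ** 2)
            assert p["tp"] == pytest.approx(var, rel=0.10)


class TestHRVMetrics:
    def test_tp_identity_and_nonnegativity(self, subject, flat_profile):
        from exhrv import synthetic as syn
        mod = syn.ModulationSpec(band_components=[(0.02, 13.0), (0.1, 5.0),
                                                  (0.25, 2.0)],
                                 broadband_noise_sd=1.0)
        rr = syn.generate_rr_series(subject, flat_profile, mod, seed=5)
        res = hrv.hrv_metrics(rr, hrv.AnalysisWindow(flat_profile.t_stop_start,
                                                     300))
        assert res.tp == pytest.approx(res.vlf + res.lf + res.hf, abs=1e-9)
        for v in (res.rmssd, res.sdnn, res.vlf, res.lf, res.hf, res.tp):
            assert v >= 0

    def test_short_window_warns(self, caplog):
        rr = constant_series(1000.0, 400)
        with caplog.at_level("WARNING", logger="exhrv"):
            hrv.extract_window(rr, hrv.AnalysisWindow(10.0, 60.0))
        assert any("90 s" in r.message for r in caplog.records)
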