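"""Cohort simulator: determinism, quantile calibration, IPFM beat
generation and artifact injection."""

import numpy as np
import pytest

from exhrv import synthetic as syn
from exhrv.core import ConfigError
from exhrv.hrv import AnalysisWindow, hrv_metrics

from conftest import constant_series


def degenerate_params(lf=12.4):
    """Zero-width IQRs: every latent collapses to its median."""
    gp = syn.GroupParams()
    for name in ("age", "bmi", "hr_rest", "hr_max_lab", "vo2max",
                 "sbp_start", "dbp_start", "sbp_thh", "dbp_thh",
                 "lactate_start", "lactate_thh", "lf_power", "vlf_power",
                 "hf_power", "hr_peak_uphill", "hr_drop_30s",
                 "time_uphill_s", "time_stop_s"):
        m = getattr(gp, name)[0]
        setattr(gp, name, (m, m, m))
    gp.lf_power = (lf, lf, lf)
    gp.male_frac = 1.0
    gp.smoking_prev = 0.0
    return gp


class TestGenerateCohort:
    def test_default_cohort_sizes_and_labels(self):
        subjects, truth = syn.generate_cohort(syn.CohortConfig())
        assert len(subjects) == 56
        assert sum(1 for s in subjects if s.group == "CAC-") == 31
        assert sum(1 for s in subjects if s.group == "CAC+") == 25
        assert len(truth.subject_latents) == 56

    def test_degenerate_params_share_latents(self):
        gp = degenerate_params()
        cfg = syn.CohortConfig(n_neg=2, n_pos=2,
                               group_params={"CAC-": gp, "CAC+": gp},
                               n_walkers_neg=0, n_walkers_pos=0)
        subjects, truth = syn.generate_cohort(cfg)
        lf = {truth.subject_latents[s.subject_id]["lf_power"] for s in subjects}
        assert lf == {12.4}
        assert len({s.sbp_thh for s in subjects}) == 1

    def test_group_medians_converge(self):
        cfg = syn.CohortConfig(n_neg=500, n_pos=500, seed=7,
                               n_walkers_neg=0, n_walkers_pos=0)
        subjects, truth = syn.generate_cohort(cfg)
        for group, target in (("CAC-", 12.4), ("CAC+", 6.3)):
            lf = [truth.subject_latents[s.subject_id]["lf_power"]
                  for s in subjects if s.group == group]
            assert abs(np.median(lf) - target) / target < 0.15

    def test_bp_quantile_matching(self):
        cfg = syn.CohortConfig(n_neg=1000, n_pos=2, seed=11,
                               n_walkers_neg=0, n_walkers_pos=0)
        subjects, _ = syn.generate_cohort(cfg)
        sbp = [s.sbp_thh for s in subjects if s.group == "CAC-"]
        assert abs(np.median(sbp) - 220) <= 5

    def test_invalid_iqr_rejected(self):
        gp = syn.GroupParams(age=(50, 55, 45))
        with pytest.raises(ConfigError):
            syn.CohortConfig(group_params={"CAC-": gp,
                                           "CAC+": syn.GroupParams()})

    def test_seed_determinism(self):
        a, _ = syn.generate_cohort(syn.CohortConfig(seed=3))
        b, _ = syn.generate_cohort(syn.CohortConfig(seed=3))
        assert all(x == y for x, y in zip(a, b))


class TestGenerateBPLactate:
    def test_degenerate_cac_pos_values(self):
        gp = degenerate_params()
        gp.sbp_thh = (235, 235, 235)
        gp.dbp_thh = (105, 105, 105)
        rng = np.random.default_rng(0)
        for _ in range(5):
            bp = syn.generate_bp_lactate(gp, rng, replicate_sd=0.0)
            assert bp["sbp_thh"] == 235 and bp["dbp_thh"] == 105

    def test_configured_delta_exact(self):
        gp = degenerate_params()
        gp.dbp_delta = (20, 20, 20)
        bp = syn.generate_bp_lactate(gp, np.random.default_rng(0),
                                     replicate_sd=0.0)
        assert bp["dbp_thh"] - bp["dbp_start"] == 20

    def test_sbp_rises_to_hill_top(self):
        gp = syn.cac_negative_defaults()
        rng = np.random.default_rng(1)
        draws = [syn.generate_bp_lactate(gp, rng) for _ in range(300)]
        frac = np.mean([d["sbp_thh"] > d["sbp_start"] for d in draws])
        assert frac >= 0.99


class TestGenerateRRSeries:
    def test_constant_rate_unit_intervals(self, subject):
        # flat 60 bpm trajectory: lab max 100 with peak frac ~0.6 won't be
        # flat, so drive a constant rate through a degenerate profile
        profile = syn.RaceProfile(t_hill_start=50, t_hill_top=60,
                                  stop_duration=10, post_window=40,
                                  hr_baseline_frac=0.5999999,
                                  hr_hill_peak_frac=0.6,
                                  recovery_drop_30s=1e-9, post_rise_bpm=0.0)
        subject.hr_max_lab = 100.0  # peak 60 bpm -> RR 1000 ms
        rr = syn.generate_rr_series(subject, profile, syn.ModulationSpec(),
                                    seed=0)
        assert np.allclose(rr.rr, 1000.0, atol=2.0)
        assert abs(rr.duration_ms - 1000 * len(rr)) < 1000

    def test_time_conservation_and_rate_tracking(self, subject, flat_profile):
        rr = syn.generate_rr_series(subject, flat_profile,
                                    syn.ModulationSpec(), seed=1)
        assert abs(rr.duration_ms / 1000.0 - flat_profile.t_end) < 1.5
        # mean HR over a 60 s baseline segment tracks the trajectory
        sel = rr.t / 1000.0 < 45
        mean_hr = 60000.0 / rr.rr[sel].mean()
        assert abs(mean_hr - 0.78 * subject.hr_max_lab) < 3.0

    def test_recovery_drop_visible(self, subject):
        profile = syn.RaceProfile(t_hill_start=50, t_hill_top=150,
                                  stop_duration=120, post_window=300,
                                  recovery_drop_30s=12.0)
        rr = syn.generate_rr_series(subject, profile, syn.ModulationSpec(),
                                    seed=2)
        hr = 60000.0 / rr.rr
        t = rr.t / 1000.0
        at_stop = hr[np.abs(t - 150) < 2.5].mean()
        at_30 = hr[np.abs(t - 180) < 2.5].mean()
        assert at_stop - at_30 == pytest.approx(12.0, abs=2.0)

    def test_lf_component_recovered(self, subject, flat_profile):
        mod = syn.ModulationSpec(band_components=[(0.10, 40.0)])
        rr = syn.generate_rr_series(subject, flat_profile, mod, seed=3)
        res = hrv_metrics(rr, AnalysisWindow(flat_profile.t_stop_start, 300))
        assert res.lf == pytest.approx(800.0, rel=0.10)

    def test_negative_rate_rejected(self, subject, flat_profile):
        mod = syn.ModulationSpec(band_components=[(0.10, 2000.0)])
        with pytest.raises(ValueError, match="rate trajectory"):
            syn.generate_rr_series(subject, flat_profile, mod, seed=4)


class TestInjectArtifacts:
    def test_zero_rate_noop(self):
        rr = constant_series(800, 100)
        out, pos = syn.inject_artifacts(rr, syn.ArtifactSpec(rate=0.0))
        assert np.array_equal(out.rr, rr.rr) and pos.size == 0

    def test_single_missed_beat(self):
        rr = constant_series(800, 200)
        spec = syn.ArtifactSpec(rate=1 / 200, mix=(1.0, 0.0, 0.0), seed=5)
        out, pos = syn.inject_artifacts(rr, spec)
        assert len(out) == 199
        assert pos.size == 1
        assert out.rr[pos[0]] == pytest.approx(1600.0)

    def test_sum_conservation_at_5pct(self):
        rng = np.random.default_rng(6)
        rr = syn.RRSeries.from_intervals(rng.uniform(700, 900, 1000))
        out, pos = syn.inject_artifacts(rr, syn.ArtifactSpec(rate=0.05, seed=7))
        assert abs(out.duration_ms - rr.duration_ms) < 1.0
        assert 40 <= pos.size <= 100  # ~50 sites, 1-2 indices each

    def test_overlapping_rate_rejected(self):
        rr = constant_series(800, 30)
        with pytest.raises(ValueError, match="overlap"):
            syn.inject_artifacts(rr, syn.ArtifactSpec(rate=0.45))

    def test_deterministic_given_seed(self):
        rr = constant_series(800, 500)
        spec = syn.ArtifactSpec(rate=0.04, seed=9)
        a, pa = syn.inject_artifacts(rr, spec)
        b, pb = syn.inject_artifacts(rr, spec)
        assert np.array_equal(a.rr, b.rr) and np.array_equal(pa, pb)


class TestSimulateCohort:
    def test_walkers_have_lower_vo2max_and_flat_power(self):
        cfg = syn.CohortConfig(n_neg=10, n_pos=10, seed=21,
                               n_walkers_neg=3, n_walkers_pos=3,
                               power_meter_frac=1.0)
        subjects, rr, power, truth = syn.simulate_cohort(cfg)
        walkers = [s for s in subjects
                   if truth.subject_latents[s.subject_id]["walker"]]
        cyclists = [s for s in subjects
                    if not truth.subject_latents[s.subject_id]["walker"]]
        assert len(walkers) == 6
        assert (np.median([s.vo2max for s in walkers])
                < np.median([s.vo2max for s in cyclists]))
        w = power[walkers[0].subject_id]
        assert (w["watts"] == 0).sum() > 0

    def test_bit_identical_repeat(self):
        cfg = syn.CohortConfig(n_neg=4, n_pos=4, seed=33,
                               n_walkers_neg=0, n_walkers_pos=0)
        art = syn.ArtifactSpec(rate=0.03, seed=33)
        _, rr1, _, _ = syn.simulate_cohort(cfg, artifacts=art)
        _, rr2, _, _ = syn.simulate_cohort(cfg, artifacts=art)
        for sid in rr1:
            assert np.array_equal(rr1[sid].rr, rr2[sid].rr)

    def test_single_sinusoid_band_concentration(self, subject):
        """For a noiseless single-sinusoid modulation on a flat skeleton,
        nearly all detrended tachogram power falls in the component's band."""
        profile = syn.RaceProfile(t_hill_start=50, t_hill_top=51,
                                  stop_duration=10, post_window=300,
                                  hr_baseline_frac=0.5999999,
                                  hr_hill_peak_frac=0.6,
                                  recovery_drop_30s=1e-9, post_rise_bpm=0.0)
        mod = syn.ModulationSpec(band_components=[(0.25, 30.0)])
        rr = syn.generate_rr_series(subject, profile, mod, seed=13)
        res = hrv_metrics(rr, AnalysisWindow(profile.t_stop_start, 300))
        assert res.hf / res.tp >= 0.90
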