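"""Synthetic two-group exercise cohort generator.

Emulates a mountain-bike-race field study: each subject climbs a steep hill,
stops briefly at the top for blood-pressure and lactate measurements, then
rides on. A chest strap records beat-to-beat RR intervals throughout; the
autonomic analysis window is the 5 min following (and including) the stop.

Beat generation uses integral pulse frequency modulation (IPFM): the
instantaneous heart rate is integrated and a beat is emitted each time the
integral gains one unit of area. RR-interval oscillations in the VLF / LF /
HF bands are injected as sinusoidal modulation of the target RR interval, so
the generated tachogram is genuinely unevenly sampled and carries known band
powers — the ground truth against which spectral recovery is tested.

Group-level distributions (CAC+ vs CAC- : with and without coronary artery
calcification) are parameterised by median and interquartile range, the
reporting convention of the emulated study. Spectral powers are sampled
log-normally (strictly positive, right-skewed); pressures and other vitals
normally, truncated at physiological bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .core import RRSeries, Events, SubjectRecord, ConfigError, BP_BOUNDS, logger

#: z-score of the 75th percentile; converts an IQR to a normal sigma.
Z75 = 0.6744897501960817

#: Default simulator seed, recorded in config and logs.
DEFAULT_SEED = 20180421


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

Quantiles = tuple[float, float, float]  # (median, q25, q75)


def _check_quantiles(name: str, q: Quantiles) -> None:
    m, lo, hi = q
    if not (lo <= m <= hi):
        raise ConfigError(f"{name}: IQR bounds not ordered (q25 <= median <= q75)")


@dataclass
class GroupParams:
    """Median/IQR sampling targets for one group.

    Each continuous field is ``(median, q25, q75)``. Spectral powers are in
    ms^2, pressures in mmHg, lactate in mmol/L. ``dbp_delta`` optionally
    replaces direct sampling of ``dbp_thh`` with start + sampled increase.
    """

    age: Quantiles = (50.0, 43.0, 58.0)
    bmi: Quantiles = (25.0, 23.5, 27.0)
    hr_rest: Quantiles = (52.0, 47.0, 60.0)
    hr_max_lab: Quantiles = (177.0, 170.0, 185.0)
    vo2max: Quantiles = (41.0, 36.0, 47.0)
    sbp_start: Quantiles = (140.0, 130.0, 150.0)
    dbp_start: Quantiles = (80.0, 78.0, 88.0)
    sbp_thh: Quantiles = (228.0, 205.0, 242.0)
    dbp_thh: Quantiles = (100.0, 90.0, 110.0)
    dbp_delta: Quantiles | None = None
    lactate_start: Quantiles = (1.7, 1.3, 2.2)
    lactate_thh: Quantiles = (4.6, 3.6, 6.0)
    lf_power: Quantiles = (9.0, 4.0, 16.0)
    vlf_power: Quantiles = (80.0, 50.0, 115.0)
    hf_power: Quantiles = (2.0, 1.0, 4.5)
    hr_peak_uphill: Quantiles = (171.0, 163.0, 177.0)
    hr_drop_30s: Quantiles = (12.0, 9.0, 15.0)
    time_uphill_s: Quantiles = (268.0, 240.0, 310.0)
    time_stop_s: Quantiles = (129.0, 105.0, 178.0)
    male_frac: float = 0.73
    smoking_prev: float = 0.10

    def validate(self) -> None:
        for name, q in asdict(self).items():
            if isinstance(q, tuple) and len(q) == 3:
                _check_quantiles(name, q)
        for p in (self.male_frac, self.smoking_prev):
            if not (0.0 <= p <= 1.0):
                raise ConfigError("probabilities must lie in [0, 1]")


def cac_negative_defaults() -> GroupParams:
    """Printed cohort targets for the CAC- group (n = 31)."""
    return GroupParams(
        age=(46, 41, 52), bmi=(24.9, 23.3, 26.1), hr_rest=(54, 49, 60),
        hr_max_lab=(180, 173, 187), vo2max=(43.4, 38.0, 49.4),
        sbp_start=(135, 130, 150), dbp_start=(80, 80, 90),
        sbp_thh=(220, 193, 238), dbp_thh=(95, 85, 110),
        lactate_start=(1.7, 1.3, 2.2), lactate_thh=(4.3, 3.4, 5.8),
        lf_power=(12.4, 6.8, 20.2), vlf_power=(92.6, 58.9, 134.4),
        hf_power=(2.3, 1.0, 6.4),
        hr_peak_uphill=(171, 165, 179), hr_drop_30s=(12, 10, 15),
        time_uphill_s=(260, 239, 297), time_stop_s=(129, 101, 179),
        male_frac=21 / 31, smoking_prev=0.10,
    )


def cac_positive_defaults() -> GroupParams:
    """Printed cohort targets for the CAC+ group (n = 25)."""
    return GroupParams(
        age=(55, 50, 59), bmi=(25.1, 23.9, 27.6), hr_rest=(48, 45, 61),
        hr_max_lab=(172, 168, 181), vo2max=(38.3, 34.5, 44.9),
        sbp_start=(145, 130, 150), dbp_start=(80, 75, 85),
        sbp_thh=(235, 225, 245), dbp_thh=(105, 95, 110),
        lactate_start=(1.7, 1.4, 2.1), lactate_thh=(5.0, 3.9, 6.2),
        lf_power=(6.3, 2.4, 11.5), vlf_power=(64.9, 43.1, 94.3),
        hf_power=(1.6, 0.9, 3.1),
        hr_peak_uphill=(170, 160, 174), hr_drop_30s=(11, 8, 14),
        time_uphill_s=(290, 247, 320), time_stop_s=(120, 110, 179),
        male_frac=20 / 25, smoking_prev=0.10,
    )


@dataclass
class CohortConfig:
    n_neg: int = 31
    n_pos: int = 25
    group_params: dict[str, GroupParams] = field(default_factory=lambda: {
        "CAC-": cac_negative_defaults(), "CAC+": cac_positive_defaults()})
    seed: int = DEFAULT_SEED
    n_walkers_neg: int = 6
    n_walkers_pos: int = 6
    power_meter_frac: float = 38 / 56

    def __post_init__(self) -> None:
        if self.n_neg < 2 or self.n_pos < 2:
            raise ConfigError("need at least 2 subjects per group")
        for gp in self.group_params.values():
            gp.validate()
        if self.n_walkers_neg > self.n_neg or self.n_walkers_pos > self.n_pos:
            raise ConfigError("more walkers than subjects in a group")


@dataclass
class RaceProfile:
    """Timing / heart-rate skeleton of one subject's race segment (seconds)."""

    t_hill_start: float = 120.0
    t_hill_top: float = 388.0  # = stop start
    stop_duration: float = 129.0
    post_window: float = 300.0
    hr_baseline_frac: float = 0.78
    hr_hill_peak_frac: float = 0.95
    recovery_tau: float = 60.0
    recovery_drop_30s: float = 12.0
    post_rise_bpm: float = 5.0

    def __post_init__(self) -> None:
        if not self.t_hill_start < self.t_hill_top:
            raise ConfigError("hill start must precede hill top")
        if self.stop_duration <= 0:
            raise ConfigError("stop duration must be positive")
        if not (0 < self.hr_baseline_frac < self.hr_hill_peak_frac <= 1.1):
            raise ConfigError("need 0 < baseline frac < peak frac <= 1.1")

    @property
    def t_stop_start(self) -> float:
        return self.t_hill_top

    @property
    def t_stop_end(self) -> float:
        return self.t_hill_top + self.stop_duration

    @property
    def t_end(self) -> float:
        return self.t_stop_start + self.post_window + 30.0


@dataclass
class ModulationSpec:
    """RR-interval oscillations: (centre frequency Hz, amplitude ms) pairs
    plus broadband noise. One or more components per VLF/LF/HF band."""

    band_components: list[tuple[float, float]] = field(default_factory=list)
    broadband_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for f, a in self.band_components:
            if not (0.0 < f < 0.5):
                raise ConfigError(f"component frequency {f} outside (0, 0.5) Hz")
            if a < 0:
                raise ConfigError("component amplitude must be >= 0")
        if self.broadband_noise_sd < 0:
            raise ConfigError("noise SD must be >= 0")


@dataclass
class ArtifactSpec:
    rate: float = 0.03
    mix: tuple[float, float, float] = (0.4, 0.3, 0.3)  # missed, extra, ectopic
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate < 0.5):
            raise ConfigError("artifact rate must lie in [0, 0.5)")
        if abs(sum(self.mix) - 1.0) > 1e-9:
            raise ConfigError("artifact mix proportions must sum to 1")


@dataclass
class GroundTruth:
    clean_rr: dict[str, RRSeries] = field(default_factory=dict)
    artifact_positions: dict[str, np.ndarray] = field(default_factory=dict)
    subject_latents: dict[str, dict] = field(default_factory=dict)


# --------------------------------------------------------------------------
# latent sampling
# --------------------------------------------------------------------------

def _normal_from_quantiles(rng, q: Quantiles, n: int,
                           lo: float = -np.inf, hi: float = np.inf) -> np.ndarray:
    """Normal draw with mu = median and sigma matched to the IQR, truncated by
    redrawing out-of-bound values."""
    m, q25, q75 = q
    sigma = (q75 - q25) / (2 * Z75)
    x = rng.normal(m, sigma, n)
    for _ in range(100):
        bad = (x < lo) | (x > hi)
        if not bad.any():
            break
        x[bad] = rng.normal(m, sigma, bad.sum())
    return np.clip(x, lo, hi)


def _lognormal_from_quantiles(rng, q: Quantiles, n: int) -> np.ndarray:
    """Log-normal with median m and IQR ratio q75/q25; exact for degenerate
    (zero-width) quantiles."""
    m, q25, q75 = q
    if m <= 0 or q25 <= 0:
        raise ConfigError("log-normal targets must be positive")
    sigma = math.log(q75 / q25) / (2 * Z75) if q75 > q25 else 0.0
    return np.exp(rng.normal(math.log(m), sigma, n))


def _sample_group_latents(rng, gp: GroupParams, n: int) -> pd.DataFrame:
    """Per-subject latent truth for one group."""
    d = {}
    d["age"] = np.round(_normal_from_quantiles(rng, gp.age, n, 18, 90), 0)
    d["bmi"] = np.round(_normal_from_quantiles(rng, gp.bmi, n, 15, 45), 1)
    d["hr_rest"] = np.round(_normal_from_quantiles(rng, gp.hr_rest, n, 30, 100), 0)
    d["hr_max_lab"] = np.round(
        _normal_from_quantiles(rng, gp.hr_max_lab, n, 120, 220), 0)
    # resting HR must stay below lab max
    d["hr_rest"] = np.minimum(d["hr_rest"], d["hr_max_lab"] - 40)
    d["vo2max"] = np.round(_normal_from_quantiles(rng, gp.vo2max, n, 15, 80), 1)
    d["lf_power"] = _lognormal_from_quantiles(rng, gp.lf_power, n)
    d["vlf_power"] = _lognormal_from_quantiles(rng, gp.vlf_power, n)
    d["hf_power"] = _lognormal_from_quantiles(rng, gp.hf_power, n)
    d["hr_peak_uphill"] = _normal_from_quantiles(rng, gp.hr_peak_uphill, n, 90, 220)
    d["hr_peak_uphill"] = np.minimum(d["hr_peak_uphill"], 1.08 * d["hr_max_lab"])
    d["hr_drop_30s"] = _normal_from_quantiles(rng, gp.hr_drop_30s, n, 1, 60)
    d["time_uphill_s"] = _normal_from_quantiles(rng, gp.time_uphill_s, n, 60, 900)
    d["time_stop_s"] = _normal_from_quantiles(rng, gp.time_stop_s, n, 45, 600)
    d["sex"] = np.where(rng.random(n) < gp.male_frac, "M", "F")
    d["smoker"] = rng.random(n) < gp.smoking_prev
    return pd.DataFrame(d)


def generate_bp_lactate(group_params: GroupParams, rng,
                        replicate_sd: float = 0.15) -> dict:
    """Sample one subject's BP (start and hill-top) and lactate triplets.

    The hill-top systolic pressure is redrawn until it exceeds the start
    value (physiological ordering during maximal exertion); when
    ``dbp_delta`` is configured, hill-top DBP is start + sampled increase.
    """
    lo, hi = BP_BOUNDS
    sbp_start = float(_normal_from_quantiles(rng, group_params.sbp_start, 1, lo, hi)[0])
    dbp_start = float(_normal_from_quantiles(rng, group_params.dbp_start, 1, lo, hi)[0])
    if dbp_start >= sbp_start:  # degenerate draw; keep pulse pressure positive
        dbp_start = sbp_start - 30.0
    sbp_thh = float(_normal_from_quantiles(rng, group_params.sbp_thh, 1, lo, hi)[0])
    for _ in range(200):
        if sbp_thh > sbp_start:
            break
        sbp_thh = float(
            _normal_from_quantiles(rng, group_params.sbp_thh, 1, lo, hi)[0])
    else:
        sbp_thh = sbp_start + 5.0
    if group_params.dbp_delta is not None:
        dbp_thh = dbp_start + float(
            _normal_from_quantiles(rng, group_params.dbp_delta, 1)[0])
    else:
        dbp_thh = float(
            _normal_from_quantiles(rng, group_params.dbp_thh, 1, lo, hi)[0])
    if dbp_thh >= sbp_thh:
        dbp_thh = sbp_thh - 30.0

    def triplet(q: Quantiles) -> tuple[float, float, float]:
        base = float(_normal_from_quantiles(rng, q, 1, 0.3, 30)[0])
        reps = base + rng.normal(0.0, replicate_sd, 3)
        return tuple(np.round(np.maximum(reps, 0.1), 1))

    return {
        "sbp_start": round(sbp_start), "dbp_start": round(dbp_start),
        "sbp_thh": round(sbp_thh), "dbp_thh": round(dbp_thh),
        "lactate_start": triplet(group_params.lactate_start),
        "lactate_thh": triplet(group_params.lactate_thh),
    }


def generate_cohort(config: CohortConfig) -> tuple[list[SubjectRecord], GroundTruth]:
    """Sample the full cohort: metadata, BP/lactate, per-subject latent
    spectral powers and race timings. Group labels are assigned before
    sampling; identical seeds give bit-identical cohorts."""
    rng = np.random.default_rng(config.seed)
    subjects: list[SubjectRecord] = []
    truth = GroundTruth()
    for group, n, n_walk in (("CAC-", config.n_neg, config.n_walkers_neg),
                             ("CAC+", config.n_pos, config.n_walkers_pos)):
        gp = config.group_params[group]
        lat = _sample_group_latents(rng, gp, n)
        # walkers: the least-fit subjects of the group dismount on the climb
        walker = np.zeros(n, dtype=bool)
        if n_walk > 0:
            walker[np.argsort(lat["vo2max"].to_numpy(), kind="stable")[:n_walk]] = True
        lat["walker"] = walker
        lat["has_power_meter"] = rng.random(n) < config.power_meter_frac
        for i in range(n):
            tag = "n" if group == "CAC-" else "p"
            sid = f"S{tag}{i + 1:03d}"
            bp = generate_bp_lactate(gp, rng)
            row = lat.iloc[i]
            subjects.append(SubjectRecord(
                subject_id=sid, group=group, age=float(row["age"]),
                sex=str(row["sex"]), bmi=float(row["bmi"]),
                hr_rest=float(row["hr_rest"]),
                hr_max_lab=float(row["hr_max_lab"]),
                vo2max=float(row["vo2max"]), smoker=bool(row["smoker"]),
                has_power_meter=bool(row["has_power_meter"]),
                sbp_start=bp["sbp_start"], dbp_start=bp["dbp_start"],
                sbp_thh=bp["sbp_thh"], dbp_thh=bp["dbp_thh"],
                lactate_start=bp["lactate_start"],
                lactate_thh=bp["lactate_thh"],
            ))
            truth.subject_latents[sid] = {
                k: (row[k].item() if hasattr(row[k], "item") else row[k])
                for k in ("lf_power", "vlf_power", "hf_power",
                          "hr_peak_uphill", "hr_drop_30s",
                          "time_uphill_s", "time_stop_s", "walker")
            }
    return subjects, truth


# --------------------------------------------------------------------------
# beat generation (IPFM)
# --------------------------------------------------------------------------

def _hr_trajectory(tgrid: np.ndarray, profile: RaceProfile,
                   hr_max_lab: float) -> np.ndarray:
    """Piecewise deterministic HR skeleton (bpm): baseline riding, linear
    climb to the uphill peak, mono-exponential post-stop recovery toward a
    plateau, then a gentle rise once riding resumes."""
    base = profile.hr_baseline_frac * hr_max_lab
    peak = profile.hr_hill_peak_frac * hr_max_lab
    tau = profile.recovery_tau
    amp = profile.recovery_drop_30s / -math.expm1(-30.0 / tau)
    plateau = peak - amp
    t0, t1 = profile.t_hill_start, profile.t_hill_top
    t_ramp_end = t0 + 0.6 * (t1 - t0)  # peak reached before the top
    hr = np.full_like(tgrid, base)
    ramp = (tgrid >= t0) & (tgrid < t_ramp_end)
    hr[ramp] = base + (peak - base) * (tgrid[ramp] - t0) / (t_ramp_end - t0)
    hr[(tgrid >= t_ramp_end) & (tgrid < t1)] = peak
    rec = tgrid >= t1
    hr[rec] = plateau + amp * np.exp(-(tgrid[rec] - t1) / tau)
    # remount: relax toward plateau + post_rise with a 30 s time constant
    t2 = profile.t_stop_end
    post = tgrid >= t2
    if post.any():
        hr_at_t2 = plateau + amp * math.exp(-(t2 - t1) / tau)
        target = plateau + profile.post_rise_bpm
        hr[post] = target + (hr_at_t2 - target) * np.exp(-(tgrid[post] - t2) / 30.0)
    return hr


def generate_rr_series(subject: SubjectRecord, profile: RaceProfile,
                       mod: ModulationSpec, seed: int,
                       dt: float = 0.05) -> RRSeries:
    """Generate a beat series by IPFM.

    The target RR interval is the skeleton 60000/HR(t) plus the sinusoidal
    band modulation (ms); the instantaneous beat rate 1000/RR_target(t) is
    integrated on a ``dt``-spaced grid and a beat is emitted at each unit
    crossing of the integral.
    """
    if profile.t_end <= profile.t_stop_start + profile.post_window - 1e-9:
        raise ConfigError("profile must cover the stop plus the post window")
    rng = np.random.default_rng(seed)
    tgrid = np.arange(0.0, profile.t_end + dt, dt)
    hr = _hr_trajectory(tgrid, profile, subject.hr_max_lab)
    rr_target = 60000.0 / hr
    for f, a in mod.band_components:
        phase = rng.uniform(0, 2 * np.pi)
        rr_target = rr_target + a * np.sin(2 * np.pi * f * tgrid + phase)
    if mod.broadband_noise_sd > 0:
        rr_target = rr_target + rng.normal(0, mod.broadband_noise_sd, tgrid.size)
    if np.any(rr_target <= 0):
        raise ValueError("modulated RR target non-positive: rate trajectory invalid")
    rate = 1000.0 / rr_target  # beats per second
    cum = cumulative_trapezoid(rate, tgrid, initial=0.0)
    n_beats = int(np.floor(cum[-1]))
    if n_beats < 2:
        raise ValueError("recording too short to emit beats")
    beat_t = np.interp(np.arange(0, n_beats + 1, dtype=float), cum, tgrid)
    rr_ms = np.diff(beat_t) * 1000.0
    return RRSeries(rr=rr_ms, t=beat_t[1:] * 1000.0, provenance="raw")


def modulation_from_latents(latents: dict, rng,
                            broadband_noise_sd: float = 1.0) -> ModulationSpec:
    """One sinusoid per band with amplitude sqrt(2 * power) so the band power
    of the generated tachogram matches the subject's latent target."""
    def freq(lo: float, hi: float) -> float:
        return float(rng.uniform(lo, hi))

    comps = [
        (freq(0.015, 0.03), math.sqrt(2 * latents["vlf_power"])),
        (freq(0.07, 0.12), math.sqrt(2 * latents["lf_power"])),
        (freq(0.20, 0.30), math.sqrt(2 * latents["hf_power"])),
    ]
    return ModulationSpec(band_components=comps,
                          broadband_noise_sd=broadband_noise_sd)


# --------------------------------------------------------------------------
# artifact injection
# --------------------------------------------------------------------------

def inject_artifacts(rr: RRSeries, spec: ArtifactSpec) -> tuple[RRSeries, np.ndarray]:
    """Corrupt a clean series with missed, extra and ectopic beats.

    missed — two adjacent intervals merged into one; extra — one interval
    split in two; ectopic — one interval shortened and the next lengthened
    by the same amount. Total recording time is conserved. Returns the
    corrupted series and the indices (into the corrupted series) of every
    altered interval.
    """
    n = len(rr)
    if n < 10:
        raise ValueError("need at least 10 beats to inject artifacts")
    rng = np.random.default_rng(spec.seed)
    n_sites = int(round(spec.rate * n))
    if n_sites == 0:
        return RRSeries(rr.rr.copy(), rr.t.copy(), rr.provenance), np.array([], int)
    # candidate sites need two intervals (i, i+1) and 3-beat separation
    candidates = np.arange(2, n - 3)
    if n_sites > candidates.size // 3:
        raise ValueError("artifact rate too high: corrupted sites would overlap")
    sites: list[int] = []
    order = rng.permutation(candidates)
    taken = np.zeros(n, dtype=bool)
    for i in order:
        if not taken[max(i - 2, 0): i + 4].any():
            sites.append(int(i))
            taken[i: i + 2] = True
            if len(sites) == n_sites:
                break
    if len(sites) < n_sites:
        raise ValueError("artifact rate too high: corrupted sites would overlap")
    kinds = rng.choice(3, size=n_sites, p=list(spec.mix))  # 0 missed 1 extra 2 ectopic
    new_rr = list(rr.rr)
    positions: list[int] = []
    shift = 0  # cumulative index shift from insertions/deletions so far
    for site, kind in sorted(zip(sites, kinds)):
        i = site + shift
        if kind == 0:  # missed beat: merge i and i+1
            new_rr[i: i + 2] = [new_rr[i] + new_rr[i + 1]]
            positions.append(i)
            shift -= 1
        elif kind == 1:  # extra beat: split interval i
            u = rng.uniform(0.4, 0.6)
            v = new_rr[i]
            new_rr[i: i + 1] = [u * v, (1 - u) * v]
            positions.extend([i, i + 1])
            shift += 1
        else:  # ectopic: early beat, compensatory pause
            d = rng.uniform(0.25, 0.40) * min(new_rr[i], new_rr[i + 1])
            new_rr[i] -= d
            new_rr[i + 1] += d
            positions.extend([i, i + 1])
    corrupted = rr.with_intervals(np.array(new_rr), provenance="raw")
    assert abs(corrupted.duration_ms - rr.duration_ms) < 1.0
    return corrupted, np.array(sorted(positions), dtype=int)


# --------------------------------------------------------------------------
# power / speed traces and full-cohort simulation
# --------------------------------------------------------------------------

def generate_power_speed(latents: dict, profile: RaceProfile, rng,
                         has_power_meter: bool = True,
                         riding_watts: float = 250.0,
                         riding_speed: float = 2.4,
                         walking_speed: float = 1.2) -> pd.DataFrame:
    """1 Hz power/speed trace over the climb (with 30 s margins). Walkers
    show zero power and walking speed over the middle 40% of the climb;
    subjects without a power meter get a speed-only trace (watts = NaN)."""
    t = np.arange(max(profile.t_hill_start - 30.0, 0.0),
                  profile.t_hill_top + 30.0, 1.0)
    watts = rng.normal(riding_watts, 20.0, t.size)
    speed = rng.normal(riding_speed, 0.15, t.size)
    pre = t < profile.t_hill_start
    watts[pre] *= 0.6  # flat approach is easier than the climb
    if latents.get("walker"):
        climb_len = profile.t_hill_top - profile.t_hill_start
        w0 = profile.t_hill_start + 0.3 * climb_len
        w1 = w0 + 0.4 * climb_len
        walk = (t >= w0) & (t < w1)
        watts[walk] = 0.0
        speed[walk] = rng.normal(walking_speed, 0.08, walk.sum())
    watts = np.maximum(watts, 0.0)
    speed = np.maximum(speed, 0.2)
    if not has_power_meter:
        watts = np.full(t.size, np.nan)
    return pd.DataFrame({"t_s": t, "watts": watts, "speed_mps": speed})


def profile_for_subject(latents: dict, subject: SubjectRecord,
                        t_hill_start: float = 120.0,
                        recovery_tau: float = 60.0,
                        post_window: float = 300.0) -> RaceProfile:
    peak_frac = float(np.clip(latents["hr_peak_uphill"] / subject.hr_max_lab,
                              0.82, 1.1))
    return RaceProfile(
        t_hill_start=t_hill_start,
        t_hill_top=t_hill_start + latents["time_uphill_s"],
        stop_duration=latents["time_stop_s"],
        post_window=post_window,
        hr_baseline_frac=min(0.78, peak_frac - 0.04),
        hr_hill_peak_frac=peak_frac,
        recovery_tau=recovery_tau,
        recovery_drop_30s=latents["hr_drop_30s"],
    )


def simulate_cohort(config: CohortConfig,
                    artifacts: ArtifactSpec | None = None,
                    broadband_noise_sd: float = 1.0,
                    emit_power: bool = True):
    """End-to-end simulation: cohort metadata, IPFM beat series per subject,
    artifact corruption and power/speed traces.

    Returns ``(subjects, rr, power, truth)`` where ``rr`` holds the corrupted
    (observed) series and ``truth.clean_rr`` the pre-corruption series.
    """
    subjects, truth = generate_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    rr: dict[str, RRSeries] = {}
    power: dict[str, pd.DataFrame] = {}
    for s in subjects:
        lat = truth.subject_latents[s.subject_id]
        profile = profile_for_subject(lat, s)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        mod = modulation_from_latents(lat, np.random.default_rng(sub_seed),
                                      broadband_noise_sd)
        clean = generate_rr_series(s, profile, mod, seed=sub_seed + 1)
        truth.clean_rr[s.subject_id] = clean
        if artifacts is not None and artifacts.rate > 0:
            corrupted, pos = inject_artifacts(
                clean, ArtifactSpec(rate=artifacts.rate, mix=artifacts.mix,
                                    seed=sub_seed + 2))
        else:
            corrupted, pos = clean, np.array([], int)
        rr[s.subject_id] = corrupted
        truth.artifact_positions[s.subject_id] = pos
        s.events = Events(profile.t_hill_start, profile.t_stop_start,
                          profile.t_stop_end)
        lat["events"] = (profile.t_hill_start, profile.t_stop_start,
                         profile.t_stop_end)
        if emit_power:
            power[s.subject_id] = generate_power_speed(
                lat, profile, np.random.default_rng(sub_seed + 3),
                has_power_meter=s.has_power_meter)
    logger.info("simulated cohort: %d subjects, seed %d", len(subjects),
                config.seed)
    return subjects, rr, power, truth


__all__ = [
    "GroupParams", "CohortConfig", "RaceProfile", "ModulationSpec",
    "ArtifactSpec", "GroundTruth", "cac_negative_defaults",
    "cac_positive_defaults", "generate_cohort", "generate_rr_series",
    "generate_bp_lactate", "inject_artifacts", "modulation_from_latents",
    "simulate_cohort", "generate_power_speed", "profile_for_subject",
    "DEFAULT_SEED",
]
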