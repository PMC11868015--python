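"""Per-subject haemodynamic indices around the hill stop.

Heart-rate summaries are taken from a smoothed instantaneous-HR series:
60000/RR evaluated at beat times, interpolated onto a 1 Hz grid and averaged
with a 5 s centred window. HR "at" a time point therefore means a 5 s mean —
beat-level HR at an instant is noisy and a short smoothing window is the
conventional estimator. Each summary HR is also expressed as a percentage of
the laboratory maximum and as the HR reserve fraction

    reserve = (HR - HR_rest) / (HR_max,lab - HR_rest)

where HR_max,lab comes from a laboratory VO2max test and HR_rest is the
subject's self-reported resting rate.

Pressure indices: pulse pressure (SBP - DBP) at each measurement site,
start-to-hilltop deltas, and rate-pressure products — maximum RPP = hilltop
SBP x maximum uphill HR, mean RPP = hilltop SBP x mean HR during the stop
(the pressure cuff is read during the stop, so the stop-mean HR is the
matching rate).

Lactate is measured in triplicate; the reported value is the mean of the two
closest replicates (ties broken toward the pair with the lower mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RRSeries, SubjectRecord, Events, logger

HR_SMOOTH_S = 5.0
GAP_WARN_S = 10.0


@dataclass
class HRSummary:
    hr_max_uphill: float
    mean_hr_stop: float
    mean_hr_5min: float
    recovery_30s: float
    pct_max_uphill: float
    pct_max_stop: float
    pct_max_5min: float
    reserve_uphill: float
    reserve_stop: float
    reserve_5min: float


@dataclass
class BPDerived:
    pp_start: float
    pp_thh: float
    delta_sbp: float
    delta_dbp: float
    delta_pp: float
    rpp_max: float
    rpp_mean: float


def hr_reserve(hr: float, hr_rest: float, hr_max_lab: float) -> float:
    """Fraction of the heart-rate reserve used at rate ``hr``."""
    if hr_max_lab <= hr_rest:
        raise ValueError("hr_max_lab must exceed hr_rest")
    return (hr - hr_rest) / (hr_max_lab - hr_rest)


def hr_timeseries(rr: RRSeries, hz: float = 1.0,
                  smooth_s: float = HR_SMOOTH_S) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed instantaneous HR (bpm) on an even grid (seconds)."""
    t_s = rr.t / 1000.0
    hr = rr.instantaneous_hr()
    grid = np.arange(t_s[0], t_s[-1], 1.0 / hz)
    h = np.interp(grid, t_s, hr)
    k = max(int(round(smooth_s * hz)), 1)
    kernel = np.ones(k) / k
    # centred moving average; edges use the shrinking-window mean
    sm = np.convolve(h, kernel, mode="same")
    norm = np.convolve(np.ones_like(h), kernel, mode="same")
    return grid, sm / norm


def _window_mean(t: np.ndarray, hr: np.ndarray, t0: float, t1: float) -> float:
    sel = (t >= t0) & (t < t1)
    if not sel.any():
        raise ValueError(f"no HR samples in window [{t0}, {t1}) s")
    return float(hr[sel].mean())


def _check_gaps(rr: RRSeries, t0: float, t1: float) -> None:
    t_s = rr.t / 1000.0
    sel = (t_s >= t0) & (t_s <= t1)
    if sel.sum() >= 2 and np.max(np.diff(t_s[sel])) > GAP_WARN_S:
        logger.warning("HR gap > %.0f s inside window [%.0f, %.0f) s",
                       GAP_WARN_S, t0, t1)


def hr_at(t: np.ndarray, hr: np.ndarray, when: float,
          half_width: float = HR_SMOOTH_S / 2) -> float:
    """HR at a time point, taken as a 5 s mean centred on the point."""
    sel = (t >= when - half_width) & (t <= when + half_width)
    if not sel.any():
        raise ValueError(f"no HR samples around t = {when} s")
    return float(hr[sel].mean())


def hr_recovery(t: np.ndarray, hr: np.ndarray, t_stop: float) -> float:
    """HR drop over the 30 s after stopping: HR(t_stop) - HR(t_stop + 30)."""
    if t[-1] < t_stop + 30.0 - HR_SMOOTH_S / 2 or t[0] > t_stop:
        raise ValueError("series does not cover [t_stop, t_stop + 30 s]")
    return hr_at(t, hr, t_stop) - hr_at(t, hr, t_stop + 30.0)


def summarize_hr(rr: RRSeries, events: Events, hr_rest: float,
                 hr_max_lab: float, post_window_s: float = 300.0) -> HRSummary:
    """HR summaries over the climb, the stop, and the 5 min after the stop."""
    t, hr = hr_timeseries(rr)
    if t[0] > events.t_hill_start or t[-1] < events.t_stop_start + post_window_s - HR_SMOOTH_S:
        raise ValueError("HR series does not cover hill start through "
                         "stop + post window")
    for t0, t1 in ((events.t_hill_start, events.t_stop_start),
                   (events.t_stop_start, events.t_stop_end),
                   (events.t_stop_start, events.t_stop_start + post_window_s)):
        _check_gaps(rr, t0, t1)
    uphill = (t >= events.t_hill_start) & (t < events.t_stop_start)
    hr_max_up = float(hr[uphill].max())
    mean_stop = _window_mean(t, hr, events.t_stop_start, events.t_stop_end)
    mean_5min = _window_mean(t, hr, events.t_stop_start,
                             events.t_stop_start + post_window_s)
    rec = hr_recovery(t, hr, events.t_stop_start)

    def pct(h: float) -> float:
        return 100.0 * h / hr_max_lab

    def res(h: float) -> float:
        return 100.0 * hr_reserve(h, hr_rest, hr_max_lab)

    return HRSummary(
        hr_max_uphill=hr_max_up, mean_hr_stop=mean_stop,
        mean_hr_5min=mean_5min, recovery_30s=rec,
        pct_max_uphill=pct(hr_max_up), pct_max_stop=pct(mean_stop),
        pct_max_5min=pct(mean_5min),
        reserve_uphill=res(hr_max_up), reserve_stop=res(mean_stop),
        reserve_5min=res(mean_5min),
    )


def bp_derive(record: SubjectRecord, hr_summary: HRSummary) -> BPDerived:
    """Pulse pressures, start-to-hilltop deltas and rate-pressure products."""
    for sbp, dbp, site in ((record.sbp_start, record.dbp_start, "start"),
                           (record.sbp_thh, record.dbp_thh, "THH")):
        if dbp >= sbp:
            raise ValueError(f"DBP >= SBP at {site}: measurement fault")
    return BPDerived(
        pp_start=record.sbp_start - record.dbp_start,
        pp_thh=record.sbp_thh - record.dbp_thh,
        delta_sbp=record.sbp_thh - record.sbp_start,
        delta_dbp=record.dbp_thh - record.dbp_start,
        delta_pp=(record.sbp_thh - record.dbp_thh)
        - (record.sbp_start - record.dbp_start),
        rpp_max=record.sbp_thh * hr_summary.hr_max_uphill,
        rpp_mean=record.sbp_thh * hr_summary.mean_hr_stop,
    )


def aggregate_lactate(*values: float) -> float:
    """Mean of the two closest of three replicates.

    With fewer than three values the mean of what is available is returned
    (flagged in the log). Equal gaps resolve toward the pair with the lower
    mean.
    """
    vals = [float(v) for v in values]
    if any(v <= 0 for v in vals):
        raise ValueError("lactate replicates must be positive")
    if len(vals) < 3:
        logger.warning("only %d lactate replicate(s); using their mean", len(vals))
        return float(np.mean(vals))
    if len(vals) != 3:
        raise ValueError("expected at most three lactate replicates")
    pairs = [(vals[0], vals[1]), (vals[0], vals[2]), (vals[1], vals[2])]
    best = min(pairs, key=lambda p: (abs(p[0] - p[1]), (p[0] + p[1]) / 2))
    gaps = sorted(abs(a - b) for a, b in pairs)
    if gaps[0] == gaps[1]:
        logger.info("lactate tie: equal gaps, using lower-mean pair")
    return (best[0] + best[1]) / 2.0


__all__ = [
    "HRSummary", "BPDerived", "hr_reserve", "hr_timeseries", "hr_at",
    "hr_recovery", "summarize_hr", "bp_derive", "aggregate_lactate",
]
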