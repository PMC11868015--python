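"""Time- and frequency-domain heart-rate-variability metrics.

Time-domain indices (RMSSD, SDNN) are computed directly on the corrected,
unevenly spaced beat series. Frequency-domain band powers are computed from
a single-segment FFT periodogram of the tachogram after cubic-spline
resampling onto an even grid (4 Hz default; Nyquist 2 Hz well above the
0.4 Hz upper band edge). The mean and linear trend are removed before the
FFT; no taper is applied by default. Band power is the sum of one-sided
periodogram ordinates (scaled so the full sum equals the detrended mean
square, i.e. powers are in ms^2) over

    VLF (0, 0.04] Hz — excluding the zero bin, which detrending removes
    LF  (0.04, 0.15] Hz
    HF  (0.15, 0.4] Hz

with half-open, upper-inclusive edges so no bin is counted twice. Total
power is the sum of the three bands by construction.

The standard analysis window is the 5 min following (and including) the
race stop; ultra-short LF estimates need roughly 90 s of data to be
reliable, so shorter windows are flagged with a warning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import periodogram

from .core import RRSeries, logger

DEFAULT_RESAMPLE_HZ = 4.0
DEFAULT_WINDOW_S = 300.0
MIN_RELIABLE_S = 90.0

#: (low, high] band edges in Hz.
DEFAULT_BANDS = {"vlf": (0.0, 0.04), "lf": (0.04, 0.15), "hf": (0.15, 0.4)}


@dataclass
class AnalysisWindow:
    """Half-open window [t_start, t_start + duration) in seconds."""

    t_start: float
    duration: float = DEFAULT_WINDOW_S

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("window duration must be positive")


@dataclass
class HRVResult:
    rmssd: float
    sdnn: float
    vlf: float
    lf: float
    hf: float
    tp: float
    n_beats: int
    resample_hz: float
    correction_method: str = "raw"


def extract_window(rr: RRSeries, window: AnalysisWindow) -> RRSeries:
    """Beats whose occurrence time lies inside the window (times in s)."""
    t0, t1 = window.t_start * 1000.0, (window.t_start + window.duration) * 1000.0
    sel = (rr.t >= t0) & (rr.t < t1)
    if not sel.any():
        raise ValueError("analysis window contains no beats")
    out = RRSeries(rr=rr.rr[sel], t=rr.t[sel], provenance=rr.provenance)
    span_s = (out.t[-1] - out.t[0]) / 1000.0
    if span_s < MIN_RELIABLE_S:
        logger.warning("analysis window holds only %.0f s of beats; "
                       "LF power may be unreliable below ~90 s", span_s)
    return out


def rmssd(rr: RRSeries | np.ndarray) -> float:
    """Root mean square of successive RR differences (ms)."""
    x = rr.rr if isinstance(rr, RRSeries) else np.asarray(rr, float)
    if x.size < 2:
        raise ValueError("RMSSD needs at least 2 beats")
    return float(np.sqrt(np.mean(np.diff(x) ** 2)))


def sdnn(rr: RRSeries | np.ndarray) -> float:
    """Sample standard deviation (n - 1 denominator) of RR intervals (ms)."""
    x = rr.rr if isinstance(rr, RRSeries) else np.asarray(rr, float)
    if x.size < 2:
        raise ValueError("SDNN needs at least 2 beats")
    return float(np.std(x, ddof=1))


def resample_tachogram(rr: RRSeries,
                       resample_hz: float = DEFAULT_RESAMPLE_HZ
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline resampling of RR(t) onto an even grid.

    Returns ``(t_s, rr_ms)``; the grid spans [first beat, last beat] so no
    extrapolation occurs.
    """
    if len(rr) < 4:
        raise ValueError("resampling needs at least 4 beats")
    t_s = rr.t / 1000.0
    if np.any(np.diff(t_s) <= 0):
        raise ValueError("duplicate or non-increasing beat times")
    spline = CubicSpline(t_s, rr.rr)
    grid = np.arange(t_s[0], t_s[-1] + 0.5 / resample_hz, 1.0 / resample_hz)
    grid = grid[grid <= t_s[-1]]
    return grid, spline(grid)


def spectral_band_powers(values: np.ndarray,
                         resample_hz: float = DEFAULT_RESAMPLE_HZ,
                         bands: dict[str, tuple[float, float]] | None = None
                         ) -> dict[str, float]:
    """Band powers (ms^2) of an evenly resampled tachogram.

    Single-segment boxcar periodogram with linear detrend; ordinates scaled
    so their sum equals the mean square of the detrended signal.
    """
    x = np.asarray(values, dtype=float)
    min_len = int(2 * resample_hz * 30)
    if x.size < min_len:
        raise ValueError(
            f"series too short for spectral analysis ({x.size} < {min_len})")
    bands = bands or DEFAULT_BANDS
    f, p = periodogram(x, fs=resample_hz, window="boxcar",
                       detrend="linear", scaling="spectrum")
    out = {}
    for name, (lo, hi) in bands.items():
        out[name] = float(p[(f > lo) & (f <= hi)].sum())
    out["tp"] = float(sum(out[b] for b in bands))
    return out


def hrv_metrics(rr: RRSeries, window: AnalysisWindow | None = None,
                resample_hz: float = DEFAULT_RESAMPLE_HZ) -> HRVResult:
    """All HRV indices for one (optionally windowed) beat series.

    RMSSD/SDNN come from the beat series itself; spectral powers from the
    resampled tachogram.
    """
    seg = extract_window(rr, window) if window is not None else rr
    _, resampled = resample_tachogram(seg, resample_hz)
    powers = spectral_band_powers(resampled, resample_hz)
    method = (rr.provenance.split(":", 1)[1]
              if rr.provenance.startswith("corrected:") else "raw")
    return HRVResult(
        rmssd=rmssd(seg), sdnn=sdnn(seg),
        vlf=powers["vlf"], lf=powers["lf"], hf=powers["hf"], tp=powers["tp"],
        n_beats=len(seg), resample_hz=resample_hz, correction_method=method,
    )


__all__ = [
    "AnalysisWindow", "HRVResult", "extract_window", "rmssd", "sdnn",
    "resample_tachogram", "spectral_band_powers", "hrv_metrics",
    "DEFAULT_BANDS", "DEFAULT_RESAMPLE_HZ",
]
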