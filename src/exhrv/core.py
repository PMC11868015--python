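"""Shared containers and on-disk formats for the exercise-HRV pipeline.

The beat-to-beat series is the central object: an ordered sequence of RR
intervals (ms) together with the cumulative occurrence time of each beat.
Everything downstream — artifact correction, tachogram resampling, heart-rate
summaries — consumes and produces this container.

Cohort data live as plain CSV/JSON in a directory:

    subjects.csv          one row per subject (metadata, BP, lactate)
    events.csv            hill start / stop start / stop end per subject (s)
    rr/<subject_id>.csv   columns t_ms, rr_ms
    power/<subject_id>.csv  columns t_s, watts, speed_mps (optional)
    ground_truth.json     simulator latents and artifact positions
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("exhrv")

#: Physiological bounds used when sampling / validating blood pressure (mmHg).
BP_BOUNDS = (30.0, 320.0)

#: Tolerance (ms) for the t-vs-cumsum(rr) consistency invariant.
TIME_TOL_MS = 1.0


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class RRSeries:
    """Beat-to-beat RR intervals with beat occurrence times.

    Parameters
    ----------
    rr
        Interval lengths in milliseconds, all strictly positive.
    t
        Cumulative occurrence time (ms) of the beat ending each interval;
        strictly increasing, with ``diff(t) == rr[1:]`` to within 1 ms.
    provenance
        ``"raw"`` or ``"corrected:<method>"``.
    """

    rr: np.ndarray
    t: np.ndarray
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.rr.ndim != 1 or self.t.shape != self.rr.shape:
            raise ValueError("rr and t must be 1-D arrays of equal length")
        if self.rr.size and np.any(self.rr <= 0):
            raise ValueError("all RR intervals must be positive")
        if self.rr.size > 1:
            if np.any(np.diff(self.t) <= 0):
                raise ValueError("beat times must be strictly increasing")
            if np.max(np.abs(np.diff(self.t) - self.rr[1:])) > TIME_TOL_MS:
                raise ValueError("beat-time differences inconsistent with rr")

    @classmethod
    def from_intervals(
        cls, rr: np.ndarray, t0: float = 0.0, provenance: str = "raw"
    ) -> "RRSeries":
        """Build a series from intervals alone; beat k occurs at
        ``t0 + sum(rr[:k+1])``."""
        rr = np.asarray(rr, dtype=float)
        return cls(rr=rr, t=t0 + np.cumsum(rr), provenance=provenance)

    def __len__(self) -> int:
        return int(self.rr.size)

    @property
    def start_time(self) -> float:
        """Time (ms) at which the first interval begins."""
        return float(self.t[0] - self.rr[0])

    @property
    def duration_ms(self) -> float:
        return float(self.rr.sum())

    def with_intervals(self, rr: np.ndarray, provenance: str) -> "RRSeries":
        """New series with replaced intervals, re-timed from the same origin."""
        rr = np.asarray(rr, dtype=float)
        return RRSeries(
            rr=rr, t=self.start_time + np.cumsum(rr), provenance=provenance
        )

    def instantaneous_hr(self) -> np.ndarray:
        """Instantaneous heart rate (bpm) at each beat, 60000 / rr."""
        return 60000.0 / self.rr

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t_ms": self.t, "rr_ms": self.rr}).to_csv(
            path, index=False, float_format="%.6f"
        )

    @classmethod
    def read_csv(cls, path: str | Path, provenance: str = "raw") -> "RRSeries":
        df = pd.read_csv(path)
        return cls(
            rr=df["rr_ms"].to_numpy(float),
            t=df["t_ms"].to_numpy(float),
            provenance=provenance,
        )


@dataclass
class Events:
    """Race timeline for one subject (seconds from recording start)."""

    t_hill_start: float
    t_stop_start: float
    t_stop_end: float

    def __post_init__(self) -> None:
        if not (0 <= self.t_hill_start < self.t_stop_start < self.t_stop_end):
            raise ValueError("events must be ordered: hill start < stop start < stop end")


@dataclass
class SubjectRecord:
    """Per-subject metadata, events and point measurements.

    BP (mmHg) and lactate (mmol/L, three replicates) are measured at two
    sites: just before the race start and at the top of the hardest hill
    (THH) during a brief stop.
    """

    subject_id: str
    group: str  # "CAC-" or "CAC+"
    age: float
    sex: str  # "M" / "F"
    bmi: float
    hr_rest: float
    hr_max_lab: float
    vo2max: float
    smoker: bool
    sbp_start: float
    dbp_start: float
    sbp_thh: float
    dbp_thh: float
    lactate_start: tuple[float, float, float]
    lactate_thh: tuple[float, float, float]
    events: Events | None = None
    has_power_meter: bool = False

    def __post_init__(self) -> None:
        if self.group not in ("CAC-", "CAC+"):
            raise ValueError(f"group must be 'CAC-' or 'CAC+', got {self.group!r}")
        if self.hr_rest >= self.hr_max_lab:
            raise ValueError("hr_rest must be below hr_max_lab")
        for v in (self.sbp_start, self.dbp_start, self.sbp_thh, self.dbp_thh):
            if not (BP_BOUNDS[0] <= v <= BP_BOUNDS[1]):
                raise ValueError(f"blood pressure {v} outside physiological bounds")


SUBJECT_COLUMNS = [
    "subject_id", "group", "age", "sex", "bmi", "hr_rest", "hr_max_lab",
    "vo2max", "smoker", "has_power_meter",
    "sbp_start", "dbp_start", "sbp_thh", "dbp_thh",
    "lactate_start_1", "lactate_start_2", "lactate_start_3",
    "lactate_thh_1", "lactate_thh_2", "lactate_thh_3",
]


def subjects_to_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        rows.append({
            "subject_id": s.subject_id, "group": s.group, "age": s.age,
            "sex": s.sex, "bmi": s.bmi, "hr_rest": s.hr_rest,
            "hr_max_lab": s.hr_max_lab, "vo2max": s.vo2max,
            "smoker": int(s.smoker), "has_power_meter": int(s.has_power_meter),
            "sbp_start": s.sbp_start, "dbp_start": s.dbp_start,
            "sbp_thh": s.sbp_thh, "dbp_thh": s.dbp_thh,
            "lactate_start_1": s.lactate_start[0],
            "lactate_start_2": s.lactate_start[1],
            "lactate_start_3": s.lactate_start[2],
            "lactate_thh_1": s.lactate_thh[0],
            "lactate_thh_2": s.lactate_thh[1],
            "lactate_thh_3": s.lactate_thh[2],
        })
    return pd.DataFrame(rows, columns=SUBJECT_COLUMNS)


def frame_to_subjects(
    df: pd.DataFrame, events: dict[str, Events] | None = None
) -> list[SubjectRecord]:
    out = []
    for _, r in df.iterrows():
        sid = str(r["subject_id"])
        out.append(SubjectRecord(
            subject_id=sid, group=str(r["group"]), age=float(r["age"]),
            sex=str(r["sex"]), bmi=float(r["bmi"]), hr_rest=float(r["hr_rest"]),
            hr_max_lab=float(r["hr_max_lab"]), vo2max=float(r["vo2max"]),
            smoker=bool(int(r["smoker"])),
            has_power_meter=bool(int(r.get("has_power_meter", 0))),
            sbp_start=float(r["sbp_start"]), dbp_start=float(r["dbp_start"]),
            sbp_thh=float(r["sbp_thh"]), dbp_thh=float(r["dbp_thh"]),
            lactate_start=(float(r["lactate_start_1"]),
                           float(r["lactate_start_2"]),
                           float(r["lactate_start_3"])),
            lactate_thh=(float(r["lactate_thh_1"]),
                         float(r["lactate_thh_2"]),
                         float(r["lactate_thh_3"])),
            events=events.get(sid) if events else None,
        ))
    return out


def write_cohort(
    out_dir: str | Path,
    subjects: list[SubjectRecord],
    rr: dict[str, RRSeries],
    power: dict[str, pd.DataFrame] | None = None,
    ground_truth: dict | None = None,
) -> None:
    """Write a cohort directory in the plain-text layout described above."""
    out = Path(out_dir)
    (out / "rr").mkdir(parents=True, exist_ok=True)
    subjects_to_frame(subjects).to_csv(out / "subjects.csv", index=False)
    ev = pd.DataFrame(
        [{"subject_id": s.subject_id,
          "t_hill_start_s": s.events.t_hill_start,
          "t_stop_start_s": s.events.t_stop_start,
          "t_stop_end_s": s.events.t_stop_end} for s in subjects]
    )
    ev.to_csv(out / "events.csv", index=False)
    for sid, series in rr.items():
        series.to_csv(out / "rr" / f"{sid}.csv")
    if power:
        (out / "power").mkdir(exist_ok=True)
        for sid, df in power.items():
            df.to_csv(out / "power" / f"{sid}.csv", index=False,
                      float_format="%.3f")
    if ground_truth is not None:
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(ground_truth, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def read_cohort(data_dir: str | Path):
    """Read a cohort directory.

    Returns ``(subjects, rr, power)`` where ``rr`` maps subject_id to
    :class:`RRSeries` and ``power`` maps subject_id to a DataFrame with
    columns t_s / watts / speed_mps (empty dict when absent).
    """
    data = Path(data_dir)
    ev_df = pd.read_csv(data / "events.csv")
    events = {
        str(r["subject_id"]): Events(
            float(r["t_hill_start_s"]), float(r["t_stop_start_s"]),
            float(r["t_stop_end_s"]))
        for _, r in ev_df.iterrows()
    }
    subjects = frame_to_subjects(pd.read_csv(data / "subjects.csv"), events)
    rr = {}
    for s in subjects:
        p = data / "rr" / f"{s.subject_id}.csv"
        if p.exists():
            rr[s.subject_id] = RRSeries.read_csv(p)
        else:
            logger.warning("missing RR file for subject %s", s.subject_id)
    power = {}
    pdir = data / "power"
    if pdir.is_dir():
        for p in sorted(pdir.glob("*.csv")):
            power[p.stem] = pd.read_csv(p)
    return subjects, rr, power


__all__ = [
    "RRSeries", "Events", "SubjectRecord", "ConfigError",
    "write_cohort", "read_cohort", "subjects_to_frame", "frame_to_subjects",
    "BP_BOUNDS",
]
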