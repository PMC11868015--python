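import numpy as np
import pytest

from exhrv.core import RRSeries, Events, SubjectRecord
from exhrv import synthetic as syn


@pytest.fixture
def subject():
    """A mid-cohort rider: resting HR 50, lab max 180."""
    return SubjectRecord(
        subject_id="S001", group="CAC-", age=50, sex="M", bmi=25.0,
        hr_rest=50, hr_max_lab=180, vo2max=42.0, smoker=False,
        sbp_start=135, dbp_start=80, sbp_thh=220, dbp_thh=95,
        lactate_start=(1.7, 1.7, 1.7), lactate_thh=(4.3, 4.3, 4.3),
        events=Events(120.0, 388.0, 517.0),
    )


@pytest.fixture
def flat_profile():
    """Short race skeleton with a 300 s post-stop window."""
    return syn.RaceProfile(t_hill_start=50, t_hill_top=100, stop_duration=60,
                           post_window=300)


def constant_series(rr_ms: float = 800.0, n: int = 100) -> RRSeries:
    return RRSeries.from_intervals(np.full(n, rr_ms))


@pytest.fixture
def const800():
    return constant_series(800.0, 100)
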