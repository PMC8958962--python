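import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_activity_frame(rows):
    """Build a schema frame from (date, athlete, distance, duration) tuples.

    Demographics are filled deterministically per athlete.
    """
    frame = pd.DataFrame(rows, columns=["datetime", "athlete", "distance", "duration"])
    frame["athlete"] = frame["athlete"].astype(np.int64)
    frame["gender"] = np.where(frame["athlete"] % 4 == 0, "F", "M")
    frame["age_group"] = (frame["athlete"] % 3).map(
        {0: "18-34", 1: "35-54", 2: "55+"}
    )
    frame["country"] = np.where(frame["athlete"] % 2 == 0, "US", "GB")
    frame["major"] = "Boston"
    return frame


@pytest.fixture
def activity_frame_factory():
    return make_activity_frame


@pytest.fixture
def small_tables():
    """Two tiny validated yearly tables sharing three athletes."""
    from runcompare import ActivityTable

    base = make_activity_frame(
        [
            ("2019-01-01", 1, 5.0, 30.0),
            ("2019-01-02", 1, 5.0, 30.0),
            ("2019-01-03", 1, 5.0, 30.0),
            ("2019-06-15", 2, 10.0, 55.0),
            ("2019-12-30", 3, 8.0, 48.0),
        ]
    )
    comp = make_activity_frame(
        [
            ("2020-01-05", 1, 6.0, 36.0),
            ("2020-07-01", 2, 12.0, 66.0),
        ]
    )
    return ActivityTable(base, year=2019), ActivityTable(comp, year=2020)
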