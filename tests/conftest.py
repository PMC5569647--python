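import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import demotime as dt

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def hexad_graph():
    return dt.demographic_graph()


@pytest.fixture(scope="session")
def toy_lifetable():
    """Three-age lifetable, q = (0.5, 0.5, 1), radix 1.

    Hand values: l = (1, .5, .25), d = (.5, .25, .25),
    L = (.75, .375, .125), e(0) = 1.25.
    """
    return dt.build_lifetable(qx=[0.5, 0.5, 1.0])


@pytest.fixture(scope="session")
def gompertz_lifetable_default():
    return dt.gompertz_lifetable(dt.GompertzParams())


# Worked single-dyad completions: (given measures, derived measure, value).
# One row per informative dyad of the hexad; the numeric cases are the
# classic one-liners (30 years left in 1971 -> death cohort 2001, etc.).
TABLE2_CASES = [
    ({"A": 30, "P": 1971}, "C", 1941.0),
    ({"A": 23, "C": 1941}, "P", 1964.0),
    ({"C": 1941, "P": 1971}, "A", 30.0),
    ({"T": 30, "P": 1971}, "D", 2001.0),
    ({"P": 1953, "D": 1973}, "T", 20.0),
    ({"T": 30, "D": 1974}, "P", 1944.0),
    ({"T": 3, "A": 80}, "L", 83.0),
    ({"L": 86, "T": 20}, "A", 66.0),
    ({"A": 34, "L": 96}, "T", 62.0),
    ({"C": 1940, "L": 64}, "D", 2004.0),
    ({"C": 1893, "D": 1964}, "L", 71.0),
    ({"D": 1996, "L": 96}, "C", 1900.0),
]

UNINFORMATIVE_CASES = [
    {"L": 100, "P": 2016},
    {"C": 1941, "T": 30},
    {"A": 30, "D": 2001},
]


@pytest.fixture(scope="session")
def six_lifelines():
    """Six lifelines in the style of the classic diagram cast; two share
    lifespan 75 and therefore overlap on the TAL plane."""
    return [
        dt.Lifeline("a", 1900.0, 1975.0),   # L = 75
        dt.Lifeline("b", 1905.0, 1980.0),   # L = 75 (overlaps a on TAL)
        dt.Lifeline("c", 1910.0, 1950.0),
        dt.Lifeline("d", 1920.0, 2008.0),
        dt.Lifeline("e", 1931.0, 1995.5),
        dt.Lifeline("f", 1944.0, None),     # censored
    ]
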