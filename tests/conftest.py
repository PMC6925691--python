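import numpy as np
import pytest

import vitalvar as vv

try:  # hypothesis is an optional test dependency
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "suite", derandomize=True, max_examples=60, suppress_health_check=[HealthCheck.too_slow]
    )
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


def naive_extrema(x):
    """Independent index-by-index scan for interior local extrema.

    Walks runs of equal values explicitly instead of collapsing the array,
    so it shares no code path with the vectorised implementation.
    """
    x = list(x)
    n = len(x)
    out = []
    prev_distinct = None
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        if prev_distinct is not None and j + 1 < n:
            if (x[i] - prev_distinct) * (x[i] - x[j + 1]) > 0:
                out.append(x[i])
        if j + 1 < n:
            prev_distinct = x[i]
        i = j + 1
    return out


def random_windows(rng, count, min_len=2, max_len=60, integer_fraction=0.5):
    """Random test windows, a share of them integer-valued to force plateaus."""
    windows = []
    for _ in range(count):
        n = int(rng.integers(min_len, max_len + 1))
        if rng.random() < integer_fraction:
            w = rng.integers(0, 6, size=n).astype(float)
        else:
            w = rng.normal(0.0, 10.0, size=n)
        windows.append(w)
    return windows


@pytest.fixture(scope="session")
def septic_params():
    return vv.default_params("septic")


@pytest.fixture(scope="session")
def control_params():
    return vv.default_params("control")


@pytest.fixture(scope="session")
def small_cohort(septic_params, control_params):
    spec = vv.CohortSpec(n_septic=60, n_control=60, seed=42)
    return vv.simulate_cohort(spec, septic_params, control_params)


@pytest.fixture(scope="session")
def feature_table(small_cohort):
    return vv.featurize_cohort(small_cohort.series, 8, 4)
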