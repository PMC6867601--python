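import numpy as np
import pytest
from hypothesis import settings

from odoseason import DemographyParams, make_reference_fixture

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return DemographyParams()


@pytest.fixture(scope="session")
def small_fixture(params):
    """Cheap two-year census (30 specimens/survey) for unit tests."""
    return make_reference_fixture(params, n_per_month=30, rng_seed=11)


@pytest.fixture(scope="session")
def small_lib(small_fixture):
    return small_fixture[1]


@pytest.fixture(scope="session")
def reference_lib(params):
    """Study-scale reference library (100 specimens/survey over 2 years)."""
    _, lib = make_reference_fixture(params, n_per_month=100, rng_seed=1)
    return lib


def brute_force_ks(xs, ys):
    """Independent D oracle: evaluate both ECDFs at every pooled point."""
    xs, ys = sorted(xs), sorted(ys)
    points = sorted(set(xs) | set(ys))
    d = 0.0
    for t in points:
        fa = sum(1 for v in xs if v <= t) / len(xs)
        fb = sum(1 for v in ys if v <= t) / len(ys)
        d = max(d, abs(fa - fb))
    return d
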