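import numpy as np
import pytest
from hypothesis import settings

from reacheval import TractYearPanel

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


def make_panel(counts, first_year=2010, centroids=None, svi=None, ids=None):
    """Tiny panel builder used across test modules."""
    counts = np.asarray(counts)
    S, T = counts.shape
    if ids is None:
        ids = [f"{10000 + i:05d}" for i in range(S)]
    if centroids is None:
        rng = np.random.default_rng(12345)
        centroids = np.column_stack([
            rng.uniform(41.5, 42.9, S), rng.uniform(-73.5, -69.9, S)
        ])
    return TractYearPanel(
        tract_ids=ids,
        years=list(range(first_year, first_year + T)),
        counts=counts,
        centroids=np.asarray(centroids, dtype=float),
        svi=svi,
    )


@pytest.fixture
def small_panel():
    """4 tracts x 3 years with known counts."""
    counts = np.array([
        [0, 1, 2],
        [3, 0, 1],
        [5, 5, 5],
        [0, 0, 0],
    ])
    return make_panel(counts)
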