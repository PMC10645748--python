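import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from chanclust.core import ClusterPopulation

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def exponential_population():
    """10⁴ clusters with exponential volumes, mean 0.07 μm³."""
    rng = np.random.default_rng(42)
    vols = rng.exponential(0.07, size=10_000)
    table = pd.DataFrame(
        {
            "id": np.arange(len(vols)),
            "volume_um3": vols,
            "x": np.zeros(len(vols)),
            "y": np.zeros(len(vols)),
            "z": np.zeros(len(vols)),
            "on_membrane": np.ones(len(vols), dtype=bool),
        }
    )
    return ClusterPopulation(table, {"mean_volume": 0.07})


def make_population(volumes, on_membrane=True):
    volumes = np.asarray(volumes, dtype=float)
    n = len(volumes)
    table = pd.DataFrame(
        {
            "id": np.arange(n),
            "volume_um3": volumes,
            "x": np.zeros(n),
            "y": np.zeros(n),
            "z": np.zeros(n),
            "on_membrane": np.full(n, on_membrane, dtype=bool),
        }
    )
    return ClusterPopulation(table)
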