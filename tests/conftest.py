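import numpy as np
import pandas as pd
import pytest

from spiscreen.io_cli.layout import PlateLayout
from spiscreen.synthetic_data import ScreenSimSpec, simulate_screen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_layout():
    strains = [f"S{i:03d}" for i in range(384)]
    return PlateLayout.from_strain_blocks(strains, "p1")


@pytest.fixture
def flat_colony_table(small_layout):
    rows = [
        {"plate_id": "p1", "row": r, "col": c,
         "strain": small_layout.strain_at(r, c), "size": 200.0}
        for r in range(32) for c in range(48)
    ]
    return pd.DataFrame(rows)


def make_screen(n_queries=200, spi=None, noise_sigma=0.2, seed=0, **kwargs):
    """Convenience builder used across test modules."""
    spec = ScreenSimSpec(n_queries=n_queries, spi_set=spi or {},
                         noise_sigma=noise_sigma, seed=seed, **kwargs)
    return simulate_screen(spec)
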