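import numpy as np
import pandas as pd
import pytest

from kinomescreen import ScreenConfig, generate_screen


@pytest.fixture(scope="session")
def tiny_config() -> ScreenConfig:
    """A 30-gene, 3-plate screen that keeps unit tests fast."""
    return ScreenConfig(
        n_genes=30,
        duplexes_per_gene=2,
        images_per_well=2,
        wells_per_plate=24,
        mean_cells_per_image=200.0,
        n_low_hits=3,
        n_high_hits=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_screen(tiny_config):
    return generate_screen(tiny_config)


@pytest.fixture
def joined_records(tiny_screen) -> pd.DataFrame:
    layout, measurements, _ = tiny_screen
    return measurements.merge(layout, on=["plate_id", "well_id"], how="inner")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
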