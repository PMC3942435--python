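import numpy as np
import pytest

from shapescreen.simulate import (ArtifactSpec, FeatureSpec, SimConfig,
                                  generate_screen)


def small_config(seed=0, **overrides):
    """A fast, down-scaled screen: 4x10 wells, 8 negatives, 4 positives,
    80-120 cells per well, one slide design in triplicate."""
    defaults = dict(
        n_rows=4, n_cols=10, n_negative=8, n_positive=4,
        positive_tiers=(("pos_strong", 2, 0.95), ("pos_medium", 1, 0.6),
                        ("pos_weak", 1, 0.3)),
        cells_per_well=(80, 120), rng_seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def toy_screen():
    return generate_screen(small_config(seed=42, hit_fraction=0.2))


@pytest.fixture(scope="session")
def toy_screen_clean():
    """Same design without positional artifacts."""
    return generate_screen(small_config(seed=43, hit_fraction=0.2,
                                        artifact=ArtifactSpec.none()))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
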