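"""Shared fixtures: small simulated chips reused across the suite."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cncenum.chipsim import (
    FIXED_ROUND,
    LIVE_ROUND,
    PopulationModel,
    build_layout,
    render_images,
    sample_population,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_layout():
    """2x2 blocks of 4x4 wells: a 64-well chip, ~100 cells, fast to render."""
    return build_layout({"block_grid": (2, 2), "well_grid": (4, 4)})


@pytest.fixture(scope="session")
def mid_layout():
    """3x3 blocks of 6x6 wells: ~500 cells, enough for recovery statistics."""
    return build_layout({"block_grid": (3, 3), "well_grid": (6, 6)})


@pytest.fixture(scope="session")
def default_model():
    return PopulationModel()


@pytest.fixture(scope="session")
def clean_model():
    """No debris, no noise: every truth cell is a detectable nucleated object."""
    return PopulationModel(debris_rate=0.0, read_noise_sd=0.0)


@pytest.fixture(scope="session")
def mid_scene(mid_layout, default_model):
    """One simulated chip at default (noisy) conditions with both rounds."""
    ss = np.random.SeedSequence(2024)
    s_pop, s_live, s_fixed = ss.spawn(3)
    truth = sample_population(mid_layout, default_model, s_pop)
    return {
        "truth": truth,
        "layout": mid_layout,
        "model": default_model,
        LIVE_ROUND: render_images(truth, mid_layout, default_model, LIVE_ROUND, s_live),
        FIXED_ROUND: render_images(truth, mid_layout, default_model, FIXED_ROUND, s_fixed),
    }


@pytest.fixture(scope="session")
def big_truth():
    """Sampling-only truth at 10,000 wells for distributional checks."""
    layout = build_layout({"block_grid": (10, 10), "well_grid": (10, 10)})
    model = PopulationModel()
    truth = sample_population(layout, model, seed=77)
    return {"layout": layout, "model": model, "truth": truth}
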