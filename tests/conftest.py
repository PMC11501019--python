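"""Shared fixtures: small synthetic designs reused across test modules."""

import numpy as np
import pytest

from obpc.simulate import (
    SimDesign,
    generate_breathing,
    generate_epochs,
    generate_ratings,
)


@pytest.fixture(scope="session")
def small_design():
    """Six participants, 30 trials: enough for pipeline mechanics."""
    return SimDesign(n_participants=6, n_trials=30, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    rng = small_design.rng()
    ratings = generate_ratings(small_design, rng)
    epochs = generate_epochs(small_design, ratings, rng)
    breaths = generate_breathing(small_design, ratings, rng)
    return {"design": small_design, "ratings": ratings,
            "epochs": epochs, "breaths": breaths}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
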