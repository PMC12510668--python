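"""Shared fixtures: RNGs, small networks, and reference scenario runs.

The reference runs are session-scoped because several test modules probe
different facets of the same simulated data (signature statistics, norm
decompositions, place-field statistics).
"""

from __future__ import annotations

import numpy as np
import pytest

from placeremap import reference_config, run_scenario
from placeremap.network import build_network

REFERENCE_SEED = 1


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_network(rng):
    """A modest mixed-code network for solver/encoder unit tests."""
    return build_network(Y=4, N=32, code="M", rng=rng)


@pytest.fixture(scope="session")
def multichart_run():
    return run_scenario(reference_config("multi_chart", seed=REFERENCE_SEED))


@pytest.fixture(scope="session")
def fulld_run():
    return run_scenario(reference_config("full_d", seed=REFERENCE_SEED))


@pytest.fixture(scope="session")
def gridrealign_run():
    return run_scenario(reference_config("grid_realign", seed=REFERENCE_SEED))


@pytest.fixture(scope="session")
def spacefeature_run():
    return run_scenario(reference_config("space_feature", seed=REFERENCE_SEED))


@pytest.fixture(scope="session")
def nullspace_run():
    return run_scenario(reference_config("null_space", seed=REFERENCE_SEED))


@pytest.fixture(scope="session")
def reward_runs():
    """Both reward-coding variants: conjunctive and pure-and-mixed."""
    return {
        "C": run_scenario(reference_config("reward", seed=REFERENCE_SEED)),
        "pM": run_scenario(
            reference_config("reward_pure_mixed", seed=REFERENCE_SEED)
        ),
    }
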