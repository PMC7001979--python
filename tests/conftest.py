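"""Shared fixtures: synthetic preset scenes reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import goldpcf as gp

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

#: seeds of the stock 20-replicate preset ensemble
PRESET_SEEDS = list(range(20))


@pytest.fixture(scope="session")
def preset_scenes():
    """Twenty seeded replicates of the default collagen-VI preset scene."""
    return [gp.simulate_scene(gp.SimulationConfig(), seed=s) for s in PRESET_SEEDS]


@pytest.fixture(scope="session")
def preset_clusterings(preset_scenes):
    """Single-linkage (25 nm) cluster assignments for each preset scene."""
    return [
        gp.cluster_labels(sc.labels[["x_nm", "y_nm"]].to_numpy(), 25.0)
        for sc in preset_scenes
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_window():
    return gp.Window2D(0.0, 1000.0, 0.0, 1000.0)
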