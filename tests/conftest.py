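"""Shared fixtures: small simulated time-lapses reused across test modules."""

import logging

import numpy as np
import pytest

from colonytrack import simdata

logging.getLogger("colonytrack").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def fast_division_sim():
    """Dense, fast-dividing colony: many divisions in few frames.

    The short interdivision times (not biologically realistic) pack many
    division events into a computationally small stack for annotation
    and event tests.
    """
    cfg = simdata.SimulationConfig(
        n_cells_initial=12,
        n_frames=80,
        image_shape=(256, 256),
        noise_sd=0.0,
        interdivision_mean_h=2.0,
        interdivision_sd_h=0.5,
        interdivision_min_h=1.0,
        interdivision_max_h=4.0,
        rng_seed=11,
    )
    return simdata.simulate_timelapse(cfg)


@pytest.fixture(scope="session")
def noisy_sim():
    """Moderate colony with rendering noise, default biology."""
    cfg = simdata.SimulationConfig(
        n_cells_initial=25,
        n_frames=30,
        image_shape=(320, 320),
        noise_sd=2.0,
        rng_seed=5,
    )
    return simdata.simulate_timelapse(cfg)


def random_instance_frame(rng, n_objects, shape=(64, 64), obj_size=3):
    """Instance mask with small square objects at random positions."""
    inst = np.zeros(shape, dtype=np.int32)
    for lab in range(1, n_objects + 1):
        r = int(rng.integers(obj_size, shape[0] - obj_size))
        c = int(rng.integers(obj_size, shape[1] - obj_size))
        inst[r : r + obj_size, c : c + obj_size] = lab
    return inst
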