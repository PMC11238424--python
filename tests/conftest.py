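"""Shared fixtures: small synthetic movies with exact ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from bactglass import rodsim


@pytest.fixture(scope="session")
def dilute_scene():
    """A few well-separated rods rendered at the default optics.

    Returns (ensemble, stack, ground_truth, optics); rods are fully inside
    the frame and mutually separated by several tensor scales.
    """
    optics = rodsim.OpticsParams(shape=(128, 128), noise_seed=5)
    params = rodsim.SimParams(
        n_rods=8, well_radius=9.5, speed=2.0, duration=0.1, seed=5
    )
    ensembles = rodsim.simulate_rods(params)
    stack = rodsim.render_frames(ensembles, optics)
    gt = rodsim.ground_truth(ensembles, optics)
    return ensembles, stack, gt, optics


@pytest.fixture(scope="session")
def medium_movie():
    """A moderate-density interacting movie with ground truth (31 frames)."""
    optics = rodsim.OpticsParams(shape=(64, 64), noise_seed=11)
    params = rodsim.SimParams(
        n_rods=45, well_radius=12.0, speed=3.0, duration=0.8, seed=11
    )
    ensembles = rodsim.simulate_rods(params)
    stack = rodsim.render_frames(ensembles, optics)
    gt = rodsim.ground_truth(ensembles, optics, roi="frame")
    return ensembles, stack, gt, optics


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
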