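"""Shared fixtures: tiny shapes, models, and a small trained coder.

The trained coder is session-scoped because NumPy-only training is the
expensive step; unit tests share one small configuration while the
acceptance tests train their own larger one.
"""

import numpy as np
import pytest

from saxshape import (AtomicModel, ShapeSpec, VoxelGrid, build_coder,
                      generate_shape, make_dataset, train)
from saxshape.voxel_shapes import _COORDS


@pytest.fixture(scope="session")
def ball_grid() -> VoxelGrid:
    """Rasterized solid ball of radius 10 voxels, centered."""
    r = np.sqrt((_COORDS ** 2).sum(-1))
    return VoxelGrid((r <= 10.0).astype(np.uint8), radius=50.0)


@pytest.fixture(scope="session")
def dumbbell_grid() -> VoxelGrid:
    return generate_shape(ShapeSpec("dumbbell", {"ball_radius": 0.45,
                                                 "separation": 0.8}, seed=3))


@pytest.fixture(scope="session")
def random_ball_model() -> AtomicModel:
    """Dense point sample of a solid ball of radius 50 A."""
    rng = np.random.default_rng(7)
    pts = rng.normal(size=(8000, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    pts *= rng.uniform(0, 1, len(pts))[:, None] ** (1 / 3) * 50.0
    return AtomicModel(pts, ["bead"] * len(pts))


@pytest.fixture(scope="session")
def small_dataset():
    """Small mixed-family corpus for quick training runs."""
    return make_dataset(120, seed=11)


@pytest.fixture(scope="session")
def tiny_coder(small_dataset):
    """A small trained coder + prior shared across unit tests."""
    coder = build_coder(latent_dim=32, channels=(6, 12, 24), seed=5)
    coder, prior = train(coder, small_dataset, epochs=6, batch=8, seed=5)
    return coder, prior
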