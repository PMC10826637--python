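"""Shared fixtures and independent oracles.

The quadrature oracle integrates band-limited spherical functions exactly:
Gauss-Legendre nodes in cos(theta) crossed with an equispaced azimuthal
grid, which is exact for products of order-8 spherical harmonics (degree
16 integrands).  The brute-force bundle-distance oracle computes all-pairs
voxel-center distances with no distance transform.
"""

import dataclasses

import numpy as np
import pytest

from tractod.phantom import PhantomParams


class SphereQuadrature:
    """Exact quadrature for spherical polynomials up to degree ~32."""

    def __init__(self, n_theta: int = 33, n_phi: int = 64):
        x, w = np.polynomial.legendre.leggauss(n_theta)
        theta = np.arccos(x)
        phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
        T, P = np.meshgrid(theta, phi, indexing="ij")
        self.dirs = np.stack(
            [np.sin(T) * np.cos(P), np.sin(T) * np.sin(P), np.cos(T)], axis=-1
        ).reshape(-1, 3)
        self.weights = np.repeat(w[:, None], n_phi, axis=1).ravel() * (
            2.0 * np.pi / n_phi
        )

    def integrate(self, values: np.ndarray) -> float:
        return float(np.dot(self.weights, values))


@pytest.fixture(scope="session")
def quad() -> SphereQuadrature:
    return SphereQuadrature()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


def brute_force_bd(a: np.ndarray, b: np.ndarray, spacing=1.0):
    """O(n^2) bundle distance and signed bundle distance (mm)."""
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    pa = np.argwhere(a) * spacing
    pb = np.argwhere(b) * spacing
    assert len(pa) and len(pb), "oracle requires non-empty masks"

    def min_d(points, targets):
        if len(points) == 0:
            return np.zeros(0)
        d = np.linalg.norm(points[:, None, :] - targets[None, :, :], axis=2)
        return d.min(axis=1)

    only_a = np.argwhere(a & ~b) * spacing
    only_b = np.argwhere(b & ~a) * spacing
    da = min_d(only_a, pb)
    db = min_d(only_b, pa)
    n = da.size + db.size
    if n == 0:
        return 0.0, 0.0
    return float((da.sum() + db.sum()) / n), float((db.sum() - da.sum()) / n)


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    """Scaled-down scene for fast unit tests (not the acceptance conditions)."""
    return dataclasses.replace(
        PhantomParams(), n_subjects=3, n_streamlines=60, grid_shape=(40, 40, 40)
    )
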