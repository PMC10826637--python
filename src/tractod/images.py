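"""In-memory containers: SH coefficient images, streamline bundles, masks.

All world coordinates are RAS millimetres; voxel indices are 0-based and the
voxel-to-world mapping is the NIfTI sform convention (world = affine @ index,
homogeneous).  An :class:`SHImage` plays three roles in the pipeline: subject
FOD image, per-subject TOD image, and population tract atlas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import shcore

__all__ = ["SHImage", "StreamlineBundle", "voxel_sizes"]


def voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Voxel edge lengths (mm) along each axis: column norms of the linear part."""
    return np.linalg.norm(np.asarray(affine, dtype=float)[:3, :3], axis=0)


@dataclass
class SHImage:
    """3D grid of real even-order SH coefficient vectors plus an affine.

    Attributes
    ----------
    data : (nx, ny, nz, J) float array, coefficient index last.
    affine : 4x4 voxel-to-world matrix (RAS mm, sform convention).
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"SHImage data must be 4D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine linear part is singular")
        shcore.lmax_for(self.data.shape[3])  # validates coefficient count

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def lmax(self) -> int:
        return shcore.lmax_for(self.data.shape[3])

    @property
    def n_coeffs(self) -> int:
        return self.data.shape[3]

    def same_grid(self, other: "SHImage", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points to (fractional) voxel indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def copy(self) -> "SHImage":
        return SHImage(self.data.copy(), self.affine.copy())

    @classmethod
    def zeros(
        cls, shape: tuple[int, int, int], affine: np.ndarray, lmax: int = 8
    ) -> "SHImage":
        return cls(np.zeros((*shape, shcore.n_coeffs(lmax))), affine)


@dataclass
class StreamlineBundle:
    """Ordered 3D polylines in world (mm) coordinates."""

    streamlines: list = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        for i, s in enumerate(self.streamlines):
            s = np.asarray(s, dtype=float)
            if s.ndim != 2 or s.shape[1] != 3:
                raise ValueError(f"streamline {i} is not an (N, 3) point array")
            if s.shape[0] < 2:
                raise ValueError(f"streamline {i} has fewer than 2 points")
            if not np.all(np.isfinite(s)):
                raise ValueError(f"streamline {i} contains non-finite coordinates")
            cleaned.append(s)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def total_length(self) -> float:
        """Total arc length (mm) over all streamlines."""
        return float(
            sum(
                np.linalg.norm(np.diff(s, axis=0), axis=1).sum()
                for s in self.streamlines
            )
        )
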