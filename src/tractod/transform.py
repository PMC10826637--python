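"""Affine transport of SH coefficient images between world frames.

The atlas lives in template space; a subject-specific 4x4 world-to-world
affine (template mm -> subject mm, e.g. from a linear registration of the
structural images) carries it onto the subject's voxel grid.  Transport is
a pull-resample: each target voxel is mapped back through the inverse
affine into the source image and the 45 coefficient channels are
interpolated independently (coefficients are linear functionals of the
underlying function, so channel-wise interpolation is well defined).
Directional content is then reoriented by the rotation factor of the
affine's polar decomposition — one global rotation, since a single linear
part has a single rotational component.

FLIRT-style voxel-based matrices are not accepted; convert them to
world-to-world RAS-mm form first.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import polar
from scipy.ndimage import map_coordinates

from . import shcore
from .images import SHImage

__all__ = [
    "read_affine",
    "write_affine",
    "rotation_part",
    "transform_sh_image",
]


def read_affine(path) -> np.ndarray:
    """Read a 4x4 world-to-world affine from a whitespace-delimited text file."""
    A = np.loadtxt(path, dtype=float)
    if A.shape != (4, 4):
        raise ValueError(f"{path}: expected a 4x4 matrix, got shape {A.shape}")
    _validate_affine(A)
    return A


def write_affine(A: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(A, dtype=float), fmt="%.10g")


def _validate_affine(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got shape {A.shape}")
    if abs(np.linalg.det(A[:3, :3])) < 1e-12:
        raise ValueError("affine linear part is singular")
    return A


def rotation_part(A: np.ndarray) -> np.ndarray:
    """Rotation factor R of the polar decomposition L = R S of the linear part.

    S is symmetric positive-definite (scales/shears); R is orthogonal.  A
    reflection (det R = -1) is folded through -I, which acts as the
    identity on antipodally symmetric functions, so the returned matrix is
    always a proper rotation.
    """
    A = _validate_affine(A)
    R, S = polar(A[:3, :3], side="right")
    if np.linalg.det(R) < 0:
        R = -R
    return R


def transform_sh_image(
    img: SHImage,
    A: np.ndarray,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray,
    order: int = 1,
    reorient: bool = True,
) -> SHImage:
    """Resample ``img`` onto a target grid through the world affine ``A``.

    Parameters
    ----------
    img : source image whose world frame is the *domain* of ``A``.
    A : 4x4 affine mapping source world mm to target world mm.
    order : interpolation order (1 = trilinear; 0 = nearest, for masks).
    reorient : rotate each voxel's coefficient vector by the rotation part
        of ``A`` (disable only to inspect the effect of reorientation).
    """
    A = _validate_affine(A)
    target_affine = np.asarray(target_affine, dtype=float)
    # target voxel -> target world -> source world -> source voxel
    M = np.linalg.inv(img.affine) @ np.linalg.inv(A) @ target_affine
    idx = np.indices(target_shape, dtype=float).reshape(3, -1)
    src = M[:3, :3] @ idx + M[:3, 3:4]

    n = img.n_coeffs
    out = np.empty((n, src.shape[1]))
    for j in range(n):
        out[j] = map_coordinates(
            img.data[..., j], src, order=order, mode="constant", cval=0.0
        )
    data = out.T.reshape(*target_shape, n)

    if reorient:
        R = rotation_part(A)
        if not np.allclose(R, np.eye(3), atol=1e-12):
            M_sh = shcore.rotation_matrix_sh(R, img.lmax)
            data = data @ M_sh.T
    return SHImage(data, target_affine.copy())
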