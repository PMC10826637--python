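"""Track orientation distribution (TOD) mapping and density normalization.

A streamline bundle is converted to a voxel-wise spherical function whose
lobes follow the local streamline directions: each short segment deposits a
length-weighted, apodized orientation lobe into the voxel containing its
midpoint.  The raw TOD still carries streamline density; dividing each
visited voxel by its spherical integral (sqrt(4*pi) * t_0) leaves a
unit-integral orientation distribution that no longer depends on how many
streamlines traversed the voxel.
"""

from __future__ import annotations

import logging

import numpy as np

from . import shcore
from .images import SHImage, StreamlineBundle, voxel_sizes

__all__ = ["resample_streamline", "compute_tod", "normalize_tod", "VISITED_EPS"]

log = logging.getLogger(__name__)

#: Voxels whose first TOD coefficient is at or below this are "unvisited":
#: 1e-8 of the first coefficient of a unit-mass lobe, well above float noise.
VISITED_EPS = 1e-8 / (2.0 * np.sqrt(np.pi))


def resample_streamline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length spacing <= ``step`` mm.

    Endpoints are preserved; the spacing actually used divides the total
    arc length into equal pieces no longer than ``step``.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or points.shape[0] < 2:
        raise ValueError("streamline must be an (N>=2, 3) point array")
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    total = seg.sum()
    if total == 0:
        return points[:2].copy()
    n = max(int(np.ceil(total / step)), 1)
    targets = np.linspace(0.0, total, n + 1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    out = np.empty((n + 1, 3))
    for k in range(3):
        out[:, k] = np.interp(targets, cum, points[:, k])
    return out


def compute_tod(
    bundle: StreamlineBundle,
    grid: SHImage,
    lmax: int = 8,
    taper: np.ndarray | None = None,
    step: float | None = None,
) -> SHImage:
    """Map a streamline bundle to a TOD image on ``grid``'s voxel lattice.

    Each resampled segment contributes (segment length) x (apodized lobe
    along the segment direction) to the voxel containing its midpoint, so a
    voxel's spherical integral equals the total streamline length it
    contains, and the sum over voxels recovers the bundle arc length up to
    resampling discretization.
    """
    if taper is None:
        taper = shcore.default_taper(lmax)
    if step is None:
        step = 0.25 * float(voxel_sizes(grid.affine).min())
    out = SHImage.zeros(grid.shape, grid.affine, lmax)
    if len(bundle) == 0:
        log.warning("compute_tod called with an empty bundle; returning zeros")
        return out

    mids, dirs, lens = [], [], []
    for sl in bundle:
        pts = resample_streamline(sl, step)
        d = np.diff(pts, axis=0)
        ln = np.linalg.norm(d, axis=1)
        keep = ln > 0
        if not np.any(keep):
            continue
        mids.append(0.5 * (pts[:-1] + pts[1:])[keep])
        dirs.append(d[keep] / ln[keep, None])
        lens.append(ln[keep])
    if not mids:
        log.warning("bundle contains only zero-length segments; returning zeros")
        return out
    mids = np.concatenate(mids)
    dirs = np.concatenate(dirs)
    lens = np.concatenate(lens)

    vox = np.rint(out.world_to_voxel(mids)).astype(np.int64)
    shape = np.array(out.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    if not np.all(inside):
        vox, dirs, lens = vox[inside], dirs[inside], lens[inside]
        if vox.shape[0] == 0:
            return out

    lobes = shcore.sh_basis(dirs, lmax) * shcore._per_coeff_taper(taper, lmax)
    lobes *= lens[:, None]
    flat = np.ravel_multi_index(vox.T, out.shape)
    acc = np.zeros((int(np.prod(out.shape)), lobes.shape[1]))
    np.add.at(acc, flat, lobes)
    out.data = acc.reshape(*out.shape, lobes.shape[1])
    return out


def normalize_tod(tod: SHImage, eps: float = VISITED_EPS) -> SHImage:
    """Normalize every visited voxel to unit spherical integral.

    Visited voxels (first coefficient above ``eps``) are divided by
    sqrt(4*pi) * t_0, forcing t_0 = 1/sqrt(4*pi) and integral 1.  Voxels at
    or below ``eps`` — including any with a (numerically) negative mass —
    are set exactly to zero; negative-mass voxels are counted in a warning
    since they indicate apodization ringing rather than real visitation.
    """
    c0 = tod.data[..., 0]
    visited = c0 > eps
    n_negative = int(np.sum(c0 < -eps))
    if n_negative:
        log.warning(
            "%d voxel(s) had negative TOD mass; treated as unvisited", n_negative
        )
    out = np.zeros_like(tod.data)
    denom = shcore.SQRT_4PI * c0[visited]
    out[visited] = tod.data[visited] / denom[:, None]
    return SHImage(out, tod.affine.copy())
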