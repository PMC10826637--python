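"""Voxel-wise inner product of atlas and FOD: the tract pseudo-probability map.

For each voxel, the integral over the sphere of (registered atlas
distribution) x (subject FOD) reduces, by orthonormality of the SH basis,
to the dot product of the two coefficient vectors.  The result is a
dimensionless scalar per voxel — large where the FOD is strong AND the
atlas predicts the tract AND their peak orientations agree, small when any
of the three fails.  Typical values for conventionally scaled FODs run
from 0 to about 0.5; thresholding (default 0.05, strict '>') yields a
binary segmentation.
"""

from __future__ import annotations

import numpy as np

from . import shcore
from .images import SHImage

__all__ = ["compute_tract_map", "binarize", "DEFAULT_THRESHOLD"]

#: Default binarization threshold for tract pseudo-probability maps.
DEFAULT_THRESHOLD = 0.05


def compute_tract_map(
    fod: SHImage, atlas: SHImage, clamp_negative: bool = True
) -> np.ndarray:
    """Voxel-wise SH inner product of a subject FOD image and a registered atlas.

    Both images must be on the same grid (the atlas already transported to
    subject space).  Differing ``lmax`` is reconciled by truncating to the
    common band.  Small negative values can arise from band-limit ringing;
    they are clamped to 0 by default (pass ``clamp_negative=False`` for the
    raw values).
    """
    if fod.shape != atlas.shape or not np.allclose(fod.affine, atlas.affine, atol=1e-4):
        raise ValueError(
            "FOD and atlas are not on the same grid:\n"
            f"  FOD:   shape {fod.shape}, affine\n{fod.affine}\n"
            f"  atlas: shape {atlas.shape}, affine\n{atlas.affine}"
        )
    values = shcore.inner_product(fod.data, atlas.data)
    if clamp_negative:
        values = np.maximum(values, 0.0)
    return values


def binarize(tract_map: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Binary segmentation: voxels strictly above ``threshold``."""
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    return np.asarray(tract_map) > threshold
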