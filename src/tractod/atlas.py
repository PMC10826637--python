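"""Population tract-orientation atlas construction and filtering statistics.

The atlas is the voxel-wise arithmetic mean of per-subject unit-integral
TOD images on a common template grid.  Because every visited voxel of a
normalized TOD integrates to exactly 1, the atlas voxel's spherical
integral equals the fraction of training subjects whose tract visited that
voxel — the "spatial prior" — while the remaining coefficients carry the
pooled orientation distribution.  Voxels visited in only one of n subjects
receive weight 1/n, damping outliers.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from . import shcore
from .images import SHImage

__all__ = ["TractAtlas", "average_tods", "spatial_prior", "filtering_report"]

_NORM_TOL = 1e-6
_C0_UNIT = 1.0 / shcore.SQRT_4PI


@dataclass
class TractAtlas:
    """Mean normalized-TOD image plus provenance."""

    image: SHImage
    n_subjects: int
    label: str = ""


def _check_normalized(img: SHImage, idx: int) -> None:
    c0 = img.data[..., 0]
    ok = (np.abs(c0) <= _NORM_TOL) | (np.abs(c0 - _C0_UNIT) <= _NORM_TOL)
    if not np.all(ok):
        raise ValueError(
            f"input TOD #{idx} is not normalized: voxel c0 values must be 0 or "
            f"1/sqrt(4*pi) ~= {_C0_UNIT:.6f} (found e.g. "
            f"{c0[~ok].flat[0]:.6g}); run normalize_tod first"
        )


def average_tods(
    tods: list[SHImage], n_subjects: int | None = None, label: str = ""
) -> TractAtlas:
    """Average per-subject normalized TOD images into a tract atlas.

    All inputs must share grid shape, affine and lmax, and be normalized
    (voxel-wise unit spherical integral or exactly zero).
    """
    if not tods:
        raise ValueError("need at least one TOD image")
    ref = tods[0]
    for i, t in enumerate(tods[1:], start=1):
        if t.shape != ref.shape or t.n_coeffs != ref.n_coeffs:
            raise ValueError(
                f"grid/lmax mismatch: input #0 has shape {ref.shape} with "
                f"{ref.n_coeffs} coefficients, input #{i} has {t.shape} with "
                f"{t.n_coeffs}"
            )
        if not np.allclose(t.affine, ref.affine, atol=1e-6):
            raise ValueError(
                f"affine mismatch between input #0 and input #{i}:\n"
                f"{ref.affine}\nvs\n{t.affine}"
            )
    for i, t in enumerate(tods):
        _check_normalized(t, i)
    mean = np.mean([t.data for t in tods], axis=0)
    return TractAtlas(
        image=SHImage(mean, ref.affine.copy()),
        n_subjects=n_subjects if n_subjects is not None else len(tods),
        label=label,
    )


def spatial_prior(atlas: TractAtlas | SHImage) -> np.ndarray:
    """Subject-visitation fraction per voxel: sqrt(4*pi) times the first
    atlas coefficient.  Values lie in [0, 1]."""
    img = atlas.image if isinstance(atlas, TractAtlas) else atlas
    return shcore.SQRT_4PI * img.data[..., 0]


def _round2(x: float) -> float:
    """Half-up rounding to 2 decimals (matching conventional table display)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def filtering_report(counts: dict[str, dict[str, tuple[int, int]]]) -> pd.DataFrame:
    """Streamline-filtering statistics table.

    Parameters
    ----------
    counts : mapping ``{tract: {hemisphere: (original, retained)}}``.

    Returns
    -------
    DataFrame with columns original, filtered, difference, reduction_pct,
    one row per (tract, hemisphere) plus a "Total" row per tract summing
    the hemispheres.  ``reduction_pct = 100 * difference / original``,
    rounded half-up to 2 decimals.
    """
    rows = []
    for tract, hemis in counts.items():
        tot_orig = tot_kept = 0
        for hemi, (orig, kept) in hemis.items():
            if orig < 0 or kept < 0:
                raise ValueError(f"{tract}/{hemi}: counts must be non-negative")
            if kept > orig:
                raise ValueError(
                    f"{tract}/{hemi}: retained count {kept} exceeds original {orig}"
                )
            diff = orig - kept
            rows.append(
                {
                    "tract": tract,
                    "hemisphere": hemi,
                    "original": orig,
                    "filtered": kept,
                    "difference": diff,
                    "reduction_pct": _round2(100.0 * diff / orig) if orig else 0.0,
                }
            )
            tot_orig += orig
            tot_kept += kept
        diff = tot_orig - tot_kept
        rows.append(
            {
                "tract": tract,
                "hemisphere": "Total",
                "original": tot_orig,
                "filtered": tot_kept,
                "difference": diff,
                "reduction_pct": _round2(100.0 * diff / tot_orig) if tot_orig else 0.0,
            }
        )
    return pd.DataFrame(rows)
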