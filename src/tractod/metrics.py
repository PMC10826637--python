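"""Volumetric segmentation comparison metrics.

Four complementary measures of agreement between two segmentations:

* **DSC** (Dice-Sorensen coefficient): ``2|A∩B| / (|A|+|B|)`` for binary
  masks — overlap only.
* **Density correlation**: Pearson r between the voxel values of two
  continuous maps, insensitive to their absolute scales.  Computed over
  the union of the two supports (voxels nonzero in at least one map);
  correlating over the whole volume would be dominated by the shared
  all-zero background.
* **Bundle distance** (BD, mm): the mean, over every voxel in the
  symmetric difference, of its Euclidean distance to the *other* mask —
  how far apart the disagreeing parts are.
* **Signed bundle distance** (BDs, mm): as BD but distances from voxels
  of A\\B enter negatively, so BDs(A,B) = -BDs(B,A); its sign indicates
  whether A's boundary lies inside (negative) or outside B.

Distances are voxel-center to voxel-center in mm using the grid's voxel
sizes (anisotropic grids supported), via a Euclidean distance transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt

from .mapping import DEFAULT_THRESHOLD

__all__ = [
    "dsc",
    "density_correlation",
    "bundle_distance",
    "signed_bundle_distance",
    "compare_all",
    "MetricReport",
    "KIND_THRESHOLDS",
]

#: Default binarization thresholds by map kind (strict '>').
KIND_THRESHOLDS = {
    "tractmap": DEFAULT_THRESHOLD,  # dimensionless pseudo-probability
    "density": 10.0,  # streamline density (track counts)
    "reference": 0.0,  # reference tractography density
    "atlas": 0.1,  # atlas spatial prior, dimensionless
    "probability": 0.5,  # probabilistic segmentation
    "mask": 0.0,  # already binary
}


def _as_mask(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m)
    if m.ndim != 3:
        raise ValueError(f"mask must be 3D, got shape {m.shape}")
    return m.astype(bool)


def _check_same_grid(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: shapes {a.shape} vs {b.shape}")


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice-Sorensen coefficient of two binary masks on the same grid."""
    a, b = _as_mask(a), _as_mask(b)
    _check_same_grid(a, b)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("DSC is undefined for two empty masks")
    return 2.0 * int((a & b).sum()) / (na + nb)


def density_correlation(m1: np.ndarray, m2: np.ndarray) -> float:
    """Pearson correlation of voxel values over the union of supports."""
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    _check_same_grid(m1, m2)
    if np.any(m1 < 0) or np.any(m2 < 0) or not (
        np.all(np.isfinite(m1)) and np.all(np.isfinite(m2))
    ):
        raise ValueError("density maps must be finite and non-negative")
    support = (m1 != 0) | (m2 != 0)
    x, y = m1[support], m2[support]
    if x.size < 2:
        raise ValueError("density correlation needs at least 2 support voxels")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(
            "density correlation is undefined: a map is constant on the support"
        )
    return float(np.corrcoef(x, y)[0, 1])


def _surface_distances(
    a: np.ndarray, b: np.ndarray, spacing
) -> tuple[np.ndarray, np.ndarray]:
    """Distances (mm) of A\\B voxels to B, and of B\\A voxels to A."""
    a, b = _as_mask(a), _as_mask(b)
    _check_same_grid(a, b)
    if not a.any() or not b.any():
        raise ValueError(
            "bundle distance is undefined when a mask is empty "
            f"(|A|={int(a.sum())}, |B|={int(b.sum())})"
        )
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    dist_to_b = distance_transform_edt(~b, sampling=spacing)
    dist_to_a = distance_transform_edt(~a, sampling=spacing)
    return dist_to_b[a & ~b], dist_to_a[b & ~a]


def bundle_distance(a: np.ndarray, b: np.ndarray, spacing=1.0) -> float:
    """Mean distance (mm) from symmetric-difference voxels to the other mask.

    Returns 0 when the masks are identical (vanishing disagreement limit).
    """
    da, db = _surface_distances(a, b, spacing)
    n = da.size + db.size
    if n == 0:
        return 0.0
    return float((da.sum() + db.sum()) / n)


def signed_bundle_distance(a: np.ndarray, b: np.ndarray, spacing=1.0) -> float:
    """Antisymmetric bundle distance: A-side distances negated.

    Positive when B's excess dominates (A sits inside B); zero for
    identical masks.
    """
    da, db = _surface_distances(a, b, spacing)
    n = da.size + db.size
    if n == 0:
        return 0.0
    return float((db.sum() - da.sum()) / n)


@dataclass
class MetricReport:
    """All four metrics plus the voxel counts and thresholds that produced them."""

    dsc: float
    density_correlation: float | None
    bd: float
    bds: float
    threshold_a: float
    threshold_b: float
    n_a: int
    n_b: int
    n_intersection: int
    n_symmetric_difference: int
    notes: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "dsc": self.dsc,
            "density_correlation": self.density_correlation,
            "bd_mm": self.bd,
            "bds_mm": self.bds,
            "threshold_a": self.threshold_a,
            "threshold_b": self.threshold_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_intersection": self.n_intersection,
            "n_symmetric_difference": self.n_symmetric_difference,
        }


def compare_all(
    map_a: np.ndarray,
    map_b: np.ndarray,
    kind_a: str = "mask",
    kind_b: str = "mask",
    threshold_a: float | None = None,
    threshold_b: float | None = None,
    spacing=1.0,
) -> MetricReport:
    """Threshold two maps by their kind-specific defaults and compute all metrics.

    ``kind_*`` selects the default threshold (see :data:`KIND_THRESHOLDS`);
    an explicit ``threshold_*`` overrides it.  Binarization uses strict '>'.
    Density correlation is computed on the continuous values (``None`` if a
    map is binary-constant on the support).
    """
    for kind in (kind_a, kind_b):
        if kind not in KIND_THRESHOLDS:
            raise ValueError(
                f"unknown map kind {kind!r}; choose from {sorted(KIND_THRESHOLDS)}"
            )
    ta = KIND_THRESHOLDS[kind_a] if threshold_a is None else float(threshold_a)
    tb = KIND_THRESHOLDS[kind_b] if threshold_b is None else float(threshold_b)
    map_a = np.asarray(map_a, dtype=float)
    map_b = np.asarray(map_b, dtype=float)
    a = map_a > ta
    b = map_b > tb
    if not a.any():
        raise ValueError(
            f"first map is empty after thresholding at {ta} (kind {kind_a!r}, "
            f"max value {map_a.max():.4g})"
        )
    if not b.any():
        raise ValueError(
            f"second map is empty after thresholding at {tb} (kind {kind_b!r}, "
            f"max value {map_b.max():.4g})"
        )
    notes = ["density correlation support: union of nonzero voxels"]
    try:
        rho = density_correlation(map_a, map_b)
    except ValueError as e:
        rho = None
        notes.append(f"density correlation unavailable: {e}")
    return MetricReport(
        dsc=dsc(a, b),
        density_correlation=rho,
        bd=bundle_distance(a, b, spacing),
        bds=signed_bundle_distance(a, b, spacing),
        threshold_a=ta,
        threshold_b=tb,
        n_a=int(a.sum()),
        n_b=int(b.sum()),
        n_intersection=int((a & b).sum()),
        n_symmetric_difference=int((a ^ b).sum()),
        notes=notes,
    )
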