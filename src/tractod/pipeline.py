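"""Pipeline configuration and stage orchestration.

Two composite operations cover the full workflow:

* :func:`run_atlas_build` — per-subject bundle -> TOD -> normalization ->
  population average.
* :func:`run_map` — atlas transport (affine + SH reorientation) ->
  voxel-wise inner product with the subject FOD -> binarization.

Both log per-stage wall time and are deterministic for a given config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass

import numpy as np

from . import __version__
from .atlas import TractAtlas, average_tods
from .images import SHImage
from .mapping import DEFAULT_THRESHOLD, binarize, compute_tract_map
from .tod import compute_tod, normalize_tod
from .transform import transform_sh_image

__all__ = ["PipelineConfig", "run_atlas_build", "run_map"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved parameters of a pipeline run; serializes round-trip to JSON."""

    lmax: int = 8
    taper_sigma: float = 0.17
    resample_step: float | None = None  # None: 0.25 x smallest voxel edge
    threshold: float = DEFAULT_THRESHOLD
    interpolation: str = "linear"  # or "nearest"
    reorient: bool = True
    seed: int = 0

    def taper(self) -> np.ndarray:
        from .shcore import default_taper

        return default_taper(self.lmax, self.taper_sigma)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    def provenance(self) -> str:
        return f"tractod {__version__} cfg:{self.digest()}"


def _timed(stage: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except Exception as e:
        raise RuntimeError(f"stage '{stage}' failed: {e}") from e
    log.info("stage %-18s %.3f s", stage, time.perf_counter() - t0)
    return result


def run_atlas_build(
    bundles: list,
    grid: SHImage,
    config: PipelineConfig = PipelineConfig(),
    label: str = "",
) -> TractAtlas:
    """Build a population tract atlas from per-subject streamline bundles."""
    taper = config.taper()
    normalized = []
    for i, bundle in enumerate(bundles):
        tod = _timed(
            f"tod[{i}]",
            compute_tod,
            bundle,
            grid,
            lmax=config.lmax,
            taper=taper,
            step=config.resample_step,
        )
        normalized.append(_timed(f"normalize[{i}]", normalize_tod, tod))
    return _timed("average", average_tods, normalized, label=label)


def run_map(
    fod: SHImage,
    atlas: SHImage,
    transform: np.ndarray | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Transport the atlas to the subject grid, map, and binarize.

    Returns (tract map, binary mask), both on the FOD grid.  With
    ``transform=None`` an identity transform is assumed (logged).
    """
    if transform is None:
        log.warning("no transform given; assuming identity (atlas already aligned)")
        transform = np.eye(4)
    registered = _timed(
        "transport",
        transform_sh_image,
        atlas,
        transform,
        fod.shape,
        fod.affine,
        order=0 if config.interpolation == "nearest" else 1,
        reorient=config.reorient,
    )
    tract_map = _timed("inner-product", compute_tract_map, fod, registered)
    mask = _timed("binarize", binarize, tract_map, config.threshold)
    return tract_map, mask
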