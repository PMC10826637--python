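"""File I/O: SH coefficient images (4D NIfTI-1) and streamlines (MRtrix .tck).

SH images are stored with the coefficient index on the 4th axis; the
number of 4th-axis volumes must be a valid even-order coefficient count
(1, 6, 15, 28, 45, ...), from which ``lmax`` is inferred.  The sform
affine is authoritative (RAS mm).  Streamline files use the MRtrix .tck
container (binary header starting "mrtrix tracks", float32 triplets with
NaN separators), handled by ``nibabel.streamlines``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel.streamlines import Tractogram
from nibabel.streamlines.tck import TckFile

from . import shcore
from .images import SHImage, StreamlineBundle

__all__ = [
    "read_sh_image",
    "write_sh_image",
    "read_scalar_image",
    "write_scalar_image",
    "read_tck",
    "write_tck",
    "write_sidecar",
]

log = logging.getLogger(__name__)


def _sform(img: nib.Nifti1Image) -> np.ndarray:
    sform, code = img.get_sform(coded=True)
    if code > 0:
        return np.asarray(sform, dtype=float)
    return np.asarray(img.affine, dtype=float)


def read_sh_image(path) -> SHImage:
    """Load a 4D NIfTI of SH coefficients; lmax is inferred from the 4th axis."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D SH coefficient image, got {data.ndim}D")
    try:
        shcore.lmax_for(data.shape[3])
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from None
    return SHImage(data, _sform(img))


def write_sh_image(img: SHImage, path, description: str = "") -> None:
    """Write an SH image as float32 4D NIfTI-1 with the sform set."""
    nii = nib.Nifti1Image(img.data.astype(np.float32), img.affine)
    nii.set_sform(img.affine, code=2)
    nii.set_qform(img.affine, code=2)
    if description:
        nii.header["descrip"] = description.encode()[:79]
    nib.save(nii, str(path))


def read_scalar_image(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3D scalar NIfTI: (data, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    return data, _sform(img)


def write_scalar_image(
    data: np.ndarray, affine: np.ndarray, path, description: str = ""
) -> None:
    dtype = np.uint8 if data.dtype == bool else np.float32
    nii = nib.Nifti1Image(np.asarray(data).astype(dtype), affine)
    nii.set_sform(affine, code=2)
    nii.set_qform(affine, code=2)
    if description:
        nii.header["descrip"] = description.encode()[:79]
    nib.save(nii, str(path))


def read_tck(path) -> StreamlineBundle:
    """Read an MRtrix .tck streamline file (world mm coordinates)."""
    path = Path(path)
    with open(path, "rb") as f:
        magic = f.read(13)
    if not magic.startswith(b"mrtrix tracks"):
        raise ValueError(f"{path}: not a .tck file (missing 'mrtrix tracks' magic)")
    try:
        tck = TckFile.load(str(path), lazy_load=False)
    except Exception as e:  # header errors: missing END, bad datatype field ...
        raise ValueError(f"{path}: failed to parse .tck file: {e}") from e
    streamlines = [np.asarray(s, dtype=float) for s in tck.streamlines]
    kept = [s for s in streamlines if s.shape[0] >= 2]
    if len(kept) < len(streamlines):
        log.warning(
            "%s: dropped %d streamline(s) with fewer than 2 points",
            path,
            len(streamlines) - len(kept),
        )
    if not kept:
        log.warning("%s: file contains no streamlines", path)
    return StreamlineBundle(kept)


def write_tck(bundle: StreamlineBundle, path) -> None:
    """Write a bundle as .tck (float32, mm world coordinates)."""
    tractogram = Tractogram(
        [np.asarray(s, dtype=np.float32) for s in bundle], affine_to_rasmm=np.eye(4)
    )
    TckFile(tractogram).save(str(path))


def write_sidecar(path, **fields) -> None:
    """Write a JSON sidecar (atlas metadata, resolved config, provenance)."""
    with open(path, "w") as f:
        json.dump(fields, f, indent=2, sort_keys=True, default=str)
        f.write("\n")
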