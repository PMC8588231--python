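"""NIfTI volume I/O and per-patch archive conventions.

Volumes are stored as NIfTI-1; the array is used in the file's native
(i, j, k) data order with no reorientation (callers must pre-orient real
data).  Displacement fields are 4-D with the component axis last in
(di, dj, dk) order, noted in the header description.  Patch archives are
directories of per-patch NIfTI files named ``patch_<i>_<j>_<k>.nii.gz``
where the suffix is the 0-based start voxel of the patch.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Iterator, Tuple

import nibabel as nib
import numpy as np

from .fusion import PatchPrediction
from .grid import PatchStart

_PATCH_RE = re.compile(r"^patch_(\d+)_(\d+)_(\d+)\.nii(\.gz)?$")

DDF_DESCRIPTION = b"displacement field, voxel units, components (di,dj,dk) on last axis"


def read_volume(path) -> Tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns ``(data, affine)``."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several incompatible types
        raise IOError(f"cannot read {path} as NIfTI: {exc}") from exc
    return np.asanyarray(img.dataobj), img.affine


def write_volume(volume: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    """Write a volume (or 4-D field) as NIfTI, carrying over the affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    volume = np.asarray(volume)
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(volume, affine)
    if volume.ndim == 4 and np.issubdtype(volume.dtype, np.floating):
        img.header["descrip"] = DDF_DESCRIPTION
    nib.save(img, str(path))


def write_patch_archive(predictions: Iterable[PatchPrediction], directory) -> int:
    """Write a prediction stream as per-patch NIfTI files; returns the count."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = 0
    for pred in predictions:
        i, j, k = pred.start.origin
        write_volume(np.asarray(pred.values, dtype=np.float32), directory / f"patch_{i}_{j}_{k}.nii.gz")
        n += 1
    return n


def read_patch_archive(directory) -> Iterator[PatchPrediction]:
    """Stream patch predictions back from a ``patch_i_j_k`` directory."""
    directory = Path(directory)
    if not directory.is_dir():
        raise IOError(f"patch archive directory not found: {directory}")
    entries = []
    for p in directory.iterdir():
        m = _PATCH_RE.match(p.name)
        if m:
            entries.append((tuple(int(g) for g in m.groups()[:3]), p))
    if not entries:
        raise IOError(f"no patch_<i>_<j>_<k>.nii[.gz] files in {directory}")
    for index, (origin, p) in enumerate(sorted(entries)):
        data, _ = read_volume(p)
        yield PatchPrediction(start=PatchStart(origin=origin, index=index), values=np.asarray(data))
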