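"""Apply a dense displacement field to volumes and label maps.

The pull (backward) convention is used: the output value at voxel ``x``
is the input sampled at ``x + u(x)``, the standard convention of
learning-based registration frameworks, so a fused DDF can be applied
directly to the moving image.  Out-of-bounds samples clamp to the border,
which avoids injecting zeros at the object boundary that would corrupt
Dice scores.  Scalar/intensity volumes use trilinear interpolation; label
maps use nearest-neighbor, which never invents class ids absent from the
input.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

_ORDERS = {"linear": 1, "nearest": 0}


def warp_volume(volume: np.ndarray, ddf: np.ndarray, interpolation: str = "linear") -> np.ndarray:
    """Resample ``volume`` at ``x + u(x)`` for every output voxel ``x``.

    Parameters
    ----------
    volume : (H, W, C) array
        Scalar image or integer label map.
    ddf : (H, W, C, 3) array
        Displacement in voxel units, component order (di, dj, dk).
    interpolation : {"linear", "nearest"}
        Use ``nearest`` for label maps.
    """
    volume = np.asarray(volume)
    ddf = np.asarray(ddf, dtype=np.float64)
    if interpolation not in _ORDERS:
        raise ValueError(f"interpolation must be one of {tuple(_ORDERS)}, got {interpolation!r}")
    if ddf.shape != volume.shape + (3,):
        raise ValueError(f"ddf shape {ddf.shape} does not match volume {volume.shape} + (3,)")
    if not np.all(np.isfinite(ddf)):
        raise ValueError("displacement field contains non-finite values")

    grid = np.meshgrid(*(np.arange(n, dtype=np.float64) for n in volume.shape), indexing="ij")
    coords = [g + ddf[..., ax] for ax, g in enumerate(grid)]
    out = map_coordinates(
        volume.astype(np.float64),
        coords,
        order=_ORDERS[interpolation],
        mode="nearest",  # clamp to border
    )
    if interpolation == "nearest":
        return out.astype(volume.dtype)
    return out
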