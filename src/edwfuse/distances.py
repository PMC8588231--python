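"""Per-patch distance fields to the patch center.

Every voxel ``(i_P, j_P, k_P)`` of a patch of shape ``(h, w, c)`` is
assigned its distance to the continuous patch center
``((h-1)/2, (w-1)/2, (c-1)/2)`` — half-integer for even sizes, so no
voxel sits exactly at the center of e.g. a 64^3 patch.  Distances are in
index space (voxel units); anisotropic spacing is deliberately not folded
in.  A map depends only on the patch shape and the metric, never on the
patch's position in the volume, so it is computed once and reused.

Supported metrics:

* ``euclidean`` — sqrt of the sum of squared offsets,
* ``manhattan`` — sum of absolute offsets,
* ``chebyshev`` — maximum absolute offset.

Pointwise ``chebyshev <= euclidean <= manhattan`` for any offset vector.
The Chebyshev map is degenerate on patch faces: every voxel of an outer
face shares the single value ``(p-1)/2``, which is why Chebyshev-weighted
fusion behaves like uniform averaging on boundary slices and can leave
residual seams there.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Tuple

import numpy as np

METRICS = ("euclidean", "manhattan", "chebyshev")


@dataclass(frozen=True)
class DistanceMap:
    """Distances from each patch voxel to the patch center."""

    values: np.ndarray
    metric: str
    center: Tuple[float, float, float]


def patch_center(patch_shape) -> Tuple[float, float, float]:
    """Continuous center ``((h-1)/2, (w-1)/2, (c-1)/2)`` of a patch."""
    shape = tuple(int(p) for p in patch_shape)
    if any(p <= 0 for p in shape):
        raise ValueError(f"patch shape must be positive, got {patch_shape!r}")
    return tuple((p - 1) / 2.0 for p in shape)


@lru_cache(maxsize=32)
def _distance_values(patch_shape: Tuple[int, ...], metric: str) -> np.ndarray:
    center = patch_center(patch_shape)
    offsets = np.meshgrid(
        *(np.abs(np.arange(p, dtype=np.float64) - c) for p, c in zip(patch_shape, center)),
        indexing="ij",
    )
    if metric == "euclidean":
        values = np.sqrt(sum(o**2 for o in offsets))
    elif metric == "manhattan":
        values = sum(offsets)
    elif metric == "chebyshev":
        values = np.maximum.reduce(offsets)
    else:
        raise ValueError(f"unknown distance metric {metric!r}; expected one of {METRICS}")
    values.flags.writeable = False
    return values


def distance_map(patch_shape, metric: str = "euclidean") -> DistanceMap:
    """Distance field of shape ``patch_shape`` under the chosen metric."""
    shape = tuple(int(p) for p in patch_shape)
    return DistanceMap(
        values=_distance_values(shape, metric),
        metric=metric,
        center=patch_center(shape),
    )
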