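"""Sliding-window patch-grid combinatorics.

A volume of shape ``(H, W, C)`` is tiled by patches of shape ``(h, w, c)``
whose low corners sit on a per-axis lattice of stride ``s``.  Patch extents
are half-open, ``[origin, origin + patch_shape)``, and coordinates are
0-based.  The number of patches per axis in strict mode is
``(D - p) / s + 1``, so the total patch count is the product over axes.

Overlap counts (how many patches cover a given voxel) are computed by
direct enumeration over the per-axis start lattice; the count is separable,
``n = n_i * n_j * n_k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence, Tuple

import numpy as np

_AXIS_NAMES = ("axis 0 (i)", "axis 1 (j)", "axis 2 (k)")


class GeometryError(ValueError):
    """Raised when a patch-grid configuration violates its invariants."""


def _as_triple(value, name: str) -> Tuple[int, int, int]:
    try:
        triple = tuple(int(v) for v in value)
    except TypeError:
        triple = (int(value),) * 3
    if len(triple) != 3:
        raise GeometryError(f"{name} must have exactly 3 components, got {value!r}")
    return triple  # type: ignore[return-value]


@dataclass(frozen=True)
class PatchStart:
    """Low-corner voxel coordinate of one patch plus its row-major rank."""

    origin: Tuple[int, int, int]
    index: int


@dataclass(frozen=True)
class FusionGeometry:
    """Volume / patch / stride triple defining the sliding-window lattice.

    Parameters
    ----------
    volume_shape : (H, W, C)
        Whole-volume extent in voxels.
    patch_shape : (h, w, c)
        Patch extent in voxels; each component must not exceed the volume.
    stride : (s_i, s_j, s_k)
        Lattice spacing of patch starts; each component must be positive
        and no larger than the patch size on its axis (a larger stride
        would leave uncovered voxels).
    boundary_mode : {"strict", "flush_end"}
        ``strict`` requires ``(D - p) % s == 0`` per axis so the lattice
        ends exactly at ``D - p``; ``flush_end`` appends a final start at
        ``D - p`` when the lattice does not already reach it, guaranteeing
        full coverage for arbitrary shapes.
    """

    volume_shape: Tuple[int, int, int]
    patch_shape: Tuple[int, int, int]
    stride: Tuple[int, int, int]
    boundary_mode: str = "strict"

    def __post_init__(self) -> None:
        object.__setattr__(self, "volume_shape", _as_triple(self.volume_shape, "volume_shape"))
        object.__setattr__(self, "patch_shape", _as_triple(self.patch_shape, "patch_shape"))
        object.__setattr__(self, "stride", _as_triple(self.stride, "stride"))
        if self.boundary_mode not in ("strict", "flush_end"):
            raise GeometryError(
                f"boundary_mode must be 'strict' or 'flush_end', got {self.boundary_mode!r}"
            )
        for ax, (D, p, s) in enumerate(zip(self.volume_shape, self.patch_shape, self.stride)):
            name = _AXIS_NAMES[ax]
            if D <= 0:
                raise GeometryError(f"volume size must be positive on {name}, got {D}")
            if not 0 < p <= D:
                raise GeometryError(
                    f"patch size must satisfy 0 < p <= volume on {name}: p={p}, volume={D}"
                )
            if not 0 < s <= p:
                raise GeometryError(
                    f"stride must satisfy 0 < s <= patch on {name}: s={s}, patch={p}"
                )
            if self.boundary_mode == "strict" and (D - p) % s != 0:
                raise GeometryError(
                    f"strict mode requires (volume - patch) divisible by stride on {name}: "
                    f"({D} - {p}) % {s} != 0"
                )

    def axis_starts(self, axis: int) -> np.ndarray:
        """Start positions of the patch lattice on one axis, ascending."""
        D = self.volume_shape[axis]
        p = self.patch_shape[axis]
        s = self.stride[axis]
        starts = np.arange(0, D - p + 1, s)
        if self.boundary_mode == "flush_end" and starts[-1] != D - p:
            starts = np.append(starts, D - p)
        return starts


def patch_starts(geom: FusionGeometry) -> list[PatchStart]:
    """All patch start coordinates in row-major (i outermost) order."""
    ai, aj, ak = (geom.axis_starts(a) for a in range(3))
    out: list[PatchStart] = []
    idx = 0
    for i in ai:
        for j in aj:
            for k in ak:
                out.append(PatchStart(origin=(int(i), int(j), int(k)), index=idx))
                idx += 1
    return out


def iter_patch_starts(geom: FusionGeometry) -> Iterator[PatchStart]:
    """Lazy row-major iterator over the start lattice."""
    yield from patch_starts(geom)


def num_patches(geom: FusionGeometry) -> int:
    """Total patch count ``m = prod_axis((D - p) / s + 1)`` (strict mode)."""
    if geom.boundary_mode == "strict":
        m = 1
        for D, p, s in zip(geom.volume_shape, geom.patch_shape, geom.stride):
            m *= (D - p) // s + 1
        return m
    return int(np.prod([len(geom.axis_starts(a)) for a in range(3)]))


def axis_overlap_counts(geom: FusionGeometry, axis: int) -> np.ndarray:
    """Per-position overlap count on one axis by enumerating the start lattice.

    Enumeration is the normative definition: position ``i`` is covered by a
    patch starting at ``a`` iff ``a <= i < a + p``.
    """
    starts = geom.axis_starts(axis)
    p = geom.patch_shape[axis]
    pos = np.arange(geom.volume_shape[axis])
    return np.sum((starts[None, :] <= pos[:, None]) & (pos[:, None] < starts[None, :] + p), axis=1)


def overlap_count(geom: FusionGeometry, voxel: Sequence[int]) -> int:
    """Number of patches whose half-open extent contains ``voxel``."""
    voxel = tuple(int(v) for v in voxel)
    for ax, (v, D) in enumerate(zip(voxel, geom.volume_shape)):
        if not 0 <= v < D:
            raise ValueError(f"voxel {voxel} outside volume on {_AXIS_NAMES[ax]} (size {D})")
    n = 1
    for ax, v in enumerate(voxel):
        starts = geom.axis_starts(ax)
        p = geom.patch_shape[ax]
        n *= int(np.sum((starts <= v) & (v < starts + p)))
    return n


def overlap_count_volume(geom: FusionGeometry) -> np.ndarray:
    """Whole-volume integer field of per-voxel overlap counts.

    Separability makes this an outer product of the three per-axis count
    vectors.  The field sums to ``num_patches * h * w * c``: each patch
    contributes exactly one coverage event per patch voxel.
    """
    ni, nj, nk = (axis_overlap_counts(geom, a) for a in range(3))
    return ni[:, None, None] * nj[None, :, None] * nk[None, None, :]
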