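import numpy as np
import pytest

from edwfuse.fusion import (
    FusionInputError,
    PatchPrediction,
    extract_patches,
    fuse,
    fuse_naive,
)
from edwfuse.grid import FusionGeometry, patch_starts

from conftest import random_strict_geometry

ALL_SCHEMES = [
    pytest.param(("edw", "euclidean"), id="edw-euclidean"),
    pytest.param(("edw", "manhattan"), id="edw-manhattan"),
    pytest.param(("edw", "chebyshev"), id="edw-chebyshev"),
    pytest.param(("aaw", "euclidean"), id="aaw"),
    pytest.param(("idw", "euclidean"), id="idw"),
]


def scheme_of(spec):
    from edwfuse.weighting import WeightScheme

    return WeightScheme(*spec)


@pytest.mark.parametrize("spec", ALL_SCHEMES)
def test_fidelity_exact_interpolation(spec, rng):
    """Fusing patches extracted from a volume reproduces the volume.

    Weights form a partition of unity, so consistent inputs are
    interpolated exactly regardless of scheme.
    """
    geom = FusionGeometry((24, 20, 24), (8, 4, 8), (4, 2, 8))
    volume = rng.normal(size=geom.volume_shape + (3,))
    fused = fuse(extract_patches(volume, geom), geom, scheme_of(spec))
    assert np.abs(fused - volume).max() <= 1e-10


def test_all_constant_patches_give_constant_volume():
    geom = FusionGeometry((12, 12, 12), (4, 4, 4), (2, 2, 2))
    preds = [
        PatchPrediction(start=ps, values=np.full((4, 4, 4, 1), 7.25))
        for ps in patch_starts(geom)
    ]
    fused = fuse(preds, geom, scheme_of(("edw", "euclidean")))
    assert np.abs(fused - 7.25).max() <= 1e-12


@pytest.mark.parametrize("spec", ALL_SCHEMES)
def test_streaming_matches_naive_oracle(spec, rng):
    """fuse (streaming accumulation) == fuse_naive (per-voxel gather)."""
    geom = FusionGeometry((12, 10, 8), (6, 5, 4), (3, 5, 2))
    preds = [
        PatchPrediction(start=ps, values=rng.normal(size=geom.patch_shape + (2,)))
        for ps in patch_starts(geom)
    ]
    scheme = scheme_of(spec)
    assert np.abs(fuse(preds, geom, scheme) - fuse_naive(preds, geom, scheme)).max() <= 1e-10


def test_naive_oracle_on_random_geometries(rng):
    """Streaming/naive agreement over randomized small geometries."""
    for _ in range(8):
        geom = random_strict_geometry(rng, max_dim=16, max_patch=6)
        preds = [
            PatchPrediction(start=ps, values=rng.normal(size=geom.patch_shape + (1,)))
            for ps in patch_starts(geom)
        ]
        scheme = scheme_of(("edw", "euclidean"))
        assert np.abs(fuse(preds, geom, scheme) - fuse_naive(preds, geom, scheme)).max() <= 1e-10


def test_single_patch_geometry_returns_the_patch(rng):
    geom = FusionGeometry((6, 6, 6), (6, 6, 6), (6, 6, 6))
    values = rng.normal(size=(6, 6, 6, 3))
    out = fuse_naive([PatchPrediction(start=patch_starts(geom)[0], values=values)], geom,
                     scheme_of(("edw", "euclidean")))
    assert np.abs(out - values).max() <= 1e-12


def test_linearity(rng):
    geom = FusionGeometry((16, 16, 16), (8, 8, 8), (4, 4, 4))
    scheme = scheme_of(("edw", "euclidean"))
    starts = patch_starts(geom)
    P = [rng.normal(size=geom.patch_shape + (1,)) for _ in starts]
    Q = [rng.normal(size=geom.patch_shape + (1,)) for _ in starts]
    alpha, beta = 2.5, -0.75
    mixed = fuse(
        [PatchPrediction(s, alpha * p + beta * q) for s, p, q in zip(starts, P, Q)],
        geom, scheme,
    )
    fp = fuse([PatchPrediction(s, p) for s, p in zip(starts, P)], geom, scheme)
    fq = fuse([PatchPrediction(s, q) for s, q in zip(starts, Q)], geom, scheme)
    assert np.abs(mixed - (alpha * fp + beta * fq)).max() <= 1e-10


@pytest.mark.parametrize("spec", ALL_SCHEMES)
def test_convexity_bound(spec, rng):
    """Each fused voxel lies within [min, max] of its overlapping inputs."""
    geom = FusionGeometry((12, 12, 12), (6, 6, 6), (3, 3, 3))
    preds = [
        PatchPrediction(start=ps, values=rng.normal(size=geom.patch_shape + (1,)))
        for ps in patch_starts(geom)
    ]
    fused = fuse(preds, geom, scheme_of(spec))
    lo = np.full(geom.volume_shape + (1,), np.inf)
    hi = np.full(geom.volume_shape + (1,), -np.inf)
    for pred in preds:
        sl = tuple(slice(o, o + p) for o, p in zip(pred.start.origin, geom.patch_shape))
        lo[sl] = np.minimum(lo[sl], pred.values)
        hi[sl] = np.maximum(hi[sl], pred.values)
    assert np.all(fused >= lo - 1e-10)
    assert np.all(fused <= hi + 1e-10)


def test_channel_agnosticism(rng):
    """Fusing a 3-channel field equals fusing each channel separately."""
    geom = FusionGeometry((16, 16, 16), (8, 8, 8), (4, 4, 4))
    volume = rng.normal(size=geom.volume_shape + (3,))
    scheme = scheme_of(("edw", "euclidean"))
    full = fuse(extract_patches(volume, geom), geom, scheme)
    for ch in range(3):
        single = fuse(extract_patches(volume[..., ch], geom), geom, scheme)
        assert np.array_equal(single[..., 0], full[..., ch])


class TestInputValidation:
    def setup_method(self):
        self.geom = FusionGeometry((8, 8, 8), (4, 4, 4), (4, 4, 4))
        self.preds = list(extract_patches(np.zeros((8, 8, 8, 1)), self.geom))

    def test_missing_patch(self):
        with pytest.raises(FusionInputError, match="missing"):
            fuse(self.preds[:-1], self.geom, scheme_of(("aaw", "euclidean")))

    def test_duplicate_patch(self):
        with pytest.raises(FusionInputError, match="duplicate"):
            fuse(self.preds + [self.preds[0]], self.geom, scheme_of(("aaw", "euclidean")))

    def test_off_lattice_start(self):
        bad = PatchPrediction(
            start=type(self.preds[0].start)(origin=(1, 0, 0), index=99),
            values=np.zeros((4, 4, 4, 1)),
        )
        with pytest.raises(FusionInputError, match="lattice"):
            fuse(self.preds[1:] + [bad], self.geom, scheme_of(("aaw", "euclidean")))

    def test_shape_mismatch(self):
        bad = PatchPrediction(start=self.preds[0].start, values=np.zeros((3, 4, 4, 1)))
        with pytest.raises(FusionInputError, match="shape"):
            fuse([bad], self.geom, scheme_of(("aaw", "euclidean")))

    def test_extract_shape_mismatch(self):
        with pytest.raises(FusionInputError, match="shape"):
            list(extract_patches(np.zeros((9, 8, 8)), self.geom))


def test_extract_patches_count_and_order(rng):
    geom = FusionGeometry((16, 16, 16), (8, 8, 8), (4, 4, 4))
    volume = rng.normal(size=(16, 16, 16))
    patches = list(extract_patches(volume, geom))
    assert len(patches) == 27
    assert [p.start.origin for p in patches[:3]] == [(0, 0, 0), (0, 0, 4), (0, 0, 8)]
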