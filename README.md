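# edwfuse

Seam-free reconstruction of whole-volume dense displacement fields (DDFs)
from overlapping 3-D patch predictions.

Patch-based registration networks predict a displacement field one
`h×w×c` patch at a time, with patches extracted by a sliding window of
stride `s`. Stitching the patches back together with uniform weights
leaves **grid-like artifacts** at patch boundaries: zero-padded
convolutions see less context near patch edges, so edge predictions are
less reliable, and overlapping patches disagree there. `edwfuse`
implements **exponential-distance weighting (EDW)** for the fusion step,
alongside the arithmetic-average (AAW) and inverse-distance (IDW)
baselines, plus everything needed to exercise and validate the method on
synthetic data: patch-grid combinatorics, warping, and evaluation
metrics.

## The method

At voxel `(i,j,k)`, covered by `n` overlapping patches, let `d_t` be the
distance from the voxel to the center of patch `t` (Euclidean, Manhattan
or Chebyshev, in voxel units; the center of an `h×w×c` patch is at
`((h−1)/2, (w−1)/2, (c−1)/2)`). The fused prediction is the convex
combination

    φ̂(i,j,k) = Σ_t ω_t φ_t(i,j,k),   ω_t = exp(−d_t) / Σ_u exp(−d_u)

so a patch's influence decays exponentially with how far the voxel sits
from that patch's center — edge predictions are suppressed, center
predictions dominate, and the weight profile across the volume is smooth
rather than piecewise constant. AAW uses `ω_t = 1/n`; IDW uses
`ω_t ∝ 1/(d_t + ε)`. The engine accumulates `exp(−d)·φ` and `exp(−d)`
in one streaming pass and divides at the end, which is algebraically
identical to per-voxel normalization but needs only O(volume) memory at
any overlap factor.

Supporting machinery: sliding-window geometry (patch counts
`m = Π (D−p)/s + 1`, per-voxel overlap counts), pull-convention warping
of images and label maps, Dice similarity, the Jacobian-determinant
folding ratio `ρ = #{det(I+∇u) < 0}/V`, a seam-energy diagnostic
(field discontinuity across patch-boundary planes relative to all
planes), and the FFT of the fusion-weight profile along a grid line.

## Worked example

Fuse the same noisy patch stream — a smooth synthetic ground-truth field
plus patch predictions whose error grows toward patch edges — under all
schemes and compare:

```python
from edwfuse.synthetic import make_scene, run_comparison_experiment

scene = make_scene(seed=0)          # 48³ volume, 16³ patches, stride 8
table = run_comparison_experiment(scene)
print(table.to_string(float_format=lambda v: f"{v:.4f}"))
```

```
                rmse  seam_energy  edge_seam_energy  folding_ratio  dsc_0  dsc_1  dsc_2  dsc_3
scheme
edw/euclidean 0.3529       0.8015            0.9280         0.0036 0.9862 0.9498 0.9597 0.9826
edw/manhattan 0.3826       0.7447            0.8202         0.0046 0.9844 0.9442 0.9567 0.9816
edw/chebyshev 0.3569       1.2039            2.4393         0.0070 0.9870 0.9531 0.9617 0.9830
aaw           0.4025       2.3534            2.4393         0.0063 0.9829 0.9377 0.9505 0.9789
idw/euclidean 0.3620       1.9978            2.2639         0.0050 0.9865 0.9507 0.9602 0.9828
```

Reading the table: Euclidean EDW reconstructs the true field most
accurately (lowest RMSE) and its seam energy sits below 1 — patch
boundaries are statistically indistinguishable from any other plane.
Uniform averaging (AAW) leaves strong seams (2.35), and IDW, whose
weights decay only polynomially with distance, barely improves on it
(2.00). The `edge_seam_energy` column is measured on the volume's last
face slice: there the Chebyshev distance is constant across the face, its
weights degenerate to uniform, and its edge seam energy equals AAW's
exactly (2.4393) while Euclidean EDW stays smooth — Chebyshev removes
interior seams but not boundary-slice ones. Dice columns score a
label phantom warped by the fused field against one warped by the true
field, per class.

A command-line interface exposes the same pipeline
(`edwfuse simulate | fuse | warp | evaluate | experiment`); patch
archives are directories of `patch_<i>_<j>_<k>.nii.gz` files keyed by
the 0-based patch start voxel.

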