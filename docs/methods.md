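# Methods

## Problem setting

A patch-based registration model maps an `h×w×c` patch pair to an
`h×w×c×3` displacement patch. At inference, patches are extracted from a
`H×W×C` volume by a sliding window with per-axis stride `s ≤ p`; patch
extents are half-open `[origin, origin + patch_shape)` with 0-based
coordinates. In *strict* mode the lattice must satisfy
`(D − p) mod s = 0` per axis, giving `m = Π_axis ((D − p)/s + 1)`
patches; *flush_end* mode appends a final start at `D − p` on any axis
whose lattice does not already reach it, so arbitrary shapes are fully
covered. Per-voxel overlap counts are defined by direct enumeration of
the per-axis start lattice (the count is separable,
`n = n_i·n_j·n_k`); enumeration is O(starts-per-axis) and unambiguous,
and the interior identity `n_i = p/s` (when `s | p`) is kept as a
property test rather than as the implementation.

## Fusion weights

Each patch carries a precomputed distance map from every patch voxel to
the continuous patch center `((h−1)/2, …)` — half-integer for even
sizes; no rounding is applied. Distances are in index space; voxel
spacing is not folded in (isotropic-resolution data is the intended
regime, and anisotropic users can resample upstream). Three metrics are
provided (Chebyshev ≤ Euclidean ≤ Manhattan pointwise); the Chebyshev
map is constant on each outer face of a cubic patch, a degeneracy with
visible consequences (below).

Weights at a voxel covered by patches at distances `d_1…d_n`:

* **EDW**: `ω_t = e^{−d_t} / Σ e^{−d_u}` — natural base, no temperature
  parameter. Computed with the minimum distance subtracted before
  exponentiation (identical algebraically, safe for any patch size).
* **AAW**: `ω_t = 1/n`.
* **IDW**: `ω_t ∝ 1/(d_t + ε)`, `ε = 10⁻⁶` by default. The
  regularizer keeps the exact-center voxel finite; any small `ε`
  preserves the qualitative contrast with EDW, namely a polynomial
  rather than exponential tail.

All schemes are convex combinations (partition of unity to 1e−12).

The fusion engine streams: `numerator += κ(d)·φ`, `denominator += κ(d)`
per patch, one division at the end, with `κ = e^{−d}`, `1`, or
`1/(d+ε)`. Because the per-voxel normalizer is the sum of the same
kernel values, this equals the per-voxel normalized sum exactly; memory
is O(volume) independent of overlap. The streaming path uses raw
`e^{−d}` without a per-voxel shift: the denominator is bounded below by
the nearest-center contribution, and the smallest kernel value for a
64³ patch (`e^{−56.3} ≈ 4·10⁻²⁵`) is far from double-precision
underflow; the approach is valid for patch diameters up to roughly 600
voxels, beyond which the per-voxel reference path (`fuse_naive`, which
shifts per voxel) should be used. `fuse_naive` implements the literal
per-voxel gather-weight-sum and serves as the oracle in tests. Patch
order is the row-major lattice order; results are order-independent to
below test tolerance.

## Warping and metrics

Warping uses the pull (backward) convention — output voxel `x` samples
the moving image at `x + u(x)` — matching how learning-based
registration frameworks define their displacement outputs; the
convention choice is documented rather than configurable.
Out-of-bounds samples clamp to the border (avoids zero-fill bleeding
into boundary tissue and corrupting Dice). Intensity images use
trilinear interpolation; label maps nearest-neighbor, which cannot
invent classes. Whether real evaluation pipelines warp labels by
nearest-neighbor or by linear-then-argmax is generally unstated;
nearest is implemented.

Dice is `2|A∩B|/(|A|+|B|)` per class, defined as 1 when the class is
empty in both volumes. The Jacobian determinant is `det(I + ∇u)` with
central differences in the interior and one-sided stencils on faces
(exact for affine fields); the folding ratio `ρ` counts strictly
negative determinants over the whole volume, faces included — voxels
with `det = 0` are not counted as folded.

Seam energy quantifies what figures usually show qualitatively: the mean
absolute one-voxel finite difference of the field across planes at
lattice multiples of the stride, divided by the same quantity over all
planes. ≈1 means boundaries look like any other plane; ≫1 means seams;
constant fields return 1 by convention. The weight-profile diagnostic
collects, along one grid line, the normalized weight of the patch
*owning* each voxel (nearest center, first on ties) and returns its FFT
amplitude; high-frequency content is compared *relative to the DC
amplitude*, since the AAW profile lives at `1/n` and the EDW profile
near 1 and absolute band amplitudes are incomparable across schemes.

## Synthetic data model

The generator stands in for trained networks plus imaging data, at desk
scale. Default study conditions: 48³ volume, 16³ patches, stride 8
(two-fold interior overlap per axis), chosen to keep the full suite in
seconds while preserving genuine overlap structure.

* **Ground truth**: a sum of 6 Gaussian-envelope vector bumps (envelope
  width uniform in `[min(shape)/6, min(shape)/3]`), rescaled so the
  maximum displacement magnitude is 2 voxels. With amplitude well below
  the envelope width the field is diffeomorphic; the default 48³/2-voxel
  field has folding ratio 0.
* **Predictor error** has two components, mirroring the two things
  zero-padding does to a convolutional predictor at patch borders:
  1. a *systematic* attenuation of the prediction toward zero,
     `(1 − γ·d/d_max)`, `γ = 0.5` at the maximal-distance voxel — the
     padded context is identical in every patch's own frame, so this
     component is shared across patches (γ from the receptive-field
     argument that roughly half a border voxel's context is padding);
  2. an *independent* zero-mean Gaussian noise field per patch, smoothed
     within the patch (correlation length 1.5 voxels, renormalized to
     unit pointwise variance — network error fields are spatially
     smooth, not voxel-white) and scaled per voxel by
     `σ(d) = σ_center + (σ_edge − σ_center)·d/d_max`, default
     `(0.05, 1.0)` voxels.

  The split matters and is the package's own modeling position: for
  purely independent zero-mean errors the fused variance is
  `Σ ω_t² σ_t²` for any deterministic weights, and uniform `1/n`
  weighting is close to the inverse-variance optimum under the mild
  linear σ contrast — no center-favoring scheme can beat averaging in
  RMSE, which contradicts what distance weighting achieves in real
  systems. The shared edge bias is what averaging cannot cancel and
  center-weighting avoids; with it, EDW dominates AAW in RMSE and seam
  energy across seeds, and the Chebyshev face degeneracy reproduces the
  boundary-slice seams its interior slices do not show. With
  `σ = (0, 0)` and `γ = 0` the patches are exact restrictions and every
  scheme reconstructs the field to round-off (the master regression
  test).
* **Label phantoms**: a wobbled radial coordinate partitioned at
  quantiles into background plus nested tissue shells (inner 60% of
  voxels split evenly), every class nonempty by construction.

What the synthetic model does *not* emulate: realistic brain anatomy or
intensities, spatially correlated inter-subject deformation statistics,
network-specific error structure (the linear σ and attenuation profiles
are stand-ins — the true profiles of trained models are unknown), and
fusion wall-clock behavior at full brain scale. Passing tests therefore
demonstrate the correctness and the qualitative orderings of the fusion
machinery, not clinical registration accuracy.

## Numerical and design notes

* Distance maps are cached per `(patch_shape, metric)` and are
  position-independent.
* All accumulation in float64; fidelity and oracle-equivalence
  tolerances are 1e−10 (max abs), weight normalization 1e−12.
* Owning-patch ties in the weight profile resolve to the first patch in
  lattice order; tie voxels are measure-zero off the exact mid-planes.
* Degenerate inputs: single-patch geometries, 1³ patches (distance 0
  everywhere → uniform weights), and constant fields (seam energy
  defined as 1) are all handled and tested.
* Experiment comparisons re-seed the predictor per scheme so every
  scheme fuses the *identical* noisy patches; differences are
  attributable to weights alone.
* Sub-seeds for the scene components derive from `numpy.random.
  SeedSequence`, so scenes are bit-reproducible from a single integer.

## Limitations

Only lattice patch placement is supported (no key-point sampling or
thin-plate-spline fusion of scattered patches); no central-crop or
surface-discarding fusion; no diffeomorphic integration of the fused
field; no learned weighting. Real NIfTI inputs are used in their native
data order without reorientation — users must pre-orient. The EDW/AAW
RMSE comparison depends on the presence of a systematic edge-error
component; if a predictor's edge errors were genuinely independent and
zero-mean, uniform averaging would be the better estimator and the
seam-free advantage of EDW would be cosmetic rather than quantitative.
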