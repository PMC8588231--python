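"""Normalized per-voxel fusion weights from per-patch center distances.

Three schemes are supported.  With ``d_t`` the distance from a voxel to
the center of the t-th overlapping patch:

* EDW:  ``w_t = exp(-d_t) / sum_u exp(-d_u)`` — a softmax over negative
  distances; strictly decreasing in ``d_t``, so edge predictions (large
  ``d``) are exponentially suppressed.
* AAW:  ``w_t = 1/n`` — uniform averaging, the conventional baseline.
* IDW:  ``w_t = (1/(d_t+eps)) / sum_u (1/(d_u+eps))`` — inverse-distance
  weighting, regularized with a small ``eps`` so the exact patch center
  (``d = 0``) stays finite.

All schemes return a convex combination (non-negative, sums to 1).  The
EDW softmax is evaluated with the minimum distance subtracted before
exponentiating — algebraically identical but immune to underflow for
arbitrarily large patches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

METHODS = ("edw", "aaw", "idw")

DEFAULT_IDW_EPSILON = 1e-6


@dataclass(frozen=True)
class WeightScheme:
    """Weighting method plus the distance metric feeding it.

    ``metric`` is ignored by AAW (uniform weights need no distances).
    """

    method: str = "edw"
    metric: str = "euclidean"
    idw_epsilon: float = DEFAULT_IDW_EPSILON

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown weighting method {self.method!r}; expected one of {METHODS}")
        if self.method == "idw" and not self.idw_epsilon > 0:
            raise ValueError(f"idw_epsilon must be positive, got {self.idw_epsilon}")

    @property
    def label(self) -> str:
        return self.method if self.method == "aaw" else f"{self.method}/{self.metric}"

    def kernel(self, distances: np.ndarray) -> np.ndarray:
        """Unnormalized weight kernel kappa(d); weights are kappa / sum(kappa).

        Used by the streaming fusion accumulator: because the normalizer is
        the sum of the same kernel values, accumulating ``kappa * value``
        and ``kappa`` separately and dividing at the end reproduces the
        normalized weighted sum exactly.
        """
        d = np.asarray(distances, dtype=np.float64)
        if self.method == "edw":
            return np.exp(-d)
        if self.method == "aaw":
            return np.ones_like(d)
        return 1.0 / (d + self.idw_epsilon)

    def weights(self, distances) -> np.ndarray:
        """Normalized weights for one voxel's list of per-patch distances."""
        if self.method == "edw":
            return edw_weights(distances)
        if self.method == "aaw":
            return aaw_weights(len(np.atleast_1d(distances)))
        return idw_weights(distances, epsilon=self.idw_epsilon)


def _check_distances(distances) -> np.ndarray:
    d = np.asarray(distances, dtype=np.float64)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("distances must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(d)) or np.any(d < 0):
        raise ValueError("distances must be finite and non-negative")
    return d


def edw_weights(distances) -> np.ndarray:
    """Exponential-distance weights ``exp(-d_t) / sum exp(-d_u)``.

    Shifting by the minimum distance before exponentiating leaves the
    ratio unchanged and keeps the numerator of the dominant term at 1, so
    the result is finite for any distance magnitude.
    """
    d = _check_distances(distances)
    shifted = np.exp(-(d - d.min()))
    return shifted / shifted.sum()


def aaw_weights(n: int) -> np.ndarray:
    """Uniform weights ``1/n`` over the n overlapping patches."""
    n = int(n)
    if n < 1:
        raise ValueError(f"need at least one overlapping patch, got n={n}")
    return np.full(n, 1.0 / n)


def idw_weights(distances, epsilon: float = DEFAULT_IDW_EPSILON) -> np.ndarray:
    """Inverse-distance weights ``(1/(d_t+eps)) / sum (1/(d_u+eps))``."""
    if not epsilon > 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    d = _check_distances(distances)
    inv = 1.0 / (d + epsilon)
    return inv / inv.sum()
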