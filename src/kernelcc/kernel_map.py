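"""Weighted-distance universal kernel and kernel-matrix construction.

The kernel replaces an explicit feature map: k(x, xj) = c_x * exp(-D(x, xj))
with the per-component weighted Euclidean distance

    D(x, xj) = sqrt( s1*(x1 - x1j)^2/sigma1^2 + s2*(x2 - x2j)^2/sigma2^2 ).

Note the exponent is the *distance itself*, not its square (exponential of
Euclidean, a member of the universal kernel class), and each component has its
own sigma-weight.  The 0/1 component mask (s1, s2) switches single-factor
variants on and off.  A subject's row of the 2m x 2m kernel matrix is its new
feature vector; each entry doubles as an unnormalized Gaussian-like density
contribution, which is what lets the downstream perceptron embed the training
distribution.

The normalization constant c_x defaults to 1: it rescales all perceptron
inputs uniformly and is absorbed by the learned weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_data import CaseControlDataset

__all__ = [
    "SigmaWeights",
    "ComponentMask",
    "KernelMatrix",
    "weighted_distance",
    "kernel_value",
    "kernel_matrix",
    "kernel_row",
]


@dataclass(frozen=True)
class SigmaWeights:
    """Per-component bandwidths of the weighted distance."""

    sigma1: float
    sigma2: float

    def __post_init__(self) -> None:
        for name in ("sigma1", "sigma2"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.sigma1, self.sigma2])


@dataclass(frozen=True)
class ComponentMask:
    """0/1 switches selecting which risk factors enter the distance."""

    s1: int
    s2: int

    def __post_init__(self) -> None:
        if self.s1 not in (0, 1) or self.s2 not in (0, 1):
            raise ValueError("mask entries must be 0 or 1")
        if self.s1 == self.s2 == 0:
            raise ValueError("at least one component must be active")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.s1, self.s2], dtype=float)


BOTH = ComponentMask(1, 1)
X1_ONLY = ComponentMask(1, 0)
X2_ONLY = ComponentMask(0, 1)


@dataclass(frozen=True)
class KernelMatrix:
    """2m x 2m kernel of a training set; row i is subject i's feature vector."""

    values: np.ndarray
    c_x: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("kernel matrix must be square")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _as_points(x) -> np.ndarray:
    pts = np.asarray(
        [x.x1, x.x2] if hasattr(x, "x1") and not isinstance(x, CaseControlDataset) else x,
        dtype=float,
    )
    return np.atleast_2d(pts)


def _pairwise_distance(
    a: np.ndarray, b: np.ndarray, sw: SigmaWeights, mask: ComponentMask
) -> np.ndarray:
    scaled = (a[:, None, :] - b[None, :, :]) / sw.as_array
    return np.sqrt((mask.as_array * scaled**2).sum(axis=-1))


def weighted_distance(x, xj, sw: SigmaWeights, mask: ComponentMask = BOTH) -> float:
    """Masked, sigma-weighted Euclidean distance between two risk vectors."""
    d = _pairwise_distance(_as_points(x), _as_points(xj), sw, mask)
    return float(d[0, 0]) if d.size == 1 else d


def kernel_value(
    x, xj, sw: SigmaWeights, mask: ComponentMask = BOTH, c_x: float = 1.0
) -> float:
    """k(x, xj) = c_x * exp(-D(x, xj)); symmetric, in (0, c_x]."""
    if c_x <= 0:
        raise ValueError("c_x must be > 0")
    d = weighted_distance(x, xj, sw, mask)
    return c_x * np.exp(-d)


def kernel_matrix(
    ds: CaseControlDataset | np.ndarray,
    sw: SigmaWeights,
    mask: ComponentMask = BOTH,
    c_x: float = 1.0,
) -> KernelMatrix:
    """Kernel matrix of a training set (symmetric, diagonal equal to c_x)."""
    if c_x <= 0:
        raise ValueError("c_x must be > 0")
    X = ds.X if isinstance(ds, CaseControlDataset) else np.asarray(ds, dtype=float)
    if X.size == 0:
        raise ValueError("empty training set")
    K = c_x * np.exp(-_pairwise_distance(X, X, sw, mask))
    return KernelMatrix(values=K, c_x=c_x)


def kernel_row(
    x,
    training: CaseControlDataset | np.ndarray,
    sw: SigmaWeights,
    mask: ComponentMask = BOTH,
    c_x: float = 1.0,
) -> np.ndarray:
    """Feature vector(s) of prospective subject(s) against the training set.

    Returns shape (2m,) for a single risk vector, else (n, 2m).
    """
    if c_x <= 0:
        raise ValueError("c_x must be > 0")
    T = training.X if isinstance(training, CaseControlDataset) else np.asarray(
        training, dtype=float
    )
    if T.size == 0:
        raise ValueError("empty training set")
    single = hasattr(x, "x1") or np.ndim(x) == 1
    pts = _as_points(x)
    rows = c_x * np.exp(-_pairwise_distance(pts, T, sw, mask))
    return rows[0] if single else rows
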