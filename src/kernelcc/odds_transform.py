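"""Continuous odds-ratio curves from classifier scores.

The kernel-perceptron output has no native epidemiologic reading, so its
normalized scores z are converted into one.  Gaussian kernel density
estimates h1 and h0 of the case and control score distributions (each
generalizing the respective histogram, continuous even where histogram bins
are empty) give the empirical conditional probability under the balanced
case-control design,

    p_r(z) = Pr(class = 1 | z) = h1(z) / (h1(z) + h0(z)),

and shifting by a positive score increment delta_z, p_1(z) = p_r(z + delta_z),
yields the continuous odds ratio

    OR(z) = [p_1/(1 - p_1)] * [(1 - p_r)/p_r].

For scores produced by a logistic model the ln-OR curve is (asymptotically)
constant -- the model coefficient on the score scale -- while nonlinear
learners produce genuinely z-dependent curves.  Grid points where a density
vanishes or p hits 0/1 numerically are masked (NaN) rather than clipped, so
no infinite odds ratios are fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .perceptron import ScoreSet

__all__ = [
    "DensityPair",
    "ORCurve",
    "estimate_densities",
    "conditional_probability",
    "or_curve",
]

GRID_SIZE = 512
_EPS = 1e-9


@dataclass
class DensityPair:
    """Case (h1) and control (h0) score densities on a common [0, 1] grid."""

    z_grid: np.ndarray
    h0: np.ndarray
    h1: np.ndarray
    bandwidth0: float
    bandwidth1: float

    def __post_init__(self) -> None:
        if np.any(self.h0 < 0) or np.any(self.h1 < 0):
            raise ValueError("densities must be nonnegative")


@dataclass
class ORCurve:
    """Odds-ratio curve over the score grid for increment delta_z."""

    z_grid: np.ndarray
    p_r: np.ndarray
    p_1: np.ndarray
    odds_ratio: np.ndarray
    log_or: np.ndarray
    delta_z: float
    n_masked: int


def estimate_densities(
    scores: ScoreSet | tuple[np.ndarray, np.ndarray],
    bandwidth: float | str = "silverman",
    grid_size: int = GRID_SIZE,
) -> DensityPair:
    """Separate Gaussian KDEs of case and control scores on a common grid.

    ``bandwidth`` is either ``"silverman"``/``"scott"`` (rule applied to each
    class separately) or an absolute bandwidth in score units.  Accepts a
    :class:`~kernelcc.perceptron.ScoreSet` or a ``(case, control)`` pair of
    score arrays.
    """
    if isinstance(scores, ScoreSet):
        case, ctrl = scores.case_scores(), scores.control_scores()
    else:
        case, ctrl = (np.asarray(s, dtype=float) for s in scores)
    if case.size < 2 or ctrl.size < 2:
        raise ValueError("need at least two scores per class for a KDE")
    grid = np.linspace(0.0, 1.0, grid_size)

    def _kde(sample: np.ndarray) -> tuple[np.ndarray, float]:
        if isinstance(bandwidth, str):
            kde = gaussian_kde(sample, bw_method=bandwidth)
        else:
            if bandwidth <= 0:
                raise ValueError("bandwidth must be > 0")
            kde = gaussian_kde(
                sample, bw_method=bandwidth / sample.std(ddof=1)
            )
        return kde(grid), float(kde.factor * sample.std(ddof=1))

    h0, bw0 = _kde(ctrl)
    h1, bw1 = _kde(case)
    return DensityPair(z_grid=grid, h0=h0, h1=h1, bandwidth0=bw0, bandwidth1=bw1)


def conditional_probability(d: DensityPair) -> np.ndarray:
    """p_r(z) = h1/(h1 + h0): Pr(case | z) under equal class prevalence.

    Grid points where both densities vanish are NaN (undefined, not
    fabricated).
    """
    total = d.h0 + d.h1
    scale = max(float(total.max()), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > _EPS * scale, d.h1 / total, np.nan)
    return p


def or_curve(
    p_r: np.ndarray,
    z_grid: np.ndarray | None = None,
    delta_z: float = 0.10,
) -> ORCurve:
    """Continuous OR(z) from the conditional probability curve.

    p_1 is the grid interpolation of p_r at z + delta_z; points whose shifted
    argument leaves the grid, or where p_r/p_1 are numerically 0 or 1, are
    masked.
    """
    p_r = np.asarray(p_r, dtype=float)
    if z_grid is None:
        z_grid = np.linspace(0.0, 1.0, p_r.size)
    z_grid = np.asarray(z_grid, dtype=float)
    span = z_grid[-1] - z_grid[0]
    if not 0.0 < delta_z <= span:
        raise ValueError(f"delta_z must lie in (0, {span}]")
    valid = np.isfinite(p_r)
    p_1 = np.full_like(p_r, np.nan)
    inside = z_grid + delta_z <= z_grid[-1] + 1e-12
    if valid.any():
        p_1[inside] = np.interp(z_grid[inside] + delta_z, z_grid[valid], p_r[valid])
    # forbid interpolation across masked gaps: require the shifted point to
    # land in a finite region of the original curve
    nearest = np.searchsorted(z_grid, np.clip(z_grid + delta_z, z_grid[0], z_grid[-1]))
    nearest = np.clip(nearest, 0, p_r.size - 1)
    p_1[~valid[nearest]] = np.nan
    ok = (
        np.isfinite(p_r)
        & np.isfinite(p_1)
        & (p_r > _EPS)
        & (p_r < 1 - _EPS)
        & (p_1 > _EPS)
        & (p_1 < 1 - _EPS)
    )
    odds = np.full_like(p_r, np.nan)
    odds[ok] = (p_1[ok] / (1 - p_1[ok])) * ((1 - p_r[ok]) / p_r[ok])
    with np.errstate(invalid="ignore"):
        log_or = np.log(odds)
    return ORCurve(
        z_grid=z_grid,
        p_r=p_r,
        p_1=p_1,
        odds_ratio=odds,
        log_or=log_or,
        delta_z=delta_z,
        n_masked=int((~ok).sum()),
    )
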