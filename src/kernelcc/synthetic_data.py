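"""Simulated case-control data with a stochastic nonlinear separation boundary.

Each simulated subject carries two continuous risk factors, x1 ~ Uniform(0, 1)
and x2 = (x1 + z1)/10 with z1 ~ Normal(5, 1).  Disease status is induced by an
*activation* boundary

    g(x1) = (1/c0) * [ x1^2 / (x1^2 + (1 - x1)^2) + exp(-(a0*x1 - m0)^2) ],

a sigmoid built from a parabola plus a scalable, movable Gaussian bulge.  A
subject is a **case** when its x2 lies strictly above the boundary
(x2 > g(x1)); ties and points below are controls.  This orientation makes the
second risk factor positively associated with disease (positive fitted x2
log-odds-ratio, raw Az(x2) well above one half) while the first factor is
informative only through the *shape* of its case/control distributions, not
their ordering -- the configuration that makes the nonlinear-learning
comparison interesting.

A dataset is assembled case-control style: a large pool of subjects is drawn,
labelled by the boundary rule, and the first m cases and first m controls in
draw order are kept (controls stored first).

The boundary constants (a0, c0, m0) are free parameters.  The shipped
*reference configuration* was fixed once by :func:`calibrate`, matching three
raw-data statistics of the study design this generator emulates: marginal
Az(x2) = 0.772, marginal Az(x1) = 0.490, and pooled Pearson R(x1, x2) = 0.25
at m = 200.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneratorConfig",
    "RiskFactorVector",
    "CaseControlDataset",
    "CalibrationTargets",
    "REFERENCE_CONSTANTS",
    "activation",
    "assign_label",
    "generate_dataset",
    "pearson_r",
    "calibrate",
    "reference_config",
]

CONTROL, CASE = 0, 1

#: Boundary constants of the frozen reference configuration, found once with
#: :func:`calibrate` (see the shipped ``data/reference_config.yaml``).
REFERENCE_CONSTANTS = {"a0": 4.5, "c0": 1.6, "m0": 0.25}


@dataclass(frozen=True)
class RiskFactorVector:
    """One subject's exposure pair."""

    x1: float
    x2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x1) and np.isfinite(self.x2)):
            raise ValueError("risk factors must be finite")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the case-control simulator.

    a0, c0, m0 shape the activation boundary (c0 scales its amplitude, the
    bulge peaks at x1 = m0/a0 with width ~1/a0); m is the per-group sample
    size drawn from a pool of ``pool_size`` subjects.
    """

    a0: float
    c0: float
    m0: float
    m: int
    pool_size: int = 20_000
    x1_low: float = 0.0
    x1_high: float = 1.0
    z1_mean: float = 5.0
    z1_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c0 <= 0:
            raise ValueError("c0 must be > 0")
        if self.z1_sd <= 0:
            raise ValueError("z1_sd must be > 0")
        if not self.x1_low < self.x1_high:
            raise ValueError("x1_low must be < x1_high")
        if not 0 < self.m <= self.pool_size / 2:
            raise ValueError("m must satisfy 0 < m <= pool_size/2")


@dataclass(frozen=True)
class CaseControlDataset:
    """2m labelled subjects: m controls (stored first) then m cases."""

    x1: np.ndarray
    x2: np.ndarray
    status: np.ndarray  # 0 = control, 1 = case; controls first

    def __post_init__(self) -> None:
        x1 = np.asarray(self.x1, dtype=float)
        x2 = np.asarray(self.x2, dtype=float)
        status = np.asarray(self.status, dtype=np.int8)
        if not (x1.shape == x2.shape == status.shape) or x1.ndim != 1:
            raise ValueError("x1, x2 and status must be equal-length 1-d arrays")
        if not (np.isfinite(x1).all() and np.isfinite(x2).all()):
            raise ValueError("risk factors must be finite")
        if not np.isin(status, (CONTROL, CASE)).all():
            raise ValueError("status must be 0 (control) or 1 (case)")
        n_case = int((status == CASE).sum())
        if n_case * 2 != status.size:
            raise ValueError(
                f"dataset must be balanced: {n_case} cases vs "
                f"{status.size - n_case} controls"
            )
        object.__setattr__(self, "x1", x1)
        object.__setattr__(self, "x2", x2)
        object.__setattr__(self, "status", status)

    @property
    def m(self) -> int:
        return self.status.size // 2

    @property
    def n(self) -> int:
        return self.status.size

    @property
    def X(self) -> np.ndarray:
        """(2m, 2) matrix of risk-factor vectors."""
        return np.column_stack([self.x1, self.x2])

    @property
    def labels_pm(self) -> np.ndarray:
        """Labels encoded -1 (control) / +1 (case)."""
        return np.where(self.status == CASE, 1.0, -1.0)

    def subjects(self) -> Iterable[tuple[RiskFactorVector, int]]:
        for a, b, s in zip(self.x1, self.x2, self.status):
            yield RiskFactorVector(float(a), float(b)), int(s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(1, self.n + 1),
                "x1": self.x1,
                "x2": self.x2,
                "status": self.status.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CaseControlDataset":
        missing = {"x1", "x2", "status"} - set(df.columns)
        if missing:
            raise ValueError(f"missing column(s): {sorted(missing)}")
        return cls(
            x1=df["x1"].to_numpy(dtype=float),
            x2=df["x2"].to_numpy(dtype=float),
            status=df["status"].to_numpy(),
        )


def activation(x1, cfg: GeneratorConfig | None = None, *, a0=None, c0=None, m0=None):
    """Activation boundary g(x1); vectorized, total on the reals.

    The sigmoid term x1^2/(x1^2 + (1-x1)^2) is well defined everywhere since
    its denominator is >= 1/2 for real x1.
    """
    if cfg is not None:
        a0, c0, m0 = cfg.a0, cfg.c0, cfg.m0
    x1 = np.asarray(x1, dtype=float)
    sigmoid = x1**2 / (x1**2 + (1.0 - x1) ** 2)
    bulge = np.exp(-((a0 * x1 - m0) ** 2))
    out = (sigmoid + bulge) / c0
    return out if out.ndim else float(out)


def assign_label(x: RiskFactorVector | tuple, cfg: GeneratorConfig) -> int:
    """Disease status from the boundary rule: case iff x2 > g(x1).

    Ties (x2 == g(x1) exactly) are controls.  Cases sit strictly above the
    activation boundary, giving the second risk factor its positive marginal
    association with disease.
    """
    x1, x2 = (x.x1, x.x2) if isinstance(x, RiskFactorVector) else x
    return CASE if x2 > activation(x1, cfg) else CONTROL


def _draw_pool(cfg: GeneratorConfig, rng: np.random.Generator):
    x1 = rng.uniform(cfg.x1_low, cfg.x1_high, cfg.pool_size)
    z1 = rng.normal(cfg.z1_mean, cfg.z1_sd, cfg.pool_size)
    x2 = (x1 + z1) / 10.0
    return x1, x2


def generate_dataset(cfg: GeneratorConfig) -> CaseControlDataset:
    """Draw a pool, label it by the boundary rule, keep the first m per group.

    Raises a descriptive error when the pool contains fewer than m subjects of
    either class (a miscalibrated configuration).
    """
    rng = np.random.default_rng(cfg.seed)
    x1, x2 = _draw_pool(cfg, rng)
    is_case = x2 > activation(x1, cfg)
    case_idx = np.flatnonzero(is_case)[: cfg.m]
    ctrl_idx = np.flatnonzero(~is_case)[: cfg.m]
    if case_idx.size < cfg.m or ctrl_idx.size < cfg.m:
        frac = is_case.mean()
        raise ValueError(
            f"pool of {cfg.pool_size} yielded {case_idx.size} cases and "
            f"{ctrl_idx.size} controls (case fraction {frac:.4f}); need m={cfg.m} "
            "of each -- the generator configuration looks miscalibrated"
        )
    order = np.concatenate([ctrl_idx, case_idx])  # controls first
    status = np.concatenate(
        [np.zeros(cfg.m, dtype=np.int8), np.ones(cfg.m, dtype=np.int8)]
    )
    return CaseControlDataset(x1=x1[order], x2=x2[order], status=status)


def pearson_r(ds: CaseControlDataset) -> float:
    """Pearson correlation of x1 and x2 over the pooled 2m selected subjects."""
    if ds.n < 2:
        raise ValueError("need at least two subjects")
    if np.ptp(ds.x1) == 0 or np.ptp(ds.x2) == 0:
        raise ValueError("zero variance in a risk factor")
    return float(stats.pearsonr(ds.x1, ds.x2)[0])


@dataclass(frozen=True)
class CalibrationTargets:
    """Raw-data statistics the boundary constants are tuned against."""

    az_x2: float = 0.772
    az_x1: float = 0.490
    r: float = 0.25


def _balanced_stats(
    x1: np.ndarray, x2: np.ndarray, is_case: np.ndarray
) -> tuple[float, float, float] | None:
    """(Az_x1, Az_x2, R) on the balanced first-m-per-group selection of a pool."""
    from .roc_metrics import az  # local import: no module cycle at import time

    n_case = int(is_case.sum())
    m = min(n_case, is_case.size - n_case)
    if m < 2:
        return None
    ci = np.flatnonzero(is_case)[:m]
    ki = np.flatnonzero(~is_case)[:m]
    sel = np.concatenate([ki, ci])
    r = float(np.corrcoef(x1[sel], x2[sel])[0, 1])
    return az(x1[ci], x1[ki]), az(x2[ci], x2[ki]), r


def calibrate(
    grid: Sequence[tuple[float, float, float]],
    targets: CalibrationTargets = CalibrationTargets(),
    seed: int = 0,
    n_pool: int = 200_000,
    reps: int = 3,
    m: int | None = None,
) -> tuple[GeneratorConfig, pd.DataFrame]:
    """Pick boundary constants matching the calibration targets.

    For every (a0, c0, m0) triple the three statistics are estimated on
    ``reps`` large simulated pools (balanced selection of all available
    subjects, or the first ``m`` per group when given) and the triple
    minimizing

        |Az(x2) - target| + |Az(x1) - target| + |R - target|

    is returned as a :class:`GeneratorConfig` (with the default pool size and
    ``m`` = 200 unless overridden), together with the full record table.
    The same pools are reused across grid points (common random numbers).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty calibration grid")
    pools = []
    for child in np.random.SeedSequence(seed).spawn(reps):
        rng = np.random.default_rng(child)
        x1 = rng.uniform(0.0, 1.0, n_pool)
        z1 = rng.normal(5.0, 1.0, n_pool)
        pools.append((x1, (x1 + z1) / 10.0))
    rows = []
    for a0, c0, m0 in grid:
        acc = np.zeros(3)
        ok = 0
        for x1, x2 in pools:
            is_case = x2 > activation(x1, a0=a0, c0=c0, m0=m0)
            if m is not None:
                lim = min(int(is_case.sum()), int((~is_case).sum()), m)
                st = _balanced_stats(x1, x2, is_case) if lim >= 2 else None
            else:
                st = _balanced_stats(x1, x2, is_case)
            if st is None:
                continue
            acc += st
            ok += 1
        if ok == 0:
            rows.append((a0, c0, m0, np.nan, np.nan, np.nan, np.inf))
            continue
        az1, az2, r = acc / ok
        obj = abs(az2 - targets.az_x2) + abs(az1 - targets.az_x1) + abs(r - targets.r)
        rows.append((a0, c0, m0, az1, az2, r, obj))
    records = pd.DataFrame(
        rows, columns=["a0", "c0", "m0", "az_x1", "az_x2", "r", "objective"]
    )
    if not np.isfinite(records["objective"]).any():
        raise ValueError("no grid point produced both classes in the pools")
    best = records.loc[records["objective"].idxmin()]
    cfg = GeneratorConfig(
        a0=float(best["a0"]), c0=float(best["c0"]), m0=float(best["m0"]), m=200
    )
    return cfg, records


def reference_config(m: int = 200, seed: int = 0, **overrides) -> GeneratorConfig:
    """The frozen calibrated configuration (see :data:`REFERENCE_CONSTANTS`)."""
    return GeneratorConfig(m=m, seed=seed, **{**REFERENCE_CONSTANTS, **overrides})
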