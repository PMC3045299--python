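"""Sigma-weight selection and construction of the three kernel-perceptron variants.

Because the two sigma-weights drive the kernel geometry, perceptron training
is embedded inside a constrained grid search: for every (sigma1, sigma2)
combination the kernel matrix is built (both components active), the
perceptron is trained, and the training Az recorded, giving an experimental
set {sigma1_i, sigma2_i, Az_i}.  The pair at the maximum Az wins; ties break
toward the smallest sigma1, then sigma2 (smoother kernels), making the search
independent of grid ordering.  Each grid point draws from its own RNG
substream of the master seed, so results do not depend on execution order.

The selected pair is then reused -- without regenerating the sigma-weights --
to train the three variants: both risk factors (k), x1 only (k_x1) and
x2 only (k_x2), each fine-tuned by the incremental Az criterion.
"""

from __future__ import annotations

from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .kernel_map import BOTH, X1_ONLY, X2_ONLY, SigmaWeights, kernel_matrix
from .perceptron import (
    PerceptronConfig,
    PerceptronModel,
    fine_tune,
    train_perceptron,
)
from .synthetic_data import CaseControlDataset

__all__ = [
    "DEFAULT_SIGMA_VALUES",
    "default_sigma_grid",
    "sigma_grid_search",
    "fit_sl_variants",
    "VARIANT_MASKS",
]

DEFAULT_SIGMA_VALUES = (0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)

VARIANT_MASKS = {"k": BOTH, "k_x1": X1_ONLY, "k_x2": X2_ONLY}


def default_sigma_grid() -> list[SigmaWeights]:
    return [SigmaWeights(s1, s2) for s1, s2 in product(DEFAULT_SIGMA_VALUES, repeat=2)]


def sigma_grid_search(
    training: CaseControlDataset,
    grid: Sequence[SigmaWeights] | None = None,
    seed: int | np.random.SeedSequence = 0,
    cfg: PerceptronConfig = PerceptronConfig(),
    c_x: float = 1.0,
) -> tuple[SigmaWeights, pd.DataFrame]:
    """Constrained search over sigma pairs maximizing the training Az.

    Returns the winning pair and the full {sigma1, sigma2, Az} record table.
    """
    grid = default_sigma_grid() if grid is None else list(grid)
    if not grid:
        raise ValueError("empty sigma grid")
    if isinstance(seed, np.random.SeedSequence):
        base = int(seed.generate_state(1, dtype=np.uint32)[0])
    else:
        base = int(seed)
    # substream keyed by the sigma pair itself, not its grid position, so the
    # search result cannot depend on grid ordering or execution order
    substreams = [
        np.random.SeedSequence(
            base,
            spawn_key=(
                int(round(sw.sigma1 * 1e6)) & 0xFFFFFFFF,
                int(round(sw.sigma2 * 1e6)) & 0xFFFFFFFF,
            ),
        )
        for sw in grid
    ]
    y = training.labels_pm
    rows = []
    for sw, child in zip(grid, substreams):
        K = kernel_matrix(training, sw, BOTH, c_x)
        res = train_perceptron(
            K,
            y,
            az_target=1.0,
            max_epochs=cfg.search_epochs,
            learning_rate=cfg.learning_rate,
            rng=np.random.default_rng(child),
            bias=cfg.bias,
        )
        rows.append((sw.sigma1, sw.sigma2, res.az))
    records = pd.DataFrame(rows, columns=["sigma1", "sigma2", "az"])
    # max Az; ties toward the smoothest kernel (smallest sigma1, then sigma2)
    ranked = records.sort_values(
        by=["az", "sigma1", "sigma2"], ascending=[False, True, True]
    )
    best = ranked.iloc[0]
    return SigmaWeights(float(best["sigma1"]), float(best["sigma2"])), records


def _train_variant(
    training: CaseControlDataset,
    sw: SigmaWeights,
    mask,
    cfg: PerceptronConfig,
    c_x: float,
    rng: np.random.Generator,
) -> PerceptronModel:
    K = kernel_matrix(training, sw, mask, c_x)
    y = training.labels_pm
    res = train_perceptron(
        K,
        y,
        az_target=cfg.az_start,
        max_epochs=cfg.epochs_per_level,
        learning_rate=cfg.learning_rate,
        rng=rng,
        bias=cfg.bias,
    )
    res = fine_tune(
        K,
        y,
        res.alpha,
        az_step=cfg.az_step,
        epochs_per_level=cfg.epochs_per_level,
        learning_rate=cfg.learning_rate,
        rng=rng,
        bias=cfg.bias,
    )
    raw = K.values @ res.alpha + cfg.bias
    lo, hi = float(raw.min()), float(raw.max())
    if hi <= lo:
        raise ValueError("degenerate training scores: no spread to normalize")
    return PerceptronModel(
        alpha=res.alpha,
        sw=sw,
        mask=mask,
        c_x=c_x,
        train_X=training.X,
        train_labels=training.status.astype(int),
        norm_lo=lo,
        norm_hi=hi,
        train_az=res.az,
        bias=cfg.bias,
    )


def fit_sl_variants(
    training: CaseControlDataset,
    sw: SigmaWeights,
    seed: int | np.random.SeedSequence = 0,
    cfg: PerceptronConfig = PerceptronConfig(),
    c_x: float = 1.0,
) -> dict[str, PerceptronModel]:
    """Train and fine-tune the three variants k, k_x1, k_x2 with shared sigmas."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    out = {}
    for (name, mask), child in zip(VARIANT_MASKS.items(), ss.spawn(len(VARIANT_MASKS))):
        out[name] = _train_variant(
            training, sw, mask, cfg, c_x, np.random.default_rng(child)
        )
    return out
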