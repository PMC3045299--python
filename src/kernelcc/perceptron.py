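"""Rosenblatt perceptron on kernel rows, with bootstrap-ordered training.

The perceptron never sees the raw risk factors: its inputs are rows of the
training kernel matrix, so the learned weight vector w = sum_j alpha_j phi(xj)
exists only implicitly through the alpha expansion.  A prospective subject's
score is

    y_est = sum_j alpha_j * k(x, xj) + b,

with the bias b externally fixed at 1 and never updated (it positions the
separation boundary but not its orientation).  Training draws kernel rows at
random with replacement (bootstrap ordering); a misclassified draw updates
alpha by the classic rule alpha <- alpha + eta * y_i * K[i].  The training Az
is evaluated after every epoch (2m draws) and serves as the convergence
criterion; the alpha with the highest Az seen anywhere in the run is retained.

Fine-tuning raises the Az criterion in small increments, retraining from the
current weights, until a level fails to converge within its epoch budget --
the weights with the highest Az before non-convergence are kept.

Scores of the training set are linearly mapped onto [0, 1] (cases and
controls as a single unit); prospective scores reuse the training bounds and
are clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .kernel_map import ComponentMask, KernelMatrix, SigmaWeights, kernel_row
from .roc_metrics import az_from_labels
from .synthetic_data import CaseControlDataset

__all__ = [
    "PerceptronConfig",
    "TrainResult",
    "PerceptronModel",
    "ScoreSet",
    "train_perceptron",
    "fine_tune",
    "score",
    "normalize_scores",
]


@dataclass(frozen=True)
class PerceptronConfig:
    """Training hyper-parameters.

    The learning rate is 1 by convention (its scale is absorbed by alpha);
    ``az_start`` is the initial convergence criterion, raised in ``az_step``
    increments during fine-tuning with ``epochs_per_level`` epochs of budget
    at each level.
    """

    learning_rate: float = 1.0
    az_start: float = 0.75
    az_step: float = 0.005
    epochs_per_level: int = 500
    search_epochs: int = 150
    bias: float = 1.0


@dataclass
class TrainResult:
    alpha: np.ndarray
    az: float
    epochs: int
    converged: bool


@njit(cache=False)
def _run_epoch(K, y, alpha, b, eta, draws):  # pragma: no cover - jitted
    for t in range(draws.shape[0]):
        i = draws[t]
        s = b
        for j in range(K.shape[1]):
            s += K[i, j] * alpha[j]
        if y[i] * s <= 0.0:
            for j in range(K.shape[1]):
                alpha[j] += eta * y[i] * K[i, j]


def _as_matrix(K) -> np.ndarray:
    return K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)


def _training_az(K: np.ndarray, y: np.ndarray, alpha: np.ndarray, b: float) -> float:
    return az_from_labels(K @ alpha + b, (y > 0).astype(int))


def train_perceptron(
    K,
    labels_pm: np.ndarray,
    az_target: float,
    max_epochs: int = 200,
    learning_rate: float = 1.0,
    rng: np.random.Generator | int | None = None,
    bias: float = 1.0,
    alpha0: np.ndarray | None = None,
) -> TrainResult:
    """Bootstrap-ordered perceptron training with an Az stopping criterion.

    Draws one kernel row at a time with replacement; an epoch is 2m draws.
    After each epoch the training Az is evaluated; training stops when it
    reaches ``az_target`` (converged) or after ``max_epochs``.  The alpha
    with the highest Az seen is returned (best-seen bookkeeping), so the
    result never degrades with more epochs.
    """
    K = _as_matrix(K)
    y = np.asarray(labels_pm, dtype=float)
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValueError("labels must be encoded -1/+1")
    if len(set(np.unique(y))) < 2:
        raise ValueError("training labels contain a single class")
    if not 0.5 <= az_target:
        raise ValueError("az_target below chance is meaningless")
    rng = np.random.default_rng(rng)
    n = K.shape[0]
    alpha = np.zeros(n) if alpha0 is None else np.array(alpha0, dtype=float)
    best_alpha = alpha.copy()
    best_az = _training_az(K, y, alpha, bias)
    epochs = 0
    converged = best_az >= az_target
    while not converged and epochs < max_epochs:
        draws = rng.integers(0, n, n)
        _run_epoch(K, y, alpha, bias, learning_rate, draws)
        epochs += 1
        cur = _training_az(K, y, alpha, bias)
        if cur > best_az:
            best_az = cur
            best_alpha = alpha.copy()
        if cur >= az_target:
            converged = True
    return TrainResult(alpha=best_alpha, az=best_az, epochs=epochs, converged=converged)


def fine_tune(
    K,
    labels_pm: np.ndarray,
    alpha0: np.ndarray,
    az_step: float = 0.005,
    epochs_per_level: int = 200,
    learning_rate: float = 1.0,
    rng: np.random.Generator | int | None = None,
    bias: float = 1.0,
) -> TrainResult:
    """Incrementally raise the Az criterion until a level fails to converge.

    Each level retrains from the current weights with target best_az +
    ``az_step``; the weights with the highest training Az observed anywhere
    (including the failed final level) are returned, so the result is
    monotonically no worse than ``alpha0``.
    """
    K = _as_matrix(K)
    y = np.asarray(labels_pm, dtype=float)
    rng = np.random.default_rng(rng)
    best = TrainResult(
        alpha=np.array(alpha0, dtype=float),
        az=_training_az(K, y, np.asarray(alpha0, dtype=float), bias),
        epochs=0,
        converged=True,
    )
    while True:
        target = best.az + az_step
        if target > 1.0:
            break
        res = train_perceptron(
            K,
            y,
            az_target=target,
            max_epochs=epochs_per_level,
            learning_rate=learning_rate,
            rng=rng,
            bias=bias,
            alpha0=best.alpha,
        )
        if res.az > best.az:
            best = TrainResult(res.alpha, res.az, best.epochs + res.epochs, res.converged)
        if not res.converged:
            break
    return best


@dataclass
class ScoreSet:
    """Raw perceptron outputs with their [0, 1] normalization."""

    raw: np.ndarray
    z: np.ndarray
    labels: np.ndarray  # 0/1

    def case_scores(self) -> np.ndarray:
        return self.z[self.labels == 1]

    def control_scores(self) -> np.ndarray:
        return self.z[self.labels == 0]


def normalize_scores(
    raw: np.ndarray,
    labels01: np.ndarray,
    bounds: tuple[float, float] | None = None,
) -> ScoreSet:
    """Map raw scores linearly onto [0, 1], cases and controls as one unit.

    Without ``bounds`` the mapping is established from ``raw`` itself (its
    min maps to 0, its max to 1).  With ``bounds`` (the training min/max)
    prospective values outside the training range are clipped.  Ranks, and
    hence Az, are preserved.
    """
    raw = np.asarray(raw, dtype=float)
    if bounds is None:
        lo, hi = float(raw.min()), float(raw.max())
    else:
        lo, hi = bounds
    if hi <= lo:
        raise ValueError("constant scores: no spread to normalize")
    z = np.clip((raw - lo) / (hi - lo), 0.0, 1.0)
    return ScoreSet(raw=raw, z=z, labels=np.asarray(labels01))


@dataclass
class PerceptronModel:
    """A trained kernel-perceptron variant.

    The kernel method embeds its whole training set: scoring a prospective
    subject compares it against all 2m stored training vectors.
    """

    alpha: np.ndarray
    sw: SigmaWeights
    mask: ComponentMask
    c_x: float
    train_X: np.ndarray
    train_labels: np.ndarray  # 0/1
    norm_lo: float
    norm_hi: float
    train_az: float
    bias: float = 1.0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.train_X = np.asarray(self.train_X, dtype=float)
        self.train_labels = np.asarray(self.train_labels)
        if self.alpha.size != self.train_X.shape[0]:
            raise ValueError("alpha length must equal the training-set size")

    def decision_scores(self, X) -> np.ndarray:
        """Raw scores y_est = sum_j alpha_j k(x, xj) + b."""
        X = X.X if isinstance(X, CaseControlDataset) else np.atleast_2d(
            np.asarray(X, dtype=float)
        )
        rows = kernel_row(X, self.train_X, self.sw, self.mask, self.c_x)
        return rows @ self.alpha + self.bias

    def z_scores(self, X) -> np.ndarray:
        """Normalized scores using the training [0, 1] mapping (clipped)."""
        raw = self.decision_scores(X)
        return np.clip((raw - self.norm_lo) / (self.norm_hi - self.norm_lo), 0.0, 1.0)

    def score_dataset(self, ds: CaseControlDataset) -> ScoreSet:
        raw = self.decision_scores(ds)
        return ScoreSet(
            raw=raw,
            z=np.clip((raw - self.norm_lo) / (self.norm_hi - self.norm_lo), 0.0, 1.0),
            labels=ds.status.astype(int),
        )


def score(x, model: PerceptronModel) -> float | np.ndarray:
    """Raw perceptron output for prospective subject(s)."""
    if model.alpha.size == 0:
        raise ValueError("model has no trained weights")
    single = hasattr(x, "x1") or np.ndim(x) == 1
    out = model.decision_scores(
        np.atleast_2d([x.x1, x.x2] if hasattr(x, "x1") else x)
    )
    return float(out[0]) if single else out
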