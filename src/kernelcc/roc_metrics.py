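"""ROC-based model evaluation.

The area under the empirical ROC curve (Az) is the workhorse statistic of the
package: it is computed with the Mann-Whitney estimator (probability that a
randomly chosen case outscores a randomly chosen control, ties counted with
half weight), which equals the trapezoidal area under the empirical ROC curve.
Because Az also equals the mean sensitivity of the ROC function, each model's
operating point is set where sensitivity matches Az (the "mean-sensitivity"
rule), which fixes the reported false-positive fraction.

Evaluation protocols:

* :func:`bootstrap_training_eval` -- repetitions of stratified bootstrap
  resamples of the training subjects, scored by the frozen models.
* :func:`validation_eval` -- independent simulated validation datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .synthetic_data import CaseControlDataset

__all__ = [
    "OperatingPoint",
    "EvalSummary",
    "az",
    "az_from_labels",
    "operating_point_mean_sensitivity",
    "bootstrap_training_eval",
    "validation_eval",
    "raw_variable_az",
]


@dataclass(frozen=True)
class OperatingPoint:
    """A point on the empirical ROC curve.

    Scores at or above ``threshold`` are classified as cases.
    """

    threshold: float
    sensitivity: float
    fp: float

    def __post_init__(self) -> None:
        for name in ("sensitivity", "fp"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class EvalSummary:
    """Mean Az, spread and standard error over replicates or datasets."""

    az_mean: float
    sd: float
    se: float
    n_replicates: int


def az(case_scores: np.ndarray, control_scores: np.ndarray) -> float:
    """Area under the empirical ROC curve (Mann-Whitney estimator).

    Counts case/control score pairs with the case scoring higher; ties get
    half weight.  Equals the trapezoidal area under the empirical ROC curve.

    Raises
    ------
    ValueError
        If either class is empty.
    """
    case_scores = np.asarray(case_scores, dtype=float)
    control_scores = np.asarray(control_scores, dtype=float)
    n1, n0 = case_scores.size, control_scores.size
    if n1 == 0 or n0 == 0:
        raise ValueError("Az requires at least one score in each class")
    ranks = rankdata(np.concatenate([case_scores, control_scores]))
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def az_from_labels(scores: np.ndarray, labels01: np.ndarray) -> float:
    """Az from pooled scores with 0/1 labels (1 = case)."""
    scores = np.asarray(scores, dtype=float)
    labels01 = np.asarray(labels01)
    mask = labels01 == 1
    return az(scores[mask], scores[~mask])


def operating_point_mean_sensitivity(
    scores: np.ndarray, labels01: np.ndarray
) -> OperatingPoint:
    """Operating point whose sensitivity equals the model's Az.

    Az equals the ROC's mean sensitivity, so it doubles as a user-free choice
    of sensitivity.  Finite samples cannot hit Az exactly, so the *largest*
    threshold achieving sensitivity >= Az is used (conservative on the
    false-positive fraction).
    """
    scores = np.asarray(scores, dtype=float)
    labels01 = np.asarray(labels01)
    case = scores[labels01 == 1]
    ctrl = scores[labels01 == 0]
    target = az(case, ctrl)
    # Candidate thresholds are the observed scores; sensitivity(t) = frac of
    # cases >= t is nonincreasing in t, so scan case scores from the top.
    candidates = np.unique(scores)[::-1]
    for t in candidates:
        sens = float(np.mean(case >= t))
        if sens >= target:
            return OperatingPoint(
                threshold=float(t),
                sensitivity=sens,
                fp=float(np.mean(ctrl >= t)),
            )
    # Unreachable: the smallest score always yields sensitivity 1 >= Az.
    raise AssertionError("no threshold reached the Az sensitivity")


ScoreFn = Callable[[CaseControlDataset], np.ndarray]


def bootstrap_training_eval(
    models: Mapping[str, ScoreFn],
    training: CaseControlDataset,
    reps: int = 10,
    B: int = 150,
    rng: np.random.Generator | int | None = None,
) -> dict[str, EvalSummary]:
    """Bootstrap evaluation of frozen models on the training subjects.

    For each of ``reps`` repetitions, ``B`` stratified bootstrap resamples
    (m cases and m controls drawn with replacement, so Az is defined in every
    resample) are scored by every model.  Per repetition the mean and sd of
    the B Az values are recorded; the summaries average those over
    repetitions, with SE = mean(sd)/sqrt(reps).
    """
    if B < 2:
        raise ValueError("need at least B=2 bootstrap resamples")
    rng = np.random.default_rng(rng)
    m = training.m
    case_idx = np.flatnonzero(training.status == 1)
    ctrl_idx = np.flatnonzero(training.status == 0)
    # Score each model once; resamples only re-index the score vectors.
    score_cache = {name: np.asarray(fn(training), dtype=float) for name, fn in models.items()}
    rep_mean = {name: [] for name in models}
    rep_sd = {name: [] for name in models}
    for _ in range(reps):
        boot_case = rng.choice(case_idx, size=(B, m), replace=True)
        boot_ctrl = rng.choice(ctrl_idx, size=(B, m), replace=True)
        for name, s in score_cache.items():
            vals = [az(s[boot_case[b]], s[boot_ctrl[b]]) for b in range(B)]
            rep_mean[name].append(np.mean(vals))
            rep_sd[name].append(np.std(vals, ddof=1))
    out = {}
    for name in models:
        sd = float(np.mean(rep_sd[name]))
        out[name] = EvalSummary(
            az_mean=float(np.mean(rep_mean[name])),
            sd=sd,
            se=float(sd / np.sqrt(reps)),
            n_replicates=reps,
        )
    return out


def validation_eval(
    models: Mapping[str, ScoreFn],
    datasets: Sequence[CaseControlDataset],
) -> dict[str, EvalSummary]:
    """Az of each frozen model on each independent validation dataset.

    Reports the per-model mean, sd and SE = sd/sqrt(#datasets).
    """
    if len(datasets) < 2:
        raise ValueError("need at least two validation datasets")
    out = {}
    for name, fn in models.items():
        vals = [az_from_labels(fn(ds), ds.status) for ds in datasets]
        sd = float(np.std(vals, ddof=1))
        out[name] = EvalSummary(
            az_mean=float(np.mean(vals)),
            sd=sd,
            se=float(sd / np.sqrt(len(datasets))),
            n_replicates=len(datasets),
        )
    return out


def raw_variable_az(ds: CaseControlDataset, which: str) -> float:
    """Az of a raw risk factor (``"x1"`` or ``"x2"``), without any model."""
    if which not in ("x1", "x2"):
        raise ValueError("which must be 'x1' or 'x2'")
    col = ds.x1 if which == "x1" else ds.x2
    return az(col[ds.status == 1], col[ds.status == 0])
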