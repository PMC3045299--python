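"""Logistic regression comparators and their closed-form separation boundaries.

Two maximum-likelihood logistic models are fitted to the case-control data:

    logit Pr(case | x) = beta0 + beta1*x1 + beta2*x2 [+ beta3*x1*x2]

the *standard* model (beta3 = 0) and the *interaction* model.  Coefficients
are log odds ratios per unit increase.  Setting a probability threshold p_t
fixes the separation boundary in the (x1, x2) plane: with
tau0 = ln((1 - p_t)/p_t) the standard boundary is the straight line

    x2(x1) = -(tau0 + beta0)/beta2 - (beta1/beta2) * x1

and the interaction boundary the rational curve

    x2(x1) = -(tau0 + beta0 + beta1*x1) / (beta2 + beta3*x1),

undefined at the pole x1 = -beta2/beta3.  Every boundary point satisfies
Pr(case | x) = p_t exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .synthetic_data import CaseControlDataset

__all__ = [
    "LRModel",
    "BoundaryCurve",
    "LRFitError",
    "fit_lr",
    "lr_prob",
    "boundary_standard",
    "boundary_interaction",
]


class LRFitError(RuntimeError):
    """Raised when the maximum-likelihood fit fails (e.g. complete separation)."""


@dataclass
class LRModel:
    """Fitted log-odds-ratio coefficients per unit increase."""

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    interaction: bool
    bse: np.ndarray | None = None  # standard errors, fit order (b0, b1, b2[, b3])

    def __post_init__(self) -> None:
        betas = (self.beta0, self.beta1, self.beta2, self.beta3)
        if not np.all(np.isfinite(betas)):
            raise ValueError("coefficients must be finite")
        if not self.interaction and self.beta3 != 0.0:
            raise ValueError("beta3 must be 0 in the standard model")

    @property
    def params(self) -> np.ndarray:
        p = [self.beta0, self.beta1, self.beta2]
        return np.array(p + [self.beta3] if self.interaction else p)

    def linear_predictor(self, X) -> np.ndarray:
        X = X.X if isinstance(X, CaseControlDataset) else np.atleast_2d(
            np.asarray(X, dtype=float)
        )
        eta = self.beta0 + self.beta1 * X[:, 0] + self.beta2 * X[:, 1]
        if self.interaction:
            eta = eta + self.beta3 * X[:, 0] * X[:, 1]
        return eta

    def predict_proba(self, X) -> np.ndarray:
        """Pr(case | x), the logistic of the linear predictor."""
        eta = self.linear_predictor(X)
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-eta))


def _design(ds: CaseControlDataset, interaction: bool) -> np.ndarray:
    cols = [ds.x1, ds.x2]
    if interaction:
        cols.append(ds.x1 * ds.x2)
    return sm.add_constant(np.column_stack(cols))


def fit_lr(ds: CaseControlDataset, interaction: bool = False) -> LRModel:
    """Maximum-likelihood logistic fit (Newton, tol 1e-8, <= 100 iterations).

    Complete separation or non-convergence raises :class:`LRFitError` naming
    the condition rather than returning silently clipped coefficients.
    """
    y = ds.status.astype(float)
    if y.min() == y.max():
        raise LRFitError("both classes must be present to fit")
    try:
        res = sm.Logit(y, _design(ds, interaction)).fit(
            method="newton", maxiter=100, tol=1e-8, disp=0
        )
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise LRFitError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise LRFitError("logistic fit did not converge (possible separation)")
    p = res.params
    return LRModel(
        beta0=float(p[0]),
        beta1=float(p[1]),
        beta2=float(p[2]),
        beta3=float(p[3]) if interaction else 0.0,
        interaction=interaction,
        bse=np.asarray(res.bse),
    )


def lr_prob(x, model: LRModel) -> float | np.ndarray:
    """Pr(case | x) for one risk vector or an array of them."""
    single = hasattr(x, "x1") or np.ndim(x) == 1
    arr = np.atleast_2d([x.x1, x.x2] if hasattr(x, "x1") else x)
    p = model.predict_proba(arr)
    return float(p[0]) if single else p


def _tau0(p_t: float) -> float:
    if not 0.0 < p_t < 1.0:
        raise ValueError("p_t must lie strictly between 0 and 1")
    return float(np.log((1.0 - p_t) / p_t))


@dataclass
class BoundaryCurve:
    """Level set Pr(case | x) = p_t expressed as x2 as a function of x1."""

    p_t: float
    tau0: float
    model: LRModel

    def x2_of(self, x1) -> float | np.ndarray:
        x1 = np.asarray(x1, dtype=float)
        m = self.model
        denom = m.beta2 + m.beta3 * x1
        if np.any(np.abs(denom) < 1e-12):
            raise ZeroDivisionError(
                "boundary undefined at the pole x1 = -beta2/beta3"
            )
        out = -(self.tau0 + m.beta0 + m.beta1 * x1) / denom
        return float(out) if out.ndim == 0 else out

    @property
    def pole(self) -> float | None:
        m = self.model
        return -m.beta2 / m.beta3 if m.beta3 != 0.0 else None

    def sample(self, x1_lo: float, x1_hi: float, n: int = 200) -> np.ndarray:
        """(n, 2) array of boundary points over an x1 range (pole excluded)."""
        xs = np.linspace(x1_lo, x1_hi, n)
        if self.pole is not None:
            xs = xs[np.abs(self.model.beta2 + self.model.beta3 * xs) >= 1e-9]
        return np.column_stack([xs, self.x2_of(xs)])


def boundary_standard(model: LRModel, p_t: float) -> BoundaryCurve:
    """Linear separation boundary of the standard model at threshold p_t."""
    if model.interaction:
        raise ValueError("use boundary_interaction for the interaction model")
    if model.beta2 == 0.0:
        raise ValueError("beta2 = 0: boundary not expressible as x2(x1)")
    return BoundaryCurve(p_t=p_t, tau0=_tau0(p_t), model=model)


def boundary_interaction(model: LRModel, p_t: float) -> BoundaryCurve:
    """Rational separation boundary of the interaction model at threshold p_t.

    With beta3 = 0 this reduces exactly to the standard linear boundary.
    """
    if not model.interaction:
        raise ValueError("model was fitted without the interaction term")
    return BoundaryCurve(p_t=p_t, tau0=_tau0(p_t), model=model)
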