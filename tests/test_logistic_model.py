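import numpy as np
import pytest

from kernelcc import (
    CaseControlDataset,
    LRFitError,
    LRModel,
    boundary_interaction,
    boundary_standard,
    fit_lr,
    generate_dataset,
    lr_prob,
    reference_config,
)


def _balanced_from_logistic(beta, n, rng, interaction=False):
    """Balanced case-control sample drawn from a known logistic law."""
    x = rng.uniform(0, 1, size=(4 * n, 2))
    eta = beta[0] + beta[1] * x[:, 0] + beta[2] * x[:, 1]
    if interaction:
        eta = eta + beta[3] * x[:, 0] * x[:, 1]
    y = (rng.uniform(size=4 * n) < 1 / (1 + np.exp(-eta))).astype(int)
    m = min((y == 1).sum(), (y == 0).sum(), n)
    ctrl = np.flatnonzero(y == 0)[:m]
    case = np.flatnonzero(y == 1)[:m]
    idx = np.r_[ctrl, case]
    return CaseControlDataset(
        x1=x[idx, 0], x2=x[idx, 1], status=np.r_[np.zeros(m, int), np.ones(m, int)]
    )


class TestFitLR:
    def test_parameter_recovery_within_three_se(self, rng):
        # balanced retention shifts only the intercept; slopes are preserved
        beta = (-1.0, 2.0, -3.0)
        ds = _balanced_from_logistic(beta, 2500, rng)
        model = fit_lr(ds)
        for est, true, se in zip(
            (model.beta1, model.beta2), beta[1:], model.bse[1:]
        ):
            assert abs(est - true) < 3 * se

    def test_null_simulation_slopes_near_zero(self, rng):
        beta = (0.0, 0.0, 0.0)
        ds = _balanced_from_logistic(beta, 2500, rng)
        model = fit_lr(ds, interaction=True)
        for est, se in zip((model.beta1, model.beta2, model.beta3), model.bse[1:]):
            assert abs(est) < 3 * se

    def test_reference_sign_pattern(self):
        # shielding x1, strongly protective... positive x2 association: the
        # large-sample coefficient signs of the simulated design
        ds = generate_dataset(reference_config(m=3000, pool_size=40_000, seed=3))
        model = fit_lr(ds)
        assert model.beta1 < 0 < model.beta2

    def test_interaction_flag_controls_beta3(self, small_dataset):
        std = fit_lr(small_dataset, interaction=False)
        inter = fit_lr(small_dataset, interaction=True)
        assert std.beta3 == 0.0 and not std.interaction
        assert inter.interaction

    def test_complete_separation_raises(self):
        x2 = np.r_[np.linspace(0.0, 0.4, 20), np.linspace(0.6, 1.0, 20)]
        ds = CaseControlDataset(
            x1=np.linspace(0, 1, 40),
            x2=x2,
            status=np.r_[np.zeros(20, int), np.ones(20, int)],
        )
        with pytest.raises(LRFitError):
            fit_lr(ds)

    def test_single_class_rejected(self):
        ds_args = dict(x1=np.arange(4.0), x2=np.arange(4.0))
        with pytest.raises(Exception):
            fit_lr(CaseControlDataset(status=np.zeros(4, int), **ds_args))


class TestLRProb:
    def test_all_zero_betas_give_half(self):
        m = LRModel(0, 0, 0, 0, interaction=False)
        assert lr_prob((0.3, 0.8), m) == pytest.approx(0.5)

    def test_linear_predictor_ln3_gives_three_quarters(self):
        m = LRModel(np.log(3.0), 0, 0, 0, interaction=False)
        assert lr_prob((0.0, 0.0), m) == pytest.approx(0.75)

    def test_matches_hand_rolled_logistic(self, rng):
        m = LRModel(-1.2, 0.7, 2.5, -0.9, interaction=True)
        for x1, x2 in rng.uniform(-2, 2, size=(100, 2)):
            eta = -1.2 + 0.7 * x1 + 2.5 * x2 - 0.9 * x1 * x2
            assert lr_prob((x1, x2), m) == pytest.approx(
                1 / (1 + np.exp(-eta)), rel=1e-12
            )


class TestBoundaries:
    MODEL = LRModel(-7.0, -1.7, 14.0, 0.0, interaction=False)
    MODEL_INT = LRModel(-13.7, 9.7, 26.0, -20.1, interaction=True)

    def test_standard_halfprob_threshold(self):
        bc = boundary_standard(self.MODEL, p_t=0.5)
        assert bc.tau0 == pytest.approx(0.0)
        assert bc.x2_of(0.0) == pytest.approx(7.0 / 14.0)

    @pytest.mark.parametrize("p_t", [0.2, 0.42, 0.5, 0.8])
    def test_boundary_points_sit_on_probability_level_set(self, p_t):
        bc = boundary_standard(self.MODEL, p_t)
        for x1 in np.linspace(-1, 2, 13):
            assert lr_prob((x1, bc.x2_of(x1)), self.MODEL) == pytest.approx(
                p_t, abs=1e-10
            )
        bci = boundary_interaction(self.MODEL_INT, p_t)
        for x1 in np.linspace(0, 1, 13):
            assert lr_prob((x1, bci.x2_of(x1)), self.MODEL_INT) == pytest.approx(
                p_t, abs=1e-10
            )

    def test_slope_independent_of_threshold(self):
        slopes = []
        for p_t in (0.3, 0.5, 0.7):
            bc = boundary_standard(self.MODEL, p_t)
            slopes.append(bc.x2_of(1.0) - bc.x2_of(0.0))
        assert np.allclose(slopes, -self.MODEL.beta1 / self.MODEL.beta2)
        assert np.allclose(slopes, slopes[0])

    def test_interaction_reduces_to_standard_when_beta3_zero(self):
        flat = LRModel(-7.0, -1.7, 14.0, 0.0, interaction=True)
        bc_std = boundary_standard(self.MODEL, 0.42)
        bc_int = boundary_interaction(flat, 0.42)
        xs = np.linspace(-1, 2, 20)
        assert np.allclose(bc_int.x2_of(xs), bc_std.x2_of(xs), atol=1e-12)

    def test_pole_is_excluded(self):
        bci = boundary_interaction(self.MODEL_INT, 0.5)
        pole = -self.MODEL_INT.beta2 / self.MODEL_INT.beta3
        with pytest.raises(ZeroDivisionError):
            bci.x2_of(pole)
        pts = bci.sample(pole - 0.1, pole + 0.1, n=50)
        assert np.isfinite(pts).all()

    def test_beta2_zero_not_expressible(self):
        degenerate = LRModel(-1.0, 2.0, 0.0, 0.0, interaction=False)
        with pytest.raises(ValueError, match="beta2"):
            boundary_standard(degenerate, 0.5)

    def test_agrees_with_bisection_level_set(self):
        # independent oracle: find x2 with lr_prob = p_t by bisection
        from scipy.optimize import brentq

        p_t = 0.37
        bc = boundary_standard(self.MODEL, p_t)
        for x1 in (0.0, 0.4, 0.9):
            root = brentq(
                lambda x2: lr_prob((x1, x2), self.MODEL) - p_t, -10.0, 10.0, xtol=1e-12
            )
            assert bc.x2_of(x1) == pytest.approx(root, abs=1e-9)

    def test_points_above_boundary_exceed_threshold(self):
        bc = boundary_standard(self.MODEL, 0.42)
        for x1 in np.linspace(0, 1, 7):
            assert lr_prob((x1, bc.x2_of(x1) + 0.01), self.MODEL) > 0.42
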