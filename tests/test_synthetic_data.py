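import numpy as np
import pytest

from kernelcc import (
    GeneratorConfig,
    RiskFactorVector,
    activation,
    assign_label,
    calibrate,
    generate_dataset,
    pearson_r,
    reference_config,
)
from kernelcc.synthetic_data import CASE, CONTROL, CalibrationTargets


@pytest.fixture()
def cfg() -> GeneratorConfig:
    return GeneratorConfig(a0=4.5, c0=1.6, m0=0.25, m=100, seed=3)


class TestActivation:
    def test_sigmoid_term_is_half_at_midpoint(self, cfg):
        # parabola-built sigmoid is symmetric about x1 = 1/2
        expected = (0.5 + np.exp(-((0.5 * cfg.a0 - cfg.m0) ** 2))) / cfg.c0
        assert activation(0.5, cfg) == pytest.approx(expected, abs=1e-15)

    def test_sigmoid_term_vanishes_at_zero(self, cfg):
        assert activation(0.0, cfg) == pytest.approx(np.exp(-cfg.m0**2) / cfg.c0)

    def test_bulge_peaks_at_its_center(self, cfg):
        x_peak = cfg.m0 / cfg.a0
        xs = np.linspace(0, 1, 2001)
        sigmoid = xs**2 / (xs**2 + (1 - xs) ** 2)
        bulge_height = activation(xs, cfg) - sigmoid / cfg.c0
        assert np.argmax(bulge_height) == pytest.approx(x_peak * 2000, abs=1)
        assert bulge_height.max() == pytest.approx(1 / cfg.c0, rel=1e-6)

    def test_total_on_reals(self, cfg):
        xs = np.linspace(-50, 50, 999)
        assert np.isfinite(activation(xs, cfg)).all()


class TestAssignLabel:
    def test_case_iff_above_boundary(self, cfg):
        # cases sit strictly above g(x1): the orientation that gives x2 its
        # positive association with disease
        rng = np.random.default_rng(0)
        for x1 in rng.uniform(0, 1, 50):
            g = activation(x1, cfg)
            assert assign_label(RiskFactorVector(x1, g + 1e-9), cfg) == CASE
            assert assign_label(RiskFactorVector(x1, g - 1e-9), cfg) == CONTROL

    def test_far_above_global_max_is_always_case(self, cfg):
        # g <= 2/c0 everywhere, so any x2 beyond that bound is a case
        for x1 in np.linspace(-2, 3, 21):
            assert assign_label((x1, 2 / cfg.c0 + 0.01), cfg) == CASE

    def test_exact_tie_is_control(self, cfg):
        g = activation(0.3, cfg)
        assert assign_label(RiskFactorVector(0.3, g), cfg) == CONTROL


class TestGenerateDataset:
    def test_exact_class_balance_and_order(self, cfg):
        ds = generate_dataset(cfg)
        assert ds.m == cfg.m
        assert (ds.status[: cfg.m] == CONTROL).all()
        assert (ds.status[cfg.m :] == CASE).all()

    def test_bit_identical_under_same_seed(self, cfg):
        a, b = generate_dataset(cfg), generate_dataset(cfg)
        assert np.array_equal(a.x1, b.x1) and np.array_equal(a.x2, b.x2)
        c = generate_dataset(GeneratorConfig(**{**cfg.__dict__, "seed": 4}))
        assert not np.array_equal(a.x1, c.x1)

    def test_labels_match_boundary_rule(self, cfg):
        ds = generate_dataset(cfg)
        expected = (ds.x2 > activation(ds.x1, cfg)).astype(int)
        assert np.array_equal(ds.status, expected)

    def test_pool_exhaustion_raises(self):
        # huge c0 flattens g to ~0, so essentially every draw is a case and
        # controls run out
        bad = GeneratorConfig(a0=4.5, c0=1e9, m0=0.25, m=100, pool_size=2000, seed=0)
        with pytest.raises(ValueError, match="miscalibrated"):
            generate_dataset(bad)

    def test_case_fraction_increases_with_c0(self):
        # weakening the boundary (larger c0) can only move subjects above it
        fracs = []
        for c0 in (1.0, 1.6, 2.5, 4.0):
            cfg = GeneratorConfig(a0=4.5, c0=c0, m0=0.25, m=10, pool_size=20000, seed=11)
            rng = np.random.default_rng(cfg.seed)
            x1 = rng.uniform(0, 1, cfg.pool_size)
            x2 = (x1 + rng.normal(5, 1, cfg.pool_size)) / 10
            fracs.append(np.mean(x2 > activation(x1, cfg)))
        assert np.all(np.diff(fracs) > 0)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(a0=1, c0=0, m0=0, m=10)
        with pytest.raises(ValueError):
            GeneratorConfig(a0=1, c0=1, m0=0, m=10, z1_sd=0)
        with pytest.raises(ValueError):
            GeneratorConfig(a0=1, c0=1, m0=0, m=10, x1_low=1, x1_high=0)
        with pytest.raises(ValueError):
            GeneratorConfig(a0=1, c0=1, m0=0, m=10_001, pool_size=20_000)


class TestPearsonR:
    def test_exact_affine_relation_gives_one(self, cfg):
        ds = generate_dataset(cfg)
        affine = type(ds)(x1=ds.x1, x2=2.0 * ds.x1 + 1.0, status=ds.status)
        assert pearson_r(affine) == pytest.approx(1.0)

    def test_independent_components_near_zero(self):
        rng = np.random.default_rng(5)
        n = 4000
        from kernelcc import CaseControlDataset

        ds = CaseControlDataset(
            x1=rng.normal(size=n),
            x2=rng.normal(size=n),
            status=np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)],
        )
        assert abs(pearson_r(ds)) < 0.05

    def test_zero_variance_errors(self, cfg):
        ds = generate_dataset(cfg)
        flat = type(ds)(x1=ds.x1, x2=np.full(ds.n, 0.5), status=ds.status)
        with pytest.raises(ValueError, match="variance"):
            pearson_r(flat)


class TestCalibrate:
    def test_single_point_grid_returned_with_objective(self):
        cfg, rec = calibrate([(4.5, 1.6, 0.25)], seed=0, n_pool=20_000, reps=1)
        assert (cfg.a0, cfg.c0, cfg.m0) == (4.5, 1.6, 0.25)
        assert len(rec) == 1 and rec["objective"].iloc[0] >= 0

    def test_objective_zero_only_at_exact_match(self):
        _, rec = calibrate([(4.5, 1.6, 0.25)], seed=0, n_pool=20_000, reps=1)
        row = rec.iloc[0]
        t = CalibrationTargets(
            az_x2=row["az_x2"], az_x1=row["az_x1"], r=row["r"]
        )
        _, rec2 = calibrate([(4.5, 1.6, 0.25)], targets=t, seed=0, n_pool=20_000, reps=1)
        assert rec2["objective"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError, match="empty"):
            calibrate([], seed=0)

    def test_reference_config_matches_frozen_constants(self):
        cfg = reference_config()
        assert (cfg.a0, cfg.c0, cfg.m0) == (4.5, 1.6, 0.25)
        assert cfg.m == 200 and cfg.pool_size == 20_000
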