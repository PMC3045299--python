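"""End-to-end study driver: simulate, train, evaluate, transform, export.

One seeded run reproduces the whole comparison: a single training dataset
fixes every model parameter (sigma-weight grid search with embedded
perceptron training, fine-tuned kernel-perceptron variants k / k_x1 / k_x2,
standard and interaction logistic fits); the frozen models are then assessed
on bootstrap resamples of the training subjects and on independent validation
datasets; odds-ratio curves and separation-boundary samples are exported for
one validation dataset.

Everything stochastic derives from one master seed through named substreams,
so stages can be rerun independently yet reproducibly and a rerun with the
same seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as kio
from .logistic_model import boundary_interaction, boundary_standard, fit_lr
from .model_selection import (
    DEFAULT_SIGMA_VALUES,
    fit_sl_variants,
    sigma_grid_search,
)
from .kernel_map import SigmaWeights
from .odds_transform import conditional_probability, estimate_densities, or_curve
from .perceptron import PerceptronConfig
from .roc_metrics import (
    bootstrap_training_eval,
    operating_point_mean_sensitivity,
    raw_variable_az,
    validation_eval,
)
from .synthetic_data import CaseControlDataset, GeneratorConfig, generate_dataset

__all__ = ["RunConfig", "run_full_study", "spawn_seeds", "derive_seed"]

MODEL_ORDER = ("LR", "LR_int", "k", "k_x1", "k_x2")


@dataclass(frozen=True)
class RunConfig:
    """Master configuration of a full study run."""

    generator: GeneratorConfig
    sigma_values: tuple = DEFAULT_SIGMA_VALUES
    perceptron: PerceptronConfig = field(default_factory=PerceptronConfig)
    reps: int = 10
    B: int = 150
    n_validation: int = 10
    kde_bandwidth: str | float = "silverman"
    delta_z: float = 0.10
    c_x: float = 1.0
    seed: int = 0


def derive_seed(ss: np.random.SeedSequence) -> int:
    """A 31-bit integer seed from a substream (safe for any consumer)."""
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def spawn_seeds(master: int, n_validation: int):
    """Named substreams of the master seed, in a fixed documented order."""
    ss_train, ss_val, ss_sigma, ss_variants, ss_boot = np.random.SeedSequence(
        master
    ).spawn(5)
    val_children = ss_val.spawn(n_validation)
    return {
        "train": ss_train,
        "validation": val_children,
        "sigma_search": ss_sigma,
        "variants": ss_variants,
        "bootstrap": ss_boot,
    }


def _score_fns(sl_models: dict, lr, lr_int) -> dict:
    fns = {
        "LR": lr.predict_proba,
        "LR_int": lr_int.predict_proba,
    }
    for name, model in sl_models.items():
        fns[name] = model.z_scores
    return {name: fns[name] for name in MODEL_ORDER}


def _summary_rows(summaries: dict) -> list[dict]:
    return [
        {
            "method": name,
            "az": round(s.az_mean, 6),
            "sd": round(s.sd, 6),
            "se": round(s.se, 6),
        }
        for name, s in summaries.items()
    ]


def run_full_study(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full analysis sequence; return (and optionally write) the report."""
    seeds = spawn_seeds(cfg.seed, cfg.n_validation)
    stage = "simulate"
    try:
        train_cfg = dataclasses.replace(cfg.generator, seed=derive_seed(seeds["train"]))
        training = generate_dataset(train_cfg)
        validation = [
            generate_dataset(dataclasses.replace(cfg.generator, seed=derive_seed(c)))
            for c in seeds["validation"]
        ]

        stage = "sigma_search"
        grid = [
            SigmaWeights(a, b)
            for a in cfg.sigma_values
            for b in cfg.sigma_values
        ]
        sw, sigma_records = sigma_grid_search(
            training, grid, seed=seeds["sigma_search"], cfg=cfg.perceptron, c_x=cfg.c_x
        )

        stage = "fit"
        sl_models = fit_sl_variants(
            training, sw, seed=seeds["variants"], cfg=cfg.perceptron, c_x=cfg.c_x
        )
        lr = fit_lr(training, interaction=False)
        lr_int = fit_lr(training, interaction=True)
        fns = _score_fns(sl_models, lr, lr_int)

        stage = "bootstrap_eval"
        boot_fns = dict(fns)
        boot_fns["x1"] = lambda ds: ds.x1
        boot_fns["x2"] = lambda ds: ds.x2
        table1 = bootstrap_training_eval(
            boot_fns,
            training,
            reps=cfg.reps,
            B=cfg.B,
            rng=np.random.default_rng(seeds["bootstrap"]),
        )

        stage = "validation_eval"
        table2 = validation_eval(fns, validation)

        stage = "operating_points"
        eval_ds = validation[0]
        op_points = {}
        for name in MODEL_ORDER:
            s = fns[name](eval_ds)
            op = operating_point_mean_sensitivity(s, eval_ds.status)
            op_points[name] = {
                "threshold": round(op.threshold, 6),
                "sensitivity": round(op.sensitivity, 6),
                "fp": round(op.fp, 6),
            }

        stage = "odds_transform"
        curves = {}
        for name, model in sl_models.items():
            ss = model.score_dataset(eval_ds)
            dens = estimate_densities(ss, bandwidth=cfg.kde_bandwidth)
            p_r = conditional_probability(dens)
            curves[name] = or_curve(p_r, dens.z_grid, delta_z=cfg.delta_z)

        stage = "boundaries"
        x1_lo, x1_hi = float(training.x1.min()), float(training.x1.max())
        b_std = boundary_standard(lr, op_points["LR"]["threshold"])
        b_int = boundary_interaction(lr_int, op_points["LR_int"]["threshold"])
    except Exception as exc:  # annotate failures with the stage name
        raise RuntimeError(f"study stage '{stage}' failed (seed {cfg.seed}): {exc}") from exc

    report = {
        "seed": cfg.seed,
        "m": cfg.generator.m,
        "generator": dataclasses.asdict(train_cfg),
        "sigma_weights": {"sigma1": sw.sigma1, "sigma2": sw.sigma2},
        "training_az": {n: round(m.train_az, 6) for n, m in sl_models.items()},
        "lr_coefficients": {
            "standard": [round(v, 6) for v in lr.params],
            "interaction": [round(v, 6) for v in lr_int.params],
        },
        "raw_variable_az": {
            "x1": round(raw_variable_az(training, "x1"), 6),
            "x2": round(raw_variable_az(training, "x2"), 6),
        },
        "table1": _summary_rows(table1),
        "table2": _summary_rows(table2),
        "operating_points": op_points,
        "delta_z": cfg.delta_z,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        kio.write_dataset(training, outdir / "train.csv")
        for i, ds in enumerate(validation, 1):
            kio.write_dataset(ds, outdir / f"val_{i}.csv")
        sigma_records.to_csv(outdir / "sigma_records.csv", index=False, float_format="%.12g")
        for name, model in sl_models.items():
            kio.save_model(model, outdir / f"{name}.model.json")
        kio.save_model(lr, outdir / "LR.model.json")
        kio.save_model(lr_int, outdir / "LR_int.model.json")
        pd.DataFrame(report["table1"]).to_csv(outdir / "table1.csv", index=False)
        pd.DataFrame(report["table2"]).to_csv(outdir / "table2.csv", index=False)
        for name, curve in curves.items():
            pd.DataFrame(
                {
                    "z": curve.z_grid,
                    "p_r": curve.p_r,
                    "p_1": curve.p_1,
                    "log_or": curve.log_or,
                }
            ).to_csv(outdir / f"or_curve_{name}.csv", index=False, float_format="%.12g")
        for label, bc in (("lr", b_std), ("lr_int", b_int)):
            pts = bc.sample(x1_lo, x1_hi)
            pd.DataFrame(pts, columns=["x1", "x2"]).to_csv(
                outdir / f"boundary_{label}.csv", index=False, float_format="%.12g"
            )
        (outdir / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=1) + "\n"
        )
    return report
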