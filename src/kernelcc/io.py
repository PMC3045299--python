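"""File formats: dataset CSV, model JSON, configuration YAML.

Dataset CSV: header ``id,x1,x2,status``; status 0 = control, 1 = case;
controls written first; values printed to 12 significant digits so a
write/read round trip is lossless at that precision.

Models serialize to a single portable JSON file.  The kernel-perceptron file
embeds its full training set (the method needs it at predict time) together
with alpha, bias, sigma-weights, component mask, c_x and the normalization
bounds.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kernel_map import ComponentMask, SigmaWeights
from .logistic_model import LRModel
from .perceptron import PerceptronModel
from .synthetic_data import CaseControlDataset, GeneratorConfig

__all__ = [
    "read_dataset",
    "write_dataset",
    "save_model",
    "load_model",
    "read_generator_config",
    "write_generator_config",
    "reference_config_path",
]


def read_dataset(path: str | Path) -> CaseControlDataset:
    """Read and validate a case-control CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"id", "x1", "x2", "status"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    status = df["status"]
    bad = ~status.isin((0, 1))
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header is line 1
        raise ValueError(
            f"{path}, line {line}: status must be 0 or 1, got {status[bad].iloc[0]!r}"
        )
    for col in ("x1", "x2"):
        vals = pd.to_numeric(df[col], errors="coerce")
        nan = vals.isna()
        if nan.any():
            line = int(df.index[nan][0]) + 2
            raise ValueError(f"{path}, line {line}: non-numeric {col}")
    return CaseControlDataset.from_frame(df)


def write_dataset(ds: CaseControlDataset, path: str | Path) -> None:
    """Write a dataset CSV (controls first, 12 significant digits)."""
    df = ds.to_frame()
    df.to_csv(path, index=False, float_format="%.12g")


def _sw_dict(sw: SigmaWeights) -> dict:
    return {"sigma1": sw.sigma1, "sigma2": sw.sigma2}


def save_model(model: PerceptronModel | LRModel, path: str | Path) -> None:
    path = Path(path)
    if isinstance(model, PerceptronModel):
        payload = {
            "type": "kernel_perceptron",
            "alpha": model.alpha.tolist(),
            "bias": model.bias,
            "sigma_weights": _sw_dict(model.sw),
            "mask": {"s1": model.mask.s1, "s2": model.mask.s2},
            "c_x": model.c_x,
            "norm_lo": model.norm_lo,
            "norm_hi": model.norm_hi,
            "train_az": model.train_az,
            "train_X": model.train_X.tolist(),
            "train_labels": model.train_labels.astype(int).tolist(),
        }
    elif isinstance(model, LRModel):
        payload = {
            "type": "logistic",
            "beta": [model.beta0, model.beta1, model.beta2, model.beta3],
            "interaction": model.interaction,
            "bse": None if model.bse is None else np.asarray(model.bse).tolist(),
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    path.write_text(json.dumps(payload, sort_keys=True))


def load_model(path: str | Path) -> PerceptronModel | LRModel:
    payload = json.loads(Path(path).read_text())
    kind = payload.get("type")
    if kind == "kernel_perceptron":
        return PerceptronModel(
            alpha=np.array(payload["alpha"]),
            sw=SigmaWeights(**payload["sigma_weights"]),
            mask=ComponentMask(**payload["mask"]),
            c_x=payload["c_x"],
            train_X=np.array(payload["train_X"]),
            train_labels=np.array(payload["train_labels"]),
            norm_lo=payload["norm_lo"],
            norm_hi=payload["norm_hi"],
            train_az=payload["train_az"],
            bias=payload["bias"],
        )
    if kind == "logistic":
        b = payload["beta"]
        return LRModel(
            beta0=b[0],
            beta1=b[1],
            beta2=b[2],
            beta3=b[3],
            interaction=payload["interaction"],
            bse=None if payload["bse"] is None else np.array(payload["bse"]),
        )
    raise ValueError(f"unknown model type {kind!r} in {path}")


def write_generator_config(cfg: GeneratorConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True))


def read_generator_config(path: str | Path) -> GeneratorConfig:
    data = yaml.safe_load(Path(path).read_text())
    return GeneratorConfig(**data)


def reference_config_path() -> Path:
    """Path of the shipped frozen reference generator configuration."""
    return Path(__file__).parent / "data" / "reference_config.yaml"
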