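import numpy as np
import pytest

from kernelcc import (
    CaseControlDataset,
    SigmaWeights,
    generate_dataset,
    reference_config,
)


@pytest.fixture(scope="session")
def small_dataset() -> CaseControlDataset:
    """Reference-configuration dataset at reduced size for fast training."""
    return generate_dataset(reference_config(m=60, seed=7))


@pytest.fixture(scope="session")
def training_dataset() -> CaseControlDataset:
    """Full-size (m=200) reference training dataset, canonical seed."""
    return generate_dataset(reference_config(m=200, seed=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_sw() -> SigmaWeights:
    return SigmaWeights(3.0, 2.0)


def make_clouds(m: int, gap: float, rng: np.random.Generator) -> CaseControlDataset:
    """Two Gaussian point clouds separated along x2 by ``gap``."""
    ctrl = rng.normal([0.3, 0.3], 0.05, size=(m, 2))
    case = rng.normal([0.3, 0.3 + gap], 0.05, size=(m, 2))
    X = np.vstack([ctrl, case])
    status = np.r_[np.zeros(m, dtype=int), np.ones(m, dtype=int)]
    return CaseControlDataset(x1=X[:, 0], x2=X[:, 1], status=status)


def make_xor(m_per_cluster: int, rng: np.random.Generator) -> CaseControlDataset:
    """Classic XOR layout: same-label clusters on opposite diagonal corners."""
    centers_case = [(0.0, 0.0), (1.0, 1.0)]
    centers_ctrl = [(0.0, 1.0), (1.0, 0.0)]
    pts, labels = [], []
    for cx, cy in centers_ctrl:
        pts.append(rng.normal([cx, cy], 0.08, size=(m_per_cluster, 2)))
        labels.append(np.zeros(m_per_cluster, dtype=int))
    for cx, cy in centers_case:
        pts.append(rng.normal([cx, cy], 0.08, size=(m_per_cluster, 2)))
        labels.append(np.ones(m_per_cluster, dtype=int))
    X = np.vstack(pts)
    y = np.concatenate(labels)
    return CaseControlDataset(x1=X[:, 0], x2=X[:, 1], status=y)
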