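"""Shared fixtures: explicit low-dimensional feature instances (for oracle
checks against kernelized computations) and small synthetic benchmarks."""

from __future__ import annotations

import numpy as np
import pytest

from iokr import GeneratorConfig, KernelMatrix, generate_benchmark


@pytest.fixture(scope="session")
def feature_instance():
    """Explicit feature tables for a 30-train / 10-query / 20-candidate
    problem with linear input and output kernels, so every kernelized
    quantity has a closed-form feature-space counterpart."""
    rng = np.random.default_rng(42)
    n_train, n_query, n_cand = 30, 10, 20
    p, d = 8, 12
    X = rng.normal(size=(n_train, p))
    Yf = rng.normal(size=(n_train, d))
    Q = rng.normal(size=(n_query, p))
    C = rng.normal(size=(n_cand, d))
    train_ids = [f"t{i}" for i in range(n_train)]
    K_X = KernelMatrix(train_ids, train_ids, X @ X.T)
    K_Y = KernelMatrix(train_ids, train_ids, Yf @ Yf.T)
    return {
        "X": X, "Yf": Yf, "Q": Q, "C": C,
        "K_X": K_X, "K_Y": K_Y, "train_ids": train_ids,
    }


@pytest.fixture(scope="session")
def signal_benchmark():
    """A small signal-bearing benchmark reused by slower integration tests."""
    cfg = GeneratorConfig(n_molecules=40, candidates_per_query=8, n_views=2, seed=5)
    return generate_benchmark(cfg)
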