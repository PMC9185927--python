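import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from ocproteo.matrix import AbundanceMatrix
from ocproteo.simulate import SimConfig, generate_experiment


def small_config(seed: int = 11, **overrides) -> SimConfig:
    """A reduced experiment for fast unit tests."""
    base = dict(
        n_proteins=12,
        peptides_per_protein=(5, 8),
        n_planted_semitryptic=5,
        n_background_semitryptic=10,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_experiment():
    return generate_experiment(small_config())


@pytest.fixture(scope="session")
def default_experiment():
    """Full default study conditions; shared across tests for speed."""
    return generate_experiment(SimConfig(seed=42))


def make_matrix(values, donors=None, treatments=None, batches=None,
                compartment="media", scale="raw") -> AbundanceMatrix:
    """Small AbundanceMatrix helper: values is features x samples array."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    sample_ids = [f"s{j + 1}" for j in range(n_samp)]
    meta = pd.DataFrame(
        {
            "donor": donors or [f"d{j + 1}" for j in range(n_samp)],
            "treatment": treatments or ["N"] * n_samp,
            "batch": batches or ["b1"] * n_samp,
            "compartment": [compartment] * n_samp,
            "replicate": [1] * n_samp,
        },
        index=sample_ids,
    )
    frame = pd.DataFrame(
        values, index=[f"f{i + 1}" for i in range(n_feat)], columns=sample_ids
    )
    return AbundanceMatrix(frame, meta, scale)


def brute_force_knn_impute(X: np.ndarray, k: int) -> np.ndarray:
    """Independent exhaustive-oracle kNN imputation (pure python loops).

    Mirrors the documented rule: neighbours are features observed at the
    target sample, distances are plain Euclidean over mutually observed
    samples, ties break by feature order, imputed value is the unweighted
    mean of the k nearest neighbours' values at the sample.
    """
    X = X.astype(float).copy()
    out = X.copy()
    n_feat, n_samp = X.shape
    for f in range(n_feat):
        for s in range(n_samp):
            if not np.isnan(X[f, s]):
                continue
            dists = []
            for g in range(n_feat):
                if g == f or np.isnan(X[g, s]):
                    continue
                common = [
                    j
                    for j in range(n_samp)
                    if not np.isnan(X[f, j]) and not np.isnan(X[g, j])
                ]
                if not common:
                    continue
                d = sum((X[f, j] - X[g, j]) ** 2 for j in common)
                dists.append((d, g))
            dists.sort()
            chosen = [g for _, g in dists[:k]]
            out[f, s] = np.mean([X[g, s] for g in chosen])
    return out
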