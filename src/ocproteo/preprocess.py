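"""Filtering, kNN imputation, DNA normalization, log2 scaling, batch removal.

Order of operations in the standard pipeline: presence filter on the raw
matrix, DNA normalization (tissue only), log2 transform, kNN imputation on the
log2 scale, per-feature standardization, then design-preserving batch
correction for the ordination/regression analyses.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConfoundingError, InputError, JoinError
from .matrix import (
    SCALE_LOG2,
    SCALE_LOG2_SCALED,
    SCALE_RAW,
    AbundanceMatrix,
)


def filter_features(
    m: AbundanceMatrix,
    min_frac: float = 0.70,
    exogenous: Iterable[str] = (),
) -> AbundanceMatrix:
    """Keep features quantified in >= ceil(min_frac * n_samples) samples.

    Exogenous features (e.g. culture-medium or contaminant accessions) are
    removed regardless of presence. Feature order is preserved.
    """
    if not 0.0 <= min_frac <= 1.0:
        raise ConfigurationError(f"min_frac must be in [0,1], got {min_frac}")
    m.require_scale(SCALE_RAW)
    exo = set(exogenous)
    need = math.ceil(min_frac * m.n_samples)
    counts = m.values.notna().sum(axis=1)
    keep = [
        f for f in m.feature_ids if f not in exo and counts[f] >= need
    ]
    return m.subset_features(keep)


def knn_impute(m: AbundanceMatrix, k: int = 10) -> AbundanceMatrix:
    """k-nearest-neighbour imputation with features as neighbours.

    For a missing cell (f, s): candidate neighbours are the other features
    observed at sample s; distance from f to a candidate is the plain
    Euclidean distance over the samples where both are observed (candidates
    sharing no observed sample are unusable); the imputed value is the
    unweighted mean of the k nearest candidates' values at s, using all
    candidates when fewer than k exist. Ties in distance break by feature
    order. Observed cells are never touched.
    """
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    m.require_scale(SCALE_LOG2)
    X = m.values.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    zero_obs = np.where(obs.sum(axis=1) == 0)[0]
    if zero_obs.size:
        ids = [m.feature_ids[i] for i in zero_obs[:5]]
        raise InputError(
            f"features with no observed values (filter first): {ids}"
        )
    if obs.all():
        return m.copy()

    # pairwise NaN-aware squared Euclidean distances over common samples
    X0 = np.where(obs, X, 0.0)
    M = obs.astype(float)
    sq = X0**2
    common = M @ M.T
    d2 = (sq @ M.T) + (M @ sq.T) - 2.0 * (X0 @ X0.T)
    d2 = np.maximum(d2, 0.0)
    d2[common == 0] = np.inf
    np.fill_diagonal(d2, np.inf)

    out = X.copy()
    for s in range(X.shape[1]):
        missing_rows = np.where(~obs[:, s])[0]
        if missing_rows.size == 0:
            continue
        candidates = np.where(obs[:, s])[0]
        for f in missing_rows:
            dists = d2[f, candidates]
            usable = candidates[np.isfinite(dists)]
            if usable.size == 0:
                raise InputError(
                    f"no usable neighbour for feature {m.feature_ids[f]} "
                    f"at sample {m.sample_ids[s]}"
                )
            dist_u = d2[f, usable]
            order = np.lexsort((usable, dist_u))
            chosen = usable[order[: min(k, usable.size)]]
            out[f, s] = X[chosen, s].mean()
    values = pd.DataFrame(out, index=m.feature_ids, columns=m.sample_ids)
    return AbundanceMatrix(values, m.sample_meta.copy(), SCALE_LOG2)


def normalize_dna(m: AbundanceMatrix, biochem: pd.DataFrame) -> AbundanceMatrix:
    """Normalize tissue intensities to DNA content per wet weight.

    Each tissue sample's values are divided by its explant's
    ``dna_ng / wet_weight_mg``, adjusting for cell-density differences between
    donors. Media samples pass through unchanged. Tissue samples are matched
    to biochemistry rows on (donor, treatment, replicate).
    """
    m.require_scale(SCALE_RAW)
    per_explant = (
        biochem.groupby(["donor", "treatment", "replicate"])[
            ["dna_ng", "wet_weight_mg"]
        ]
        .first()
    )
    values = m.values.copy()
    orphans, bad = [], []
    for sid, row in m.sample_meta.iterrows():
        if row["compartment"] != "tissue":
            continue
        key = (row["donor"], row["treatment"], row["replicate"])
        if key not in per_explant.index:
            orphans.append(sid)
            continue
        dna, ww = per_explant.loc[key, ["dna_ng", "wet_weight_mg"]]
        if dna <= 0 or ww <= 0:
            bad.append(sid)
            continue
        values[sid] = values[sid] / (dna / ww)
    if orphans:
        raise JoinError(f"tissue samples without biochemistry match: {orphans}")
    if bad:
        raise InputError(f"nonpositive DNA or wet weight for samples: {bad}")
    return AbundanceMatrix(values, m.sample_meta.copy(), SCALE_RAW)


def log2_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    """Raw -> log2. Observed values must be strictly positive."""
    m.require_scale(SCALE_RAW)
    vals = m.values
    nonpos = vals.le(0)
    if nonpos.any().any():
        f, s = next(
            (f, s)
            for f in vals.index
            for s in vals.columns
            if vals.at[f, s] <= 0
        )
        raise InputError(f"nonpositive intensity at feature {f}, sample {s}")
    return AbundanceMatrix(np.log2(vals), m.sample_meta.copy(), SCALE_LOG2)


def scale_features(
    m: AbundanceMatrix, on_constant: str = "error"
) -> AbundanceMatrix:
    """Per-feature centering to mean 0 and scaling to unit (sample) variance.

    Statistics are computed over observed values only. ``on_constant`` chooses
    behaviour for zero-variance features: ``"error"`` (default) or ``"zero"``
    (emit a zero vector).
    """
    m.require_scale(SCALE_LOG2)
    mu = m.values.mean(axis=1)
    sd = m.values.std(axis=1, ddof=1)
    const = sd.le(0) | sd.isna()
    if const.any():
        if on_constant == "error":
            raise InputError(
                f"constant features: {list(m.values.index[const])[:5]}"
            )
        sd = sd.mask(const, 1.0)
        mu = mu.mask(const, m.values.mean(axis=1))
    scaled = m.values.sub(mu, axis=0).div(sd, axis=0)
    if const.any():
        scaled.loc[const] = 0.0
    return AbundanceMatrix(scaled, m.sample_meta.copy(), SCALE_LOG2_SCALED)


def log2_scale(m: AbundanceMatrix, on_constant: str = "error") -> AbundanceMatrix:
    """Raw -> log2 -> per-feature standardized, in one call."""
    return scale_features(log2_transform(m), on_constant=on_constant)


def remove_batch(
    m: AbundanceMatrix,
    batch: pd.Series | None = None,
    design: pd.DataFrame | None = None,
) -> AbundanceMatrix:
    """Subtract per-feature additive batch effects, preserving the design.

    Per feature, fits ``value ~ design + batch`` with sum-to-zero batch coding
    and subtracts the fitted batch terms, so design-attributable variation
    (treatment effects by default) is untouched. Raises
    :class:`ConfoundingError` when batch is aliased with the design.
    """
    m.require_scale(SCALE_LOG2, SCALE_LOG2_SCALED)
    if batch is None:
        batch = m.sample_meta["batch"]
    batch = batch.loc[m.sample_ids]
    levels = sorted(batch.unique())
    if len(levels) < 2:
        raise ConfoundingError("need >= 2 batches to correct")
    if design is None:
        design = pd.get_dummies(
            m.sample_meta["treatment"], drop_first=True, dtype=float
        )
    design = design.loc[m.sample_ids].astype(float)

    # sum-to-zero coding: last level = -1 on every indicator column
    B = np.zeros((m.n_samples, len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        B[:, j] = (batch == lev).astype(float)
    B[(batch == levels[-1]).to_numpy(), :] = -1.0

    Xd = np.column_stack([np.ones(m.n_samples), design.to_numpy()])
    Z = np.column_stack([Xd, B])
    if np.linalg.matrix_rank(Z) < np.linalg.matrix_rank(Xd) + B.shape[1]:
        raise ConfoundingError("batch is aliased with the design matrix")

    Y = m.values.to_numpy(dtype=float).T  # samples x features
    if np.isnan(Y).any():
        raise InputError("remove_batch requires a complete matrix")
    coef, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    gamma = coef[Xd.shape[1]:, :]
    corrected = (Y - B @ gamma).T
    values = pd.DataFrame(corrected, index=m.feature_ids, columns=m.sample_ids)
    return AbundanceMatrix(values, m.sample_meta.copy(), m.scale_tag)


def warn_on_zeros(values: pd.DataFrame) -> None:
    """Zeros are treated as observed intensities, not missingness."""
    n = int((values == 0).sum().sum())
    if n:
        warnings.warn(
            f"{n} zero intensities present; zeros are observed values, "
            "use empty cells or NA for missingness",
            stacklevel=2,
        )
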