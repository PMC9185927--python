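"""PCA, replicate averaging, NIPALS PLS regression and biomarker ranking.

Biomarker candidates are ranked by regressing feature abundances (averaged
over biological replicates within each donor x treatment condition) against a
severity response — total percent sGAG loss, or the per-donor percentage of
IC-induced excess loss attenuated by dexamethasone — with a two-component
PLS1 model. Each feature's score is its pair of predictor loadings (XL1, XL2)
dotted with the response loadings (YL1, YL2): the projection of the feature
onto the response-associated direction in latent space. Large positive scores
mark features whose abundance rises with severity.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .errors import InputError, JoinError
from .matrix import SCALE_LOG2, SCALE_LOG2_SCALED, AbundanceMatrix


@dataclasses.dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    pct_variance: pd.Series  # per component, sums to 100


def pca(m: AbundanceMatrix) -> PCAResult:
    """Principal components of samples over features, via SVD.

    Columns (features) are centered; the percent variance explained sums to
    100 over all returned components. Component signs follow a deterministic
    convention: the largest-magnitude loading of each component is positive.
    """
    m.require_scale(SCALE_LOG2, SCALE_LOG2_SCALED)
    if m.n_samples < 2:
        raise InputError("PCA needs at least 2 samples")
    X = m.values.to_numpy(dtype=float).T  # samples x features
    if np.isnan(X).any():
        raise InputError("PCA requires a complete matrix")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = S > S[0] * 1e-12 if S.size and S[0] > 0 else np.zeros_like(S, bool)
    U, S, Vt = U[:, keep], S[keep], Vt[keep]
    # sign convention
    for j in range(S.size):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * S
    var = S**2
    pct = 100.0 * var / var.sum() if var.sum() > 0 else var
    comps = [f"PC{j + 1}" for j in range(S.size)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.sample_ids, columns=comps),
        loadings=pd.DataFrame(Vt.T, index=m.feature_ids, columns=comps),
        pct_variance=pd.Series(pct, index=comps, name="pct_variance"),
    )


def average_replicates(
    m: AbundanceMatrix, response: pd.Series | pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Mean abundance per donor x treatment, with an aligned response vector.

    ``response`` is indexed by (donor, treatment) — e.g. the donor loss table
    stacked — and is reindexed to the group order; a group without a response
    raises a join error. Returns (groups x features matrix, response).
    """
    meta = m.sample_meta
    keys = list(zip(meta["donor"], meta["treatment"]))
    groups = sorted(set(keys))
    X = pd.DataFrame(index=pd.MultiIndex.from_tuples(groups, names=["donor", "treatment"]),
                     columns=m.feature_ids, dtype=float)
    for g in groups:
        sids = [s for s, k in zip(m.sample_ids, keys) if k == g]
        X.loc[g, :] = m.values[sids].mean(axis=1).to_numpy()
    y = None
    if response is not None:
        if isinstance(response, pd.DataFrame):
            response = response.stack()
        missing = [g for g in groups if g not in response.index]
        if missing:
            raise JoinError(f"groups without a response value: {missing[:5]}")
        y = pd.Series(
            [float(response.loc[g]) for g in groups], index=X.index, name="response"
        )
    return X, y


@dataclasses.dataclass
class PLSModel:
    """NIPALS PLS1 model with deterministic deflation."""

    x_loadings: pd.DataFrame  # XL: features x components
    y_loadings: np.ndarray  # YL: per component
    x_scores: pd.DataFrame  # T: observations x components
    weights: pd.DataFrame  # W: features x components
    x_mean: pd.Series
    y_mean: float
    n_components: int

    def fitted(self) -> np.ndarray:
        """In-sample fitted response values."""
        return self.y_mean + self.x_scores.to_numpy() @ self.y_loadings


def plsr_nipals(
    X: pd.DataFrame, y: pd.Series, n_components: int = 2
) -> PLSModel:
    """PLS1 regression by NIPALS deflation.

    Per component: weight w proportional to X'y (unit norm), scores t = Xw,
    x-loading p = X't/t't, y-loading q = y't/t't, then X and y are deflated
    by the extracted component. X is used as given (standardize upstream);
    y is centered internally.
    """
    Xm = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    if np.isnan(Xm).any():
        raise InputError("X must be complete")
    if yv.std() == 0:
        raise InputError("response has zero variance")
    rank = np.linalg.matrix_rank(Xm - Xm.mean(axis=0))
    if n_components > rank:
        raise InputError(f"n_components {n_components} exceeds rank {rank}")
    x_mean = Xm.mean(axis=0)
    y_mean = float(yv.mean())
    Xc = Xm - x_mean
    yc = yv - y_mean
    n, p = Xc.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    Q = np.zeros(n_components)
    for a in range(n_components):
        w = Xc.T @ yc
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            raise InputError(f"component {a + 1}: X carries no covariance with y")
        w = w / norm
        t = Xc @ w
        tt = float(t @ t)
        pvec = Xc.T @ t / tt
        q = float(yc @ t / tt)
        Xc = Xc - np.outer(t, pvec)
        yc = yc - q * t
        W[:, a], P[:, a], T[:, a], Q[a] = w, pvec, t, q
    comps = [f"LV{a + 1}" for a in range(n_components)]
    feat_index = X.columns if isinstance(X, pd.DataFrame) else pd.RangeIndex(p)
    obs_index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(n)
    return PLSModel(
        x_loadings=pd.DataFrame(P, index=feat_index, columns=comps),
        y_loadings=Q,
        x_scores=pd.DataFrame(T, index=obs_index, columns=comps),
        weights=pd.DataFrame(W, index=feat_index, columns=comps),
        x_mean=pd.Series(x_mean, index=feat_index),
        y_mean=y_mean,
        n_components=n_components,
    )


def loading_dot_rank(
    model: PLSModel, top_n: int = 50, variant: str = "xl_dot_yl"
) -> pd.DataFrame:
    """Rank features by their first-two-component loading dot product.

    Default variant ``"xl_dot_yl"``: score(f) = XL[f,1]*YL[1] + XL[f,2]*YL[2].
    The alternative reading ``"xl1_xl2"`` multiplies a feature's two x-loadings
    with each other. Rank 1 is the strongest positive association; ties break
    lexicographically on feature id.
    """
    if model.n_components < 2:
        raise InputError("ranking needs a model with >= 2 components")
    XL = model.x_loadings.iloc[:, :2].to_numpy()
    if variant == "xl_dot_yl":
        score = XL @ model.y_loadings[:2]
    elif variant == "xl1_xl2":
        score = XL[:, 0] * XL[:, 1]
    else:
        raise InputError(f"unknown variant {variant!r}")
    tab = pd.DataFrame(
        {"feature_id": model.x_loadings.index, "dot_score": score}
    )
    tab = tab.sort_values(
        ["dot_score", "feature_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    if top_n > len(tab):
        warnings.warn(
            f"top_n {top_n} exceeds n_features {len(tab)}; returning all",
            stacklevel=2,
        )
        top_n = len(tab)
    return tab.head(top_n).reset_index(drop=True)
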