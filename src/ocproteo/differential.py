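"""Moderated differential abundance across treatment arms.

Per feature, an ordinary least-squares linear model on the log2 scale gives
treatment-pair log2 fold changes. Residual variances are then shrunk toward a
common prior by empirical Bayes: the per-feature sample variances s^2 (on d
residual df) are modelled as scaled chi-square draws around a prior variance
s0^2 with prior df d0, the hyperparameters are estimated in closed form by
moment-matching the distribution of log s^2 (trigamma inversion), and each
feature's posterior variance

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

replaces s^2 in the t statistic, which then has d + d0 degrees of freedom.
This borrows strength across the thousands of peptides so that features with
accidentally tiny variance do not dominate the significant lists.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InputError
from .matrix import SCALE_LOG2, SCALE_LOG2_SCALED, SCALE_RAW, AbundanceMatrix

#: the study's four standard treatment comparisons
DEFAULT_CONTRASTS = (("D", "N"), ("IC", "N"), ("ICD", "N"), ("ICD", "IC"))


@dataclasses.dataclass
class FeatureFit:
    """Per-feature OLS fits over a shared design matrix."""

    coef: pd.DataFrame  # features x design columns
    s2: pd.Series  # residual variance per feature
    df: int  # residual degrees of freedom
    xtx_inv: np.ndarray
    design_columns: list[str]
    treatment_levels: list[str]


def fit_feature_models(
    m: AbundanceMatrix,
    include_batch: bool = True,
    donor_covariate: bool = False,
) -> FeatureFit:
    """OLS per feature: log2 abundance ~ treatment (+ batch) (+ donor).

    Treatment uses cell-means coding (one column per arm) so any pairwise
    contrast is a difference of coefficients, i.e. a log2 fold change.
    """
    m.require_scale(SCALE_LOG2, SCALE_LOG2_SCALED)
    Y = m.values.to_numpy(dtype=float).T  # samples x features
    if np.isnan(Y).any():
        raise InputError("matrix must be complete (impute first)")
    meta = m.sample_meta
    levels = sorted(meta["treatment"].unique())
    cols: list[np.ndarray] = []
    names: list[str] = []
    for lev in levels:
        cols.append((meta["treatment"] == lev).to_numpy(dtype=float))
        names.append(f"treatment[{lev}]")
    if include_batch and meta["batch"].nunique() > 1:
        for lev in sorted(meta["batch"].unique())[1:]:
            cols.append((meta["batch"] == lev).to_numpy(dtype=float))
            names.append(f"batch[{lev}]")
    if donor_covariate and meta["donor"].nunique() > 1:
        for lev in sorted(meta["donor"].unique())[1:]:
            cols.append((meta["donor"] == lev).to_numpy(dtype=float))
            names.append(f"donor[{lev}]")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = _aliased_columns(X, names)
        raise InputError(f"rank-deficient design; aliased columns: {aliased}")
    n = X.shape[0]
    dof = n - rank
    if dof < 1:
        raise InputError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y  # columns x features
    resid = Y - X @ beta
    s2 = (resid**2).sum(axis=0) / dof
    return FeatureFit(
        coef=pd.DataFrame(beta.T, index=m.feature_ids, columns=names),
        s2=pd.Series(s2, index=m.feature_ids, name="s2"),
        df=dof,
        xtx_inv=xtx_inv,
        design_columns=names,
        treatment_levels=levels,
    )


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    keep: list[int] = []
    aliased = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            aliased.append(names[j])
    return aliased


# ---------------------------------------------------------------------------
# empirical Bayes


@dataclasses.dataclass(frozen=True)
class PriorEstimate:
    d0: float  # prior degrees of freedom (may be inf)
    s02: float  # prior variance


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise InputError("trigamma_inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: Sequence[float] | pd.Series, df: float) -> PriorEstimate:
    """Closed-form (d0, s0^2) from the marginal distribution of log s^2.

    Moment-matches z = log s^2: under the scaled chi-square hierarchy,
    var(z) = trigamma(df/2) + trigamma(d0/2), which is inverted with the
    trigamma function. When the observed variances show no excess dispersion
    (var of z at or below the chi-square floor), d0 = inf and s0^2 is the
    geometric mean of s^2 — then every posterior variance equals s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 2:
        raise InputError("need >= 2 features to estimate the prior")
    if np.any(s2 <= 0):
        raise InputError("residual variances must be positive")
    z = np.log(s2)
    evar = z.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return PriorEstimate(d0=np.inf, s02=float(np.exp(z.mean())))
    d0 = 2.0 * trigamma_inverse(float(evar))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    s02 = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return PriorEstimate(d0=d0, s02=s02)


def posterior_s2(s2: np.ndarray, df: float, prior: PriorEstimate) -> np.ndarray:
    if np.isinf(prior.d0):
        return np.full_like(np.asarray(s2, dtype=float), prior.s02)
    return (prior.d0 * prior.s02 + df * s2) / (prior.d0 + df)


def moderated_contrasts(
    fit: FeatureFit,
    contrasts: Sequence[tuple[str, str]] = DEFAULT_CONTRASTS,
    prior: PriorEstimate | None = None,
) -> pd.DataFrame:
    """Moderated t, p and BH q for each treatment-pair contrast.

    Passing ``prior`` overrides hyperparameter estimation (d0=0 reproduces the
    ordinary t exactly; d0=inf pools every variance to s0^2).
    """
    if prior is None:
        prior = estimate_prior(fit.s2, fit.df)
    s2 = fit.s2.to_numpy()
    s2_post = posterior_s2(s2, fit.df, prior)
    df_total = fit.df + (prior.d0 if np.isfinite(prior.d0) else np.inf)
    out = []
    levels = set(fit.treatment_levels)
    for a, b in contrasts:
        if a not in levels or b not in levels:
            continue
        c = np.zeros(len(fit.design_columns))
        c[fit.design_columns.index(f"treatment[{a}]")] = 1.0
        c[fit.design_columns.index(f"treatment[{b}]")] = -1.0
        v_unscaled = float(c @ fit.xtx_inv @ c)
        logfc = fit.coef.to_numpy() @ c
        se = np.sqrt(v_unscaled * s2_post)
        tmod = np.where(se > 0, logfc / se, np.nan)
        p = 2.0 * stats.t.sf(np.abs(tmod), df_total)
        q = adjust_bh(p)
        out.append(
            pd.DataFrame(
                {
                    "feature_id": fit.coef.index,
                    "contrast": f"{a}/{b}",
                    "log2_fc": logfc,
                    "moderated_t": tmod,
                    "p_value": p,
                    "fdr_q": q,
                    "prior_df": prior.d0,
                    "prior_var": prior.s02,
                    "residual_df": fit.df,
                }
            )
        )
    if not out:
        raise InputError("no requested contrast matches the design")
    return pd.concat(out, ignore_index=True)


def adjust_bh(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# presence / absence


def condition_unique(
    m: AbundanceMatrix,
    donor_threshold: int | None = None,
    max_conditions: int = 2,
) -> pd.DataFrame:
    """Features quantified in only one or two treatment conditions.

    A feature is flagged for a condition set C (|C| <= ``max_conditions``)
    when in each condition of C it is quantified in at least
    ``donor_threshold`` donors, and no donor detects it in any condition
    outside C. The default threshold mirrors the study rule: all but one
    donor for media matrices (6 of 7), every donor for tissue. Operates on
    the raw, pre-imputation mask.
    """
    m.require_scale(SCALE_RAW)
    meta = m.sample_meta
    compartments = meta["compartment"].unique()
    if len(compartments) != 1:
        raise InputError("condition_unique expects a single-compartment matrix")
    n_donors = meta["donor"].nunique()
    if donor_threshold is None:
        donor_threshold = n_donors - 1 if compartments[0] == "media" else n_donors
        donor_threshold = max(donor_threshold, 1)
    if donor_threshold > n_donors:
        raise ConfigurationError(
            f"donor_threshold {donor_threshold} exceeds donor count {n_donors}"
        )
    observed = m.values.notna()
    treatments = sorted(meta["treatment"].unique())
    # donors detecting each feature, per treatment
    donors_detecting = pd.DataFrame(index=m.feature_ids, columns=treatments, dtype=int)
    for trt in treatments:
        sids = meta.index[meta["treatment"] == trt]
        det = (
            observed[sids]
            .T.groupby(meta.loc[sids, "donor"])
            .any()
            .sum(axis=0)
        )
        donors_detecting[trt] = det
    rows = []
    for f in m.feature_ids:
        det = donors_detecting.loc[f]
        strong = [t for t in treatments if det[t] >= donor_threshold]
        any_det = [t for t in treatments if det[t] >= 1]
        if 1 <= len(strong) <= max_conditions and set(any_det) <= set(strong):
            rows.append(
                {
                    "feature_id": f,
                    "conditions": ",".join(strong),
                    "n_conditions": len(strong),
                }
            )
    return pd.DataFrame(rows, columns=["feature_id", "conditions", "n_conditions"])
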