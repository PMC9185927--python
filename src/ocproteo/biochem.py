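"""Cumulative sGAG loss, dexamethasone attenuation, and the donor mixed model.

Sulfated glycosaminoglycan (sGAG) released from the cartilage into the culture
medium over the 21-day treatment, as a fraction of the total (released +
remaining in the digested tissue), measures matrix catabolism. The
dexamethasone attenuation statistic asks, per donor: of the *excess* sGAG loss
caused by injury+cytokine (IC) treatment over untreated control (N), what
percentage did adding Dex (ICD) prevent?

    attenuation% = 100 * (loss_IC - loss_ICD) / (loss_IC - loss_N)

Treatment significance uses a linear mixed model with donor as a random
intercept, followed by pairwise least-squares-means contrasts.
"""

from __future__ import annotations

import dataclasses
import enum
import itertools

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .errors import InputError


class AttenuationFlag(str, enum.Enum):
    OK = "ok"
    UNDEFINED_NO_IC_EXCESS = "undefined_no_ic_excess"
    OUT_OF_RANGE = "out_of_range"


@dataclasses.dataclass(frozen=True)
class AttenuationResult:
    donor: str
    pct_loss_n: float
    pct_loss_ic: float
    pct_loss_icd: float
    attenuation_pct: float  # NaN when undefined
    flag: AttenuationFlag


def percent_sgag_loss(media_sgag_ug, tissue_sgag_ug: float) -> float:
    """Cumulative percent sGAG loss to the medium.

    100 * sum(media) / (sum(media) + final tissue sGAG).
    """
    media = np.asarray(media_sgag_ug, dtype=float)
    if media.size == 0:
        raise InputError("at least one media measurement required")
    total = media.sum() + float(tissue_sgag_ug)
    if total <= 0:
        raise InputError("total sGAG (media + tissue) is zero; loss undefined")
    return 100.0 * media.sum() / total


def explant_loss_table(biochem: pd.DataFrame) -> pd.DataFrame:
    """Per-explant cumulative percent loss from a long biochemistry table."""
    rows = []
    for (donor, trt, explant), grp in biochem.groupby(
        ["donor", "treatment", "explant_id"], sort=True
    ):
        tissue = grp["tissue_sgag_ug"].dropna()
        if len(tissue) != 1:
            raise InputError(
                f"explant {explant} must have exactly one tissue sGAG record"
            )
        rows.append(
            {
                "donor": donor,
                "treatment": trt,
                "explant_id": explant,
                "pct_loss": percent_sgag_loss(
                    grp["media_sgag_ug"], float(tissue.iloc[0])
                ),
            }
        )
    return pd.DataFrame(rows)


def donor_loss_table(biochem: pd.DataFrame) -> pd.DataFrame:
    """Mean percent loss per donor x treatment (explants averaged)."""
    per_explant = explant_loss_table(biochem)
    return (
        per_explant.groupby(["donor", "treatment"], sort=True)["pct_loss"]
        .mean()
        .unstack("treatment")
    )


def dex_attenuation(
    pct_n: float, pct_ic: float, pct_icd: float, donor: str = ""
) -> AttenuationResult:
    """Percent of IC-induced excess sGAG loss attenuated by Dex.

    Flags, never exceptions: ``undefined_no_ic_excess`` when IC loss does not
    exceed control (ratio undefined, value NaN); ``out_of_range`` when the
    attenuation falls outside [0, 100] — donors may show no, or negative,
    Dex response — with the value still returned.
    """
    for name, v in (("pct_n", pct_n), ("pct_ic", pct_ic), ("pct_icd", pct_icd)):
        if not 0.0 <= v <= 100.0:
            raise InputError(f"{name} must be a percentage in [0,100], got {v}")
    if pct_ic <= pct_n:
        return AttenuationResult(
            donor, pct_n, pct_ic, pct_icd, float("nan"),
            AttenuationFlag.UNDEFINED_NO_IC_EXCESS,
        )
    att = 100.0 * (pct_ic - pct_icd) / (pct_ic - pct_n)
    # tolerance absorbs float noise at the exact 0/100 limits
    in_range = -1e-9 <= att <= 100.0 + 1e-9
    flag = AttenuationFlag.OK if in_range else AttenuationFlag.OUT_OF_RANGE
    return AttenuationResult(donor, pct_n, pct_ic, pct_icd, att, flag)


def attenuation_by_donor(biochem: pd.DataFrame) -> pd.DataFrame:
    """Per-donor Dex attenuation from a long biochemistry table."""
    losses = donor_loss_table(biochem)
    for col in ("N", "IC", "ICD"):
        if col not in losses.columns:
            raise InputError(f"treatment {col} missing from biochemistry table")
    rows = []
    for donor, row in losses.iterrows():
        res = dex_attenuation(row["N"], row["IC"], row["ICD"], donor=donor)
        rows.append(
            {
                "donor": donor,
                "pct_loss_N": res.pct_loss_n,
                "pct_loss_IC": res.pct_loss_ic,
                "pct_loss_ICD": res.pct_loss_icd,
                "attenuation_pct": res.attenuation_pct,
                "flag": res.flag.value,
            }
        )
    return pd.DataFrame(rows).set_index("donor")


# ---------------------------------------------------------------------------
# mixed model


@dataclasses.dataclass
class LMMResult:
    """REML fit of response ~ treatment + (1 | donor) with LS-means tests."""

    lsmeans: pd.Series  # estimated marginal mean per treatment
    contrasts: pd.DataFrame  # pair, estimate, se, df, t, p, p_adj
    donor_var: float
    resid_var: float
    singular: bool  # True when the donor variance collapsed to ~0
    df_method: str = "containment"
    adjust: str = "tukey"


def fit_lmm(
    data: pd.DataFrame,
    response: str = "pct_loss",
    treatment: str = "treatment",
    donor: str = "donor",
    adjust: str = "tukey",
) -> LMMResult:
    """Donor-random-intercept mixed model with pairwise LS-means contrasts.

    Fit by REML via statsmodels MixedLM. LS-means are the estimated marginal
    treatment means; every pairwise difference is tested with its standard
    error from the fitted fixed-effect covariance. Degrees of freedom use the
    containment approximation ``N - n_treatments - n_donors + 1``; adjusted
    p-values use Tukey's studentized-range method (``adjust="bonferroni"``
    switches to Bonferroni). A donor variance that collapses to ~0 is flagged
    singular, in which case estimates coincide with ordinary least squares.
    """
    df = data[[response, treatment, donor]].dropna().copy()
    levels = sorted(df[treatment].unique())
    donors = df[donor].unique()
    if len(levels) < 2 or len(donors) < 2:
        raise InputError("need >= 2 treatments and >= 2 donors")
    counts = df.groupby([donor, treatment]).size()
    if counts.empty:
        raise InputError("no complete observations")
    if adjust not in ("tukey", "bonferroni"):
        raise InputError(f"unknown adjustment {adjust!r}")

    model = smf.mixedlm(
        f"{response} ~ C({treatment})", df, groups=df[donor]
    )
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(reml=True)
            if not np.all(np.isfinite(fit.fe_params)):
                fit = model.fit(reml=True, method="powell")
    resid_var = float(fit.scale)
    donor_var = float(fit.cov_re.iloc[0, 0])
    singular = donor_var < 1e-8 * max(resid_var, 1e-12)

    # fixed-effect part: intercept + treatment dummies (first level reference)
    k = len(levels)
    fe = fit.fe_params
    cov = fit.cov_params().iloc[: len(fe), : len(fe)].to_numpy()
    # LS-means: contrast rows picking each treatment's marginal mean
    L = np.zeros((k, len(fe)))
    L[:, 0] = 1.0
    for i, lev in enumerate(levels[1:], start=1):
        L[i, _dummy_index(fe.index, treatment, lev)] = 1.0
    lsmeans = pd.Series(L @ fe.to_numpy(), index=levels, name="lsmean")

    n = len(df)
    ddf = max(n - k - (len(donors) - 1), 1)
    pairs = list(itertools.combinations(levels, 2))
    rows = []
    for a, b in pairs:
        c = L[levels.index(a)] - L[levels.index(b)]
        est = float(c @ fe.to_numpy())
        se = float(np.sqrt(c @ cov @ c))
        tval = est / se if se > 0 else np.nan
        p = 2.0 * stats.t.sf(abs(tval), ddf)
        if adjust == "tukey":
            q = abs(tval) * np.sqrt(2.0)
            p_adj = float(stats.studentized_range.sf(q, k, ddf))
        else:
            p_adj = min(1.0, p * len(pairs))
        rows.append(
            {
                "contrast": f"{a}-{b}",
                "estimate": est,
                "se": se,
                "df": ddf,
                "t": tval,
                "p": p,
                "p_adj": p_adj,
            }
        )
    return LMMResult(
        lsmeans=lsmeans,
        contrasts=pd.DataFrame(rows),
        donor_var=donor_var,
        resid_var=resid_var,
        singular=singular,
        adjust=adjust,
    )


def _dummy_index(index: pd.Index, treatment: str, level: str) -> int:
    """Position of the patsy dummy column for a treatment level."""
    key = f"C({treatment})[T.{level}]"
    for i, name in enumerate(index):
        if name == key:
            return i
    raise InputError(f"design column for level {level!r} not found")
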