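"""Preranked permutation enrichment and hypergeometric over-representation.

The preranked statistic is the weighted Kolmogorov-Smirnov running sum:
walking down the score-ranked feature list, members of the tested set ("hits")
increment the sum in proportion to |score|^p (normalized over the set's hits)
and non-members decrement it by 1/(N - |S|); the enrichment score (ES) is the
maximum signed deviation. The null distribution permutes the score-to-feature
assignment, which for this statistic is equivalent to drawing random hit
positions of the same set size.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .differential import adjust_bh
from .errors import InputError

logger = logging.getLogger(__name__)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from GMT (name <tab> description <tab> members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {m for m in parts[2:] if m}
    return sets


def write_gmt(sets: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{members}\n")


def _running_sum_es(
    hit_pos: np.ndarray, hit_weight: np.ndarray, n: int
) -> float:
    """Signed max deviation of the running sum.

    ``hit_pos`` are sorted 0-based ranks of the set members in the ranked
    list; ``hit_weight`` their (unnormalized) increments. Extremes of the
    running sum occur immediately after a hit (local max candidates) or just
    before one (local min candidates), so only 2|S| points are evaluated.
    """
    s = hit_pos.size
    if s == 0 or s == n:
        raise InputError("set must be a proper non-empty subset of the universe")
    wsum = hit_weight.sum()
    if wsum <= 0:
        # all-zero scores inside the set: hits contribute equal steps
        hit_weight = np.ones(s)
        wsum = float(s)
    cum_hits = np.cumsum(hit_weight) / wsum
    miss_step = 1.0 / (n - s)
    idx = np.arange(1, s + 1)
    after = cum_hits - miss_step * (hit_pos + 1 - idx)
    before = np.concatenate(([0.0], cum_hits[:-1])) - miss_step * (hit_pos - idx + 1)
    hi = after.max()
    lo = min(before.min(), 0.0)
    return float(hi if hi >= -lo else lo)


def enrichment_score(
    ranked_ids: Sequence[str],
    scores: np.ndarray,
    members: set[str],
    p: float = 1.0,
) -> float:
    """ES of ``members`` in a score-ranked list (descending)."""
    hit_mask = np.fromiter((f in members for f in ranked_ids), bool, len(ranked_ids))
    hit_pos = np.where(hit_mask)[0]
    weights = np.abs(scores[hit_pos]) ** p if p > 0 else np.ones(hit_pos.size)
    return _running_sum_es(hit_pos, weights, len(ranked_ids))


def preranked_enrichment(
    scores: pd.Series,
    sets: Mapping[str, set[str]],
    n_perm: int = 1000,
    p: float = 1.0,
    min_size: int = 5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation enrichment of each set against a ranked score vector.

    Returns per set: size in universe, ES, NES (ES normalized by the mean of
    same-sign permutation ES), and the permutation p-value (fraction of
    same-sign null ES at least as extreme). Deterministic under a fixed seed.
    """
    if seed is None:
        raise InputError("seed is required for the permutation null")
    if not np.isfinite(scores).all():
        raise InputError("scores must be finite")
    ranked = scores.sort_values(ascending=False, kind="mergesort")
    # secondary deterministic tie-break on id
    ranked = ranked.loc[
        sorted(ranked.index, key=lambda f: (-ranked[f], str(f)))
    ]
    ids = list(ranked.index)
    vals = ranked.to_numpy(dtype=float)
    n = len(ids)
    universe = set(ids)
    rng = np.random.default_rng(seed)
    abs_p = np.abs(vals) ** p if p > 0 else np.ones(n)

    rows = []
    for name in sorted(sets):
        members = sets[name] & universe
        if len(members) == 0:
            logger.warning("set %s disjoint from universe; skipped", name)
            continue
        if len(members) < min_size or len(members) == n:
            continue
        es = enrichment_score(ids, vals, members, p=p)
        s = len(members)
        null = np.empty(n_perm)
        for b in range(n_perm):
            pos = np.sort(rng.choice(n, size=s, replace=False))
            null[b] = _running_sum_es(pos, abs_p[pos], n)
        same = null[null >= 0] if es >= 0 else null[null < 0]
        if same.size == 0:
            pval, nes = 1.0, np.nan
        else:
            pval = float((np.abs(same) >= abs(es)).mean())
            nes = float(es / np.abs(same).mean())
        rows.append(
            {
                "set": name,
                "size": s,
                "es": es,
                "nes": nes,
                "p_value": pval,
            }
        )
    return pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p_value"])


def ora_hypergeom(
    selected: set[str],
    universe: set[str],
    sets: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Hypergeometric over-representation of each set in a selection.

    Upper-tail p for the observed overlap between ``selected`` and each set
    (both intersected with ``universe``), fold enrichment relative to the
    universe frequency, and BH q across sets.
    """
    if not selected:
        raise InputError("selection is empty")
    if not selected <= universe:
        raise InputError("selected ids must be a subset of the universe")
    big_n = len(universe)
    n_sel = len(selected)
    rows = []
    for name in sorted(sets):
        members = sets[name] & universe
        if not members:
            continue
        k = len(selected & members)
        pval = float(stats.hypergeom.sf(k - 1, big_n, len(members), n_sel))
        fold = (k / n_sel) / (len(members) / big_n)
        rows.append(
            {
                "set": name,
                "set_size": len(members),
                "overlap": k,
                "fold_enrichment": fold,
                "p_value": pval,
            }
        )
    out = pd.DataFrame(
        rows, columns=["set", "set_size", "overlap", "fold_enrichment", "p_value"]
    )
    if len(out):
        out["fdr_q"] = adjust_bh(out["p_value"].to_numpy())
    else:
        out["fdr_q"] = []
    return out
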