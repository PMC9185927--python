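"""Moderated differential abundance for the four treatment comparisons.

Fits per-peptide linear models (treatment + batch) on the imputed log2 media
matrix, shrinks residual variances by empirical Bayes, and reports moderated
t statistics with BH FDR for D/N, IC/N, ICD/N and ICD/IC. Also classifies
features present in only one or two treatment conditions from the raw mask.
"""

from pathlib import Path

from ocproteo import differential as diff
from ocproteo import preprocess as pp
from ocproteo.matrix import AbundanceMatrix
from ocproteo.simulate import read_peptide_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    log2 = AbundanceMatrix.read_tsv(
        ROOT / "processed" / "media_peptides_log2.tsv",
        ROOT / "processed" / "media_samples.tsv",
    )
    fit = diff.fit_feature_models(log2, include_batch=True)
    res = diff.moderated_contrasts(fit)

    raw, _ = read_peptide_table(
        ROOT / "experiment" / "peptides.tsv", ROOT / "experiment" / "samples.tsv"
    )
    media_raw = pp.filter_features(raw.select_compartment("media"), 0.0)
    uniq = diff.condition_unique(media_raw)

    out = ROOT / "differential"
    out.mkdir(parents=True, exist_ok=True)
    res.to_csv(out / "contrasts_peptides.tsv", sep="\t", index=False)
    uniq.to_csv(out / "condition_unique.tsv", sep="\t", index=False)

    prior_df = res["prior_df"].iloc[0]
    print(f"empirical-Bayes prior: d0={prior_df:.2f}, "
          f"s0^2={res['prior_var'].iloc[0]:.3f}")
    for label, grp in res.groupby("contrast"):
        n_sig = int((grp["fdr_q"] < 0.05).sum())
        print(f"  {label}: {n_sig} peptides at q<0.05 of {len(grp)}")
    print(f"{len(uniq)} peptides detected in only 1-2 conditions")
    print(f"tables written under {out}")


if __name__ == "__main__":
    main()
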