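"""Permutation enrichment over the attenuation-ranked protein list.

Builds the protein-level PLSR ranking against per-donor Dex attenuation,
synthesizes annotation sets (random groupings plus the set of proteins
carrying planted peptides), and runs preranked permutation enrichment
(1000 permutations) and the hypergeometric over-representation test on the
significant IC/N proteins.
"""

from pathlib import Path

import pandas as pd

from ocproteo import biochem as bio
from ocproteo import differential as diff
from ocproteo import enrichment as enr
from ocproteo import preprocess as pp
from ocproteo.matrix import AbundanceMatrix
from ocproteo.pipeline import rank_against_response, synthetic_gene_sets
from ocproteo.simulate import read_peptide_table

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20220610


def main() -> None:
    prot_log2 = AbundanceMatrix.read_tsv(
        ROOT / "processed" / "media_proteins_log2.tsv",
        ROOT / "processed" / "media_protein_samples.tsv",
    )
    prot_corr = pp.remove_batch(pp.scale_features(prot_log2))
    biochem = pd.read_csv(ROOT / "experiment" / "biochem.tsv", sep="\t")
    att = bio.attenuation_by_donor(biochem)["attenuation_pct"].dropna()
    treatments = sorted(prot_corr.sample_meta["treatment"].unique())
    response = pd.Series(
        {(d, t): att[d] for d in att.index for t in treatments}
    )
    keep = prot_corr.sample_meta.index[
        prot_corr.sample_meta["donor"].isin(att.index)
    ]
    prot_corr = prot_corr.subset_samples(keep)
    ranked, _ = rank_against_response(
        prot_corr, prot_corr.feature_ids, response,
        top_n=len(prot_corr.feature_ids),
    )
    scores = pd.Series(ranked["dot_score"].to_numpy(),
                       index=ranked["feature_id"])

    truth = pd.read_csv(
        ROOT / "experiment" / "ground_truth.tsv", sep="\t", index_col=0
    )
    planted_prots = set(truth.loc[truth["planted"], "protein_accession"])
    sets = synthetic_gene_sets(list(scores.index), planted_prots, SEED)
    gsea = enr.preranked_enrichment(scores, sets, n_perm=1000, seed=SEED)

    # over-representation: proteins carrying >= 1 significant IC/N peptide
    pep_log2 = AbundanceMatrix.read_tsv(
        ROOT / "processed" / "media_peptides_log2.tsv",
        ROOT / "processed" / "media_samples.tsv",
    )
    fit = diff.fit_feature_models(pep_log2, include_batch=True)
    contrasts = diff.moderated_contrasts(fit, [("IC", "N")])
    pep2prot = truth["protein_accession"]
    universe = set(pep2prot.loc[contrasts["feature_id"]].unique())
    sig_peps = contrasts.loc[contrasts["fdr_q"] < 0.05, "feature_id"]
    sig = set(pep2prot.loc[sig_peps].unique())
    ora = enr.ora_hypergeom(sig, universe, sets) if sig else pd.DataFrame()

    out = ROOT / "enrichment"
    out.mkdir(parents=True, exist_ok=True)
    gsea.to_csv(out / "gsea_attenuation.tsv", sep="\t", index=False)
    ora.to_csv(out / "ora_ic_vs_control.tsv", sep="\t", index=False)

    print(f"{len(gsea)} sets tested by permutation enrichment")
    hits = gsea[gsea["p_value"] < 0.05]
    print(f"  {len(hits)} sets at p<0.05:",
          ", ".join(hits["set"]) if len(hits) else "(none)")
    if len(ora):
        top = ora.sort_values("p_value").iloc[0]
        print(f"strongest over-representation: {top['set']} "
              f"(overlap {int(top['overlap'])}, q={top['fdr_q']:.2e})")
    print(f"tables written under {out}")


if __name__ == "__main__":
    main()
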