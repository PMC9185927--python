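"""PLSR biomarker ranking against sGAG loss and Dex attenuation.

Re-derives terminus classes from the peptide sequences, averages the
batch-corrected media abundances over replicates per donor x treatment, fits
two-component PLS1 models against (a) per-donor-and-treatment total percent
sGAG loss for the semitryptic peptides and (b) per-donor Dex attenuation for
the protein matrix, and ranks features by the loading dot-product score.
Reports recall of the generator's planted peptides among the top 50.
"""

from pathlib import Path

import pandas as pd

from ocproteo import biochem as bio
from ocproteo.matrix import AbundanceMatrix
from ocproteo.peptides import annotate_peptides, read_fasta
from ocproteo.pipeline import rank_against_response
from ocproteo.simulate import read_peptide_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    corrected = AbundanceMatrix.read_tsv(
        ROOT / "processed" / "media_peptides_corrected.tsv",
        ROOT / "processed" / "media_samples_corrected.tsv",
    )
    _, info = read_peptide_table(
        ROOT / "experiment" / "peptides.tsv", ROOT / "experiment" / "samples.tsv"
    )
    proteins = {
        p.accession: p
        for p in read_fasta(ROOT / "experiment" / "proteins.fasta",
                            ROOT / "experiment" / "domains.tsv")
    }
    ann = annotate_peptides(
        info["sequence"].to_dict(),
        info["protein_accession"].to_dict(),
        proteins,
    )
    semi = [
        f for f in corrected.feature_ids
        if f in ann.index
        and str(ann.loc[f, "terminus_class"]).startswith("semi_tryptic")
    ]
    biochem = pd.read_csv(ROOT / "experiment" / "biochem.tsv", sep="\t")
    losses = bio.donor_loss_table(biochem)
    ranked, _ = rank_against_response(corrected, semi, losses.stack(), top_n=50)
    ranked = ranked.join(ann[["protein", "start", "domain"]], on="feature_id")

    out = ROOT / "ranking"
    out.mkdir(parents=True, exist_ok=True)
    ranked.to_csv(out / "ranked_semitryptic_sgag.tsv", sep="\t", index=False)

    truth = pd.read_csv(
        ROOT / "experiment" / "ground_truth.tsv", sep="\t", index_col=0
    )
    planted = set(truth.index[truth["planted"]])
    recall = len(set(ranked["feature_id"]) & planted) / max(len(planted), 1)
    print(f"{len(semi)} semitryptic peptides ranked against sGAG loss")
    print(f"planted-peptide recall in top 50: {100 * recall:.0f}%")
    top_prots = ranked.head(50)["protein"].value_counts().head(5)
    print("most represented proteins in the top 50:")
    print(top_prots.to_string())
    print(f"tables written under {out}")


if __name__ == "__main__":
    main()
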