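"""Filter, impute, scale and batch-correct the simulated media peptide table.

Reads results/experiment/ (from 01_simulate.py), applies the 70% presence
filter, log2 transform, kNN imputation (k=10), per-feature standardization
and batch correction, and rolls peptides up to proteins with the top-3
unique-peptide rule. Writes processed matrices under results/processed/.
"""

from pathlib import Path

from ocproteo import preprocess as pp
from ocproteo.peptides import rollup_protein
from ocproteo.simulate import read_peptide_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    matrix, info = read_peptide_table(
        ROOT / "experiment" / "peptides.tsv", ROOT / "experiment" / "samples.tsv"
    )
    media = matrix.select_compartment("media")
    filtered = pp.filter_features(media, min_frac=0.70)
    print(f"presence filter: {media.n_features} -> {filtered.n_features} peptides")
    log2 = pp.knn_impute(pp.log2_transform(filtered), k=10)
    scaled = pp.scale_features(log2)
    corrected = pp.remove_batch(scaled)

    prot = rollup_protein(media, info["protein_accession"].to_dict())
    prot_filtered = pp.filter_features(prot, min_frac=0.70)
    prot_log2 = pp.knn_impute(pp.log2_transform(prot_filtered), k=10)
    print(f"protein roll-up: {prot.n_features} proteins, "
          f"{prot_filtered.n_features} after filtering")

    out = ROOT / "processed"
    out.mkdir(parents=True, exist_ok=True)
    log2.to_tsv(out / "media_peptides_log2.tsv", out / "media_samples.tsv")
    corrected.to_tsv(out / "media_peptides_corrected.tsv",
                     out / "media_samples_corrected.tsv")
    prot_log2.to_tsv(out / "media_proteins_log2.tsv",
                     out / "media_protein_samples.tsv")
    print(f"processed matrices written under {out}")


if __name__ == "__main__":
    main()
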