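"""Generate the synthetic osteochondral experiment used by the later steps.

Writes the protein FASTA, domain sidecar, peptide abundance table, sample
metadata, biochemistry table and ground-truth annotations under
results/experiment/, at the default study conditions: 7 donors, 4 treatment
arms (N, D, IC, ICD), 3 replicates, two media batches, 20 planted
severity-associated semitryptic peptides.
"""

from pathlib import Path

from ocproteo.simulate import SimConfig, generate_experiment, write_experiment

SEED = 20220610
OUT = Path(__file__).resolve().parent.parent / "results" / "experiment"


def main() -> None:
    cfg = SimConfig(seed=SEED)
    exp = generate_experiment(cfg)
    paths = write_experiment(exp, OUT)
    media = exp.matrix.select_compartment("media")
    print(f"simulated {exp.matrix.n_features} peptides "
          f"({len(exp.truth.semitryptic_ids)} semitryptic, "
          f"{len(exp.truth.planted_feature_ids)} planted) "
          f"over {media.n_samples} media + "
          f"{exp.matrix.n_samples - media.n_samples} tissue samples")
    frac = exp.matrix.missing_mask.to_numpy().mean()
    print(f"overall missingness {100 * frac:.1f}% "
          f"(target {100 * cfg.missing_total_frac:.0f}%)")
    for name, p in paths.items():
        print(f"  {name}: {p.relative_to(OUT.parent.parent)}")


if __name__ == "__main__":
    main()
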