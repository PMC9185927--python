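"""Synthetic osteochondral-explant experiments with known ground truth.

Emulates the structure of a 21-day human osteochondral explant study: seven
donors, four treatment arms (untreated N, dexamethasone D, injury+cytokines
IC, injury+cytokines+dexamethasone ICD), three biological replicates, media
and tissue compartments, and a two-batch media collection. The generator
plants severity-associated semitryptic peptides and per-donor sGAG-loss
trajectories with donor-specific dexamethasone attenuation, so every
downstream stage can be validated against a known truth.

Intensities are log-normal (normal on the log2 scale): per feature,

    log2 y = baseline + donor effect + batch offset (media batch 2 only)
             + treatment effect (planted features only) + residual

with the IC arm of planted features shifted by ``effect_size_ic`` and the ICD
arm by ``effect_size_ic * (1 - attenuation_true/100)``. Missingness is a
mixture of completely-at-random dropout and probit left-censoring of low
intensities, mixed by ``censor_weight``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError
from .matrix import META_COLUMNS, SCALE_RAW, TREATMENTS, AbundanceMatrix
from .peptides import (
    ProteinRecord,
    TerminusClass,
    classify_termini,
    digest,
    write_domains,
    write_fasta,
)

#: media collection days: every 2-3 days across the 21-day culture
COLLECTION_DAYS = (2, 5, 7, 9, 12, 14, 16, 19, 21)


@dataclasses.dataclass
class SimConfig:
    """Conditions of a simulated experiment.

    Effect and noise scales are in log2-intensity units; sGAG quantities are
    percent losses. Defaults reproduce the study conditions: 7 donors x 4
    treatments x 3 replicates, two media batches, ~20% control sGAG loss
    rising to ~54% under injury+cytokines, with dexamethasone attenuating
    two-thirds of the excess loss.
    """

    n_donors: int = 7
    treatments: tuple[str, ...] = TREATMENTS
    n_replicates: int = 3
    n_proteins: int = 40
    peptides_per_protein: tuple[int, int] = (10, 15)
    n_batches: int = 2
    tissue_donors: int = 4
    donor_sd: float = 0.5
    batch_sd: float = 0.5
    residual_sd: float = 0.4
    baseline_mean: float = 20.0
    baseline_sd: float = 2.5
    effect_size_ic: float = 2.0
    n_planted_semitryptic: int = 20
    n_background_semitryptic: int = 80
    missing_total_frac: float = 0.10
    censor_weight: float = 0.5
    sgag_baseline_pct: float = 20.0
    sgag_ic_pct: float = 54.0
    attenuation_true: float = 66.7
    donor_pct_sd: float = 3.0
    donor_attenuation_sd: float = 10.0
    sgag_noise_sd: float = 1.5
    seed: int | None = None

    def __post_init__(self) -> None:
        for field in ("missing_total_frac", "censor_weight"):
            v = getattr(self, field)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{field} must be in [0,1], got {v}")
        for field in (
            "n_donors",
            "n_replicates",
            "n_proteins",
            "n_batches",
            "tissue_donors",
            "n_planted_semitryptic",
            "n_background_semitryptic",
        ):
            v = getattr(self, field)
            if v < 0 or (field in ("n_donors", "n_replicates", "n_proteins") and v < 1):
                raise ConfigurationError(f"{field} must be positive, got {v}")
        for field in ("donor_sd", "batch_sd", "residual_sd", "donor_pct_sd",
                      "donor_attenuation_sd", "sgag_noise_sd"):
            if getattr(self, field) < 0:
                raise ConfigurationError(f"{field} must be >= 0")
        if self.sgag_ic_pct <= self.sgag_baseline_pct:
            raise ConfigurationError(
                "sgag_ic_pct must exceed sgag_baseline_pct "
                f"({self.sgag_ic_pct} <= {self.sgag_baseline_pct})"
            )
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ConfigurationError(
                f"peptides_per_protein range invalid: ({lo},{hi})"
            )
        if self.tissue_donors > self.n_donors:
            raise ConfigurationError("tissue_donors exceeds n_donors")

    @property
    def donors(self) -> list[str]:
        return [f"D{i + 1:02d}" for i in range(self.n_donors)]


@dataclasses.dataclass
class GroundTruth:
    """Planted truth of a simulated peptide table."""

    planted_feature_ids: tuple[str, ...]
    association_sign: pd.Series  # +1/-1 per planted feature
    semitryptic_ids: tuple[str, ...]
    donor_effects: pd.DataFrame  # features x donors, log2 units
    batch_offsets: pd.Series  # per feature, log2 units (media batch 2)
    true_log2: pd.DataFrame  # complete pre-missingness log2 matrix


@dataclasses.dataclass
class SimulatedExperiment:
    config: SimConfig
    proteins: list[ProteinRecord]
    matrix: AbundanceMatrix  # raw scale, NaN where missing
    peptide_info: pd.DataFrame  # sequence, modifications, protein, start, class
    truth: GroundTruth
    biochem: pd.DataFrame  # long-format biochemistry table
    donor_attenuation_pct: pd.Series  # true per-donor attenuation


# ---------------------------------------------------------------------------
# proteins

_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# K and R at >=5% each so tryptic digestion yields usable peptides; P kept low
_RES_P = np.array(
    [0.05, 0.02, 0.05, 0.06, 0.04, 0.07, 0.02, 0.05, 0.06, 0.09,
     0.02, 0.04, 0.04, 0.04, 0.06, 0.07, 0.05, 0.06, 0.01, 0.03]
)
_RES_P = _RES_P / _RES_P.sum()


def generate_proteins(config: SimConfig, seed: int | None = None) -> list[ProteinRecord]:
    """Random proteins (length 100-1500) with disjoint domain annotations."""
    rng = np.random.default_rng(_resolve_seed(config, seed))
    proteins = []
    for i in range(config.n_proteins):
        acc = f"SYN{i + 1:04d}"
        while True:
            length = int(rng.integers(300, 801))
            seq = "".join(rng.choice(_RESIDUES, size=length, p=_RES_P))
            if len(digest(ProteinRecord(acc, seq), 0, 6, 30)) >= 2:
                break
        n_dom = int(rng.integers(1, 4))
        # carve domains out of equal thirds so they never overlap
        domains = []
        seg = length // 3
        for d in range(n_dom):
            lo = d * seg + 1
            hi = (d + 1) * seg
            width = int(rng.integers(20, max(21, seg // 2 + 1)))
            start = int(rng.integers(lo, max(lo + 1, hi - width)))
            domains.append((f"G{d + 1}", start, min(start + width, hi)))
        proteins.append(ProteinRecord(acc, seq, tuple(domains)))
    return proteins


def _resolve_seed(config: SimConfig, seed: int | None) -> int:
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ConfigurationError("seed is required: set SimConfig.seed or pass seed=")
    return int(seed)


# ---------------------------------------------------------------------------
# sample layout


def media_sample_table(config: SimConfig) -> pd.DataFrame:
    """Media samples: all donors, with the donor panel split into two batches."""
    cut = (config.n_donors + 1) // 2
    rows = []
    for di, donor in enumerate(config.donors):
        batch = "b1" if (di < cut or config.n_batches < 2) else "b2"
        for trt in config.treatments:
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"M_{donor}_{trt}_r{rep}",
                        "donor": donor,
                        "treatment": trt,
                        "batch": batch,
                        "compartment": "media",
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def tissue_sample_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    for donor in config.donors[: config.tissue_donors]:
        for trt in config.treatments:
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"T_{donor}_{trt}_r{rep}",
                        "donor": donor,
                        "treatment": trt,
                        "batch": "b1",
                        "compartment": "tissue",
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# peptide table


def _make_semitryptic(
    rng: np.random.Generator,
    proteins: list[ProteinRecord],
    existing: set[tuple[str, str]],
) -> tuple[str, str, int] | None:
    """Truncate a random tryptic peptide into a semitryptic one.

    Returns (sequence, accession, start) or None if no attempt succeeded.
    """
    for _ in range(200):
        prot = proteins[int(rng.integers(len(proteins)))]
        peps = [p for p in digest(prot, 0, 6, 30) if len(p.sequence) >= 9]
        if not peps:
            continue
        pep = peps[int(rng.integers(len(peps)))]
        cut = int(rng.integers(1, 4))
        if rng.random() < 0.5:  # trim N side -> tryptic C terminus remains
            seq, start = pep.sequence[cut:], pep.start + cut
        else:  # trim C side
            seq, start = pep.sequence[:-cut], pep.start
        cls = classify_termini(seq, start, prot)
        if cls in (TerminusClass.SEMI_TRYPTIC_N, TerminusClass.SEMI_TRYPTIC_C):
            if (prot.accession, seq) not in existing:
                return seq, prot.accession, start
    return None


def generate_peptide_table(
    proteins: list[ProteinRecord],
    config: SimConfig,
    seed: int | None = None,
) -> tuple[AbundanceMatrix, pd.DataFrame, GroundTruth]:
    """Simulate a peptide-level abundance matrix over media + tissue samples.

    Returns ``(matrix, peptide_info, truth)``: the raw-scale matrix with NaN
    missingness, the per-peptide annotation frame (sequence, modifications,
    master protein, start, terminus class), and the planted ground truth.
    """
    if not proteins:
        raise ConfigurationError("proteins must be non-empty")
    rng = np.random.default_rng(_resolve_seed(config, seed))

    # -- tryptic peptide panel
    info_rows = []
    for prot in proteins:
        peps = digest(prot, 0, 6, 30)
        lo, hi = config.peptides_per_protein
        n_take = min(len(peps), int(rng.integers(lo, hi + 1)))
        idx = np.sort(rng.choice(len(peps), size=n_take, replace=False))
        for p in (peps[i] for i in idx):
            info_rows.append(
                {
                    "sequence": p.sequence,
                    "protein_accession": p.protein_accession,
                    "start": p.start,
                    "terminus_class": p.terminus_class.value,
                    "planted": False,
                }
            )

    # -- semitryptic peptides (planted + background), made by truncation
    existing = {(r["protein_accession"], r["sequence"]) for r in info_rows}
    n_semi = config.n_planted_semitryptic + config.n_background_semitryptic
    semi_rows = []
    for j in range(n_semi):
        made = _make_semitryptic(rng, proteins, existing)
        if made is None:
            raise ConfigurationError(
                "could not generate enough semitryptic peptides; "
                "increase n_proteins"
            )
        seq, acc, start = made
        existing.add((acc, seq))
        prot = next(p for p in proteins if p.accession == acc)
        semi_rows.append(
            {
                "sequence": seq,
                "protein_accession": acc,
                "start": start,
                "terminus_class": classify_termini(seq, start, prot).value,
                "planted": j < config.n_planted_semitryptic,
            }
        )
    info_rows.extend(semi_rows)

    info = pd.DataFrame(info_rows)
    info.index = [f"pep{i + 1:05d}" for i in range(len(info))]
    info["modifications"] = [
        "Carbamidomethyl(C)" if "C" in s else "" for s in info["sequence"]
    ]
    planted_ids = tuple(info.index[info["planted"]])
    semi_ids = tuple(
        info.index[info["terminus_class"].str.startswith("semi_tryptic")]
    )

    # -- sample layout
    meta = pd.concat([media_sample_table(config), tissue_sample_table(config)])
    n_feat, n_samp = len(info), len(meta)
    donors = config.donors

    # -- log2 intensity model
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n_feat)
    baseline[info["planted"].to_numpy()] = rng.normal(
        config.baseline_mean - 2.0, 1.0, len(planted_ids)
    )
    donor_eff = rng.normal(0.0, config.donor_sd, (n_feat, len(donors)))
    batch_off = rng.normal(0.0, config.batch_sd, n_feat)

    donor_idx = meta["donor"].map({d: i for i, d in enumerate(donors)}).to_numpy()
    is_b2_media = (
        (meta["batch"] == "b2") & (meta["compartment"] == "media")
    ).to_numpy()
    trt = meta["treatment"].to_numpy()
    trt_shift = np.zeros(n_samp)
    trt_shift[trt == "IC"] = config.effect_size_ic
    trt_shift[trt == "ICD"] = config.effect_size_ic * (
        1.0 - config.attenuation_true / 100.0
    )

    log2 = (
        baseline[:, None]
        + donor_eff[:, donor_idx]
        + np.outer(batch_off, is_b2_media.astype(float))
        + np.outer(info["planted"].to_numpy(dtype=float), trt_shift)
        + rng.normal(0.0, config.residual_sd, (n_feat, n_samp))
    )

    # -- missingness: MCAR + probit left-censoring mixture
    p_miss = np.zeros_like(log2)
    if config.missing_total_frac > 0:
        z = (log2 - log2.mean()) / log2.std()
        censor = norm.cdf(-z)
        censor = censor / censor.mean()
        p_miss = config.missing_total_frac * (
            (1.0 - config.censor_weight) + config.censor_weight * censor
        )
        p_miss = np.clip(p_miss, 0.0, 1.0)
    mask = rng.random(log2.shape) < p_miss

    raw = np.power(2.0, log2)
    raw[mask] = np.nan
    values = pd.DataFrame(raw, index=info.index, columns=meta.index)
    matrix = AbundanceMatrix(values, meta[list(META_COLUMNS)].copy(), SCALE_RAW)

    truth = GroundTruth(
        planted_feature_ids=planted_ids,
        association_sign=pd.Series(1, index=list(planted_ids)),
        semitryptic_ids=semi_ids,
        donor_effects=pd.DataFrame(donor_eff, index=info.index, columns=donors),
        batch_offsets=pd.Series(batch_off, index=info.index),
        true_log2=pd.DataFrame(log2, index=info.index, columns=meta.index),
    )
    cols = ["sequence", "modifications", "protein_accession", "start",
            "terminus_class", "planted"]
    return matrix, info[cols], truth


# ---------------------------------------------------------------------------
# biochemistry


def expected_sgag_losses(config: SimConfig) -> pd.DataFrame:
    """Noise-free expected percent sGAG loss per treatment (formula limit)."""
    n = config.sgag_baseline_pct
    ic = config.sgag_ic_pct
    icd = ic - config.attenuation_true / 100.0 * (ic - n)
    return pd.DataFrame(
        {"treatment": ["N", "D", "IC", "ICD"], "pct_loss": [n, n, ic, icd]}
    ).set_index("treatment")


def generate_biochem(
    config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate the per-explant biochemistry table.

    Returns the long-format table (donor, treatment, explant_id, day,
    media_sgag_ug, tissue_sgag_ug, dna_ng, wet_weight_mg) and the true
    per-donor attenuation (%). Each explant has exactly one tissue record
    (final day); media amounts over the nine collection days sum with the
    tissue to give the targeted cumulative percent loss. IC-type arms release
    sGAG front-loaded; untreated arms release evenly.
    """
    rng = np.random.default_rng(_resolve_seed(config, seed))
    donors = config.donors
    att_d = pd.Series(
        rng.normal(config.attenuation_true, config.donor_attenuation_sd, len(donors)),
        index=donors,
        name="attenuation_pct",
    )
    days = np.array(COLLECTION_DAYS, dtype=float)
    w_flat = np.ones(len(days)) / len(days)
    w_front = 0.8 ** np.arange(len(days))
    w_front = w_front / w_front.sum()

    rows = []
    for donor in donors:
        l_n = config.sgag_baseline_pct + rng.normal(0, config.donor_pct_sd)
        l_ic = config.sgag_ic_pct + rng.normal(0, config.donor_pct_sd)
        l_d = l_n + rng.normal(0, config.donor_pct_sd / 3)
        l_icd = l_ic - att_d[donor] / 100.0 * (l_ic - l_n)
        targets = {"N": l_n, "D": l_d, "IC": l_ic, "ICD": l_icd}
        sgag_conc = max(5.0, rng.normal(30.0, 3.0))  # ug sGAG per mg tissue
        dna_mean = max(50.0, rng.normal(450.0, 40.0))
        for trt in config.treatments:
            for rep in range(1, config.n_replicates + 1):
                explant = f"{donor}:{trt}:r{rep}"
                loss = targets[trt] + rng.normal(0, config.sgag_noise_sd)
                loss = float(np.clip(loss, 0.5, 99.5))
                ww = max(5.0, rng.normal(25.0, 3.0))
                pool = ww * sgag_conc
                media_total = loss / 100.0 * pool
                tissue_final = pool - media_total
                dna = max(20.0, rng.normal(dna_mean, 30.0))
                w = w_front if trt in ("IC", "ICD") else w_flat
                for i, day in enumerate(days):
                    rows.append(
                        {
                            "donor": donor,
                            "treatment": trt,
                            "explant_id": explant,
                            "replicate": rep,
                            "day": int(day),
                            "media_sgag_ug": media_total * w[i],
                            "tissue_sgag_ug": tissue_final if day == days[-1] else np.nan,
                            "dna_ng": dna,
                            "wet_weight_mg": ww,
                        }
                    )
    return pd.DataFrame(rows), att_d


# ---------------------------------------------------------------------------
# whole experiment


def generate_experiment(config: SimConfig) -> SimulatedExperiment:
    """Generate proteins, peptide table and biochemistry from one seed.

    Stage seeds are spawned deterministically from ``config.seed``.
    """
    if config.seed is None:
        raise ConfigurationError("SimConfig.seed is required")
    ss = np.random.SeedSequence(config.seed)
    s_prot, s_pep, s_bio = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    proteins = generate_proteins(config, s_prot)
    matrix, info, truth = generate_peptide_table(proteins, config, s_pep)
    biochem, att = generate_biochem(config, s_bio)
    return SimulatedExperiment(config, proteins, matrix, info, truth, biochem, att)


def write_experiment(exp: SimulatedExperiment, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated experiment in the pipeline's file formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "proteins.fasta",
        "domains": outdir / "domains.tsv",
        "peptides": outdir / "peptides.tsv",
        "samples": outdir / "samples.tsv",
        "biochem": outdir / "biochem.tsv",
        "truth": outdir / "ground_truth.tsv",
        "attenuation": outdir / "true_attenuation.tsv",
    }
    write_fasta(exp.proteins, paths["fasta"])
    write_domains(exp.proteins, paths["domains"])
    table = pd.concat(
        [
            exp.peptide_info[["sequence", "modifications", "protein_accession"]],
            exp.matrix.values,
        ],
        axis=1,
    )
    table.rename_axis("peptide_id").to_csv(paths["peptides"], sep="\t", na_rep="")
    exp.matrix.sample_meta.rename_axis("sample_id").to_csv(paths["samples"], sep="\t")
    exp.biochem.to_csv(paths["biochem"], sep="\t", index=False, na_rep="")
    exp.peptide_info.rename_axis("peptide_id").to_csv(paths["truth"], sep="\t")
    exp.donor_attenuation_pct.rename_axis("donor").to_csv(paths["attenuation"], sep="\t")
    return paths


def read_peptide_table(
    peptides_path: str | Path, samples_path: str | Path
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Read a peptide table + sample metadata written by :func:`write_experiment`."""
    table = pd.read_csv(peptides_path, sep="\t", index_col=0)
    meta = pd.read_csv(samples_path, sep="\t", index_col=0)
    ann_cols = [c for c in ("sequence", "modifications", "protein_accession",
                            "start", "terminus_class", "planted") if c in table]
    info = table[ann_cols]
    values = table.drop(columns=ann_cols)
    values = values[list(meta.index)]
    return AbundanceMatrix(values, meta, SCALE_RAW), info
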