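"""In-silico trypsin digestion and semitryptic peptide classification.

Semitryptic peptides — peptides with one terminus that trypsin cannot have
produced — are evidence of endogenous protease activity in the explant and are
candidate disease biomarkers. Everything here shares a single cleavage rule:
trypsin cuts after K or R except when the next residue is proline, and the
protein's own termini always count as valid peptide boundaries.

Also provides positional domain mapping (e.g. aggrecan G1/G2/G3 globular
domains) and the top-3 unique-peptide protein roll-up used for label-free
protein quantification.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import warnings
from collections.abc import Mapping
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AmbiguousLocationError, InputError, PeptideLookupError
from .matrix import SCALE_RAW, AbundanceMatrix

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)
CLEAVAGE_RESIDUES = frozenset("KR")


class TerminusClass(str, enum.Enum):
    """Tryptic specificity of a peptide's two termini.

    For semitryptic peptides the *tryptic* side names the class:
    ``semi_tryptic_N`` has a tryptic N-terminus and a non-tryptic C-terminus.
    """

    FULLY_TRYPTIC = "fully_tryptic"
    SEMI_TRYPTIC_N = "semi_tryptic_N"
    SEMI_TRYPTIC_C = "semi_tryptic_C"
    NON_TRYPTIC = "non_tryptic"


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with optional domain annotations.

    Domains are (name, start, end) with 1-based closed intervals, pairwise
    disjoint and within the sequence.
    """

    accession: str
    sequence: str
    domains: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise InputError(f"{self.accession}: non-standard residues {sorted(bad)}")
        length = len(self.sequence)
        seen: list[tuple[int, int]] = []
        for name, start, end in self.domains:
            if not (1 <= start <= end <= length):
                raise InputError(
                    f"{self.accession}: domain {name} interval ({start},{end}) "
                    f"outside [1,{length}]"
                )
            for s, e in seen:
                if start <= e and s <= end:
                    raise InputError(f"{self.accession}: overlapping domains")
            seen.append((start, end))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class PeptideRecord:
    """An identified peptide located within its master protein."""

    sequence: str
    protein_accession: str
    start: int  # 1-based position of the first residue in the protein
    terminus_class: TerminusClass
    modifications: tuple[tuple[int, str], ...] = ()

    @property
    def end(self) -> int:
        """1-based position of the last residue."""
        return self.start + len(self.sequence) - 1


# ---------------------------------------------------------------------------
# digestion & classification


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices i such that trypsin cuts between i and i+1."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in CLEAVAGE_RESIDUES and sequence[i + 1] != "P"
    ]


def digest(
    protein: ProteinRecord,
    missed_cleavages: int = 0,
    min_len: int = 6,
    max_len: int = 30,
) -> list[PeptideRecord]:
    """Fully tryptic peptides of ``protein`` with up to ``missed_cleavages``.

    Peptides outside ``[min_len, max_len]`` are dropped. Every returned record
    carries its correct 1-based start and classifies ``fully_tryptic``.
    """
    if missed_cleavages < 0:
        raise InputError("missed_cleavages must be >= 0")
    seq = protein.sequence
    # fragment boundaries: [b_i, b_{i+1}) half-open, 0-based
    bounds = [0] + [i + 1 for i in cleavage_sites(seq)] + [len(seq)]
    out: list[PeptideRecord] = []
    for i in range(len(bounds) - 1):
        for mc in range(missed_cleavages + 1):
            j = i + 1 + mc
            if j >= len(bounds):
                break
            s, e = bounds[i], bounds[j]
            if min_len <= e - s <= max_len:
                out.append(
                    PeptideRecord(
                        sequence=seq[s:e],
                        protein_accession=protein.accession,
                        start=s + 1,
                        terminus_class=TerminusClass.FULLY_TRYPTIC,
                    )
                )
    return out


def locate(peptide_sequence: str, protein: ProteinRecord) -> int:
    """1-based position of the unique occurrence of the peptide.

    Raises :class:`PeptideLookupError` when absent and
    :class:`AmbiguousLocationError` (carrying all positions, overlaps included)
    when the sequence occurs more than once.
    """
    if not peptide_sequence:
        raise InputError("empty peptide sequence")
    positions = []
    at = protein.sequence.find(peptide_sequence)
    while at != -1:
        positions.append(at + 1)
        at = protein.sequence.find(peptide_sequence, at + 1)
    if not positions:
        raise PeptideLookupError(
            f"{peptide_sequence!r} not found in {protein.accession}"
        )
    if len(positions) > 1:
        raise AmbiguousLocationError(
            peptide_sequence, protein.accession, tuple(positions)
        )
    return positions[0]


def classify_termini(
    sequence: str, start: int, protein: ProteinRecord
) -> TerminusClass:
    """Tryptic specificity of a located peptide.

    N-terminus is tryptic iff the peptide begins the protein, or the preceding
    residue is K/R and the first peptide residue is not P. C-terminus is
    tryptic iff the peptide ends the protein, or its last residue is K/R and
    the following residue is not P.
    """
    end = start + len(sequence) - 1
    if start < 1 or end > len(protein.sequence):
        raise InputError(f"peptide [{start},{end}] outside {protein.accession}")
    if protein.sequence[start - 1 : end] != sequence:
        raise InputError(
            f"sequence does not match {protein.accession} at position {start}"
        )
    n_tryptic = start == 1 or (
        protein.sequence[start - 2] in CLEAVAGE_RESIDUES and sequence[0] != "P"
    )
    c_tryptic = end == len(protein.sequence) or (
        sequence[-1] in CLEAVAGE_RESIDUES and protein.sequence[end] != "P"
    )
    if n_tryptic and c_tryptic:
        return TerminusClass.FULLY_TRYPTIC
    if n_tryptic:
        return TerminusClass.SEMI_TRYPTIC_N
    if c_tryptic:
        return TerminusClass.SEMI_TRYPTIC_C
    return TerminusClass.NON_TRYPTIC


def map_domain(start: int, end: int, protein: ProteinRecord) -> str:
    """Domain containing the peptide midpoint, or ``"inter-domain"``.

    The midpoint residue is ``floor((start+end)/2)``; domain intervals are
    closed, so a midpoint landing exactly on a boundary residue belongs to that
    domain.
    """
    if not (1 <= start <= end <= len(protein.sequence)):
        raise InputError("peptide interval outside protein")
    mid = (start + end) // 2
    for name, s, e in protein.domains:
        if s <= mid <= e:
            return name
    return "inter-domain"


# ---------------------------------------------------------------------------
# protein roll-up


def rollup_protein(
    m: AbundanceMatrix,
    peptide_to_protein: Mapping[str, str],
    shared_peptides: frozenset | set = frozenset(),
) -> AbundanceMatrix:
    """Top-3 unique-peptide protein quantification.

    Per protein per sample: the mean of the three largest raw intensities
    among that protein's unique, quantified peptides; fewer than three present
    uses all present; none present leaves the cell missing. Peptides in
    ``shared_peptides`` (mapping to more than one protein) are excluded, as are
    peptides absent from the map.
    """
    m.require_scale(SCALE_RAW)
    groups: dict[str, list[str]] = {}
    for pep in m.feature_ids:
        if pep in shared_peptides:
            continue
        acc = peptide_to_protein.get(pep)
        if acc is None:
            continue
        groups.setdefault(acc, []).append(pep)
    rows = {}
    for acc in sorted(groups):
        block = m.values.loc[groups[acc]].to_numpy(dtype=float)
        # top-3 per sample among non-missing peptides
        vals = np.full(block.shape[1], np.nan)
        for j in range(block.shape[1]):
            col = block[:, j]
            col = col[~np.isnan(col)]
            if col.size:
                top = np.sort(col)[-3:]
                vals[j] = top.mean()
        rows[acc] = vals
    if not rows:
        raise InputError("no protein had any unique peptide")
    values = pd.DataFrame.from_dict(rows, orient="index", columns=m.sample_ids)
    return AbundanceMatrix(values, m.sample_meta.copy(), SCALE_RAW)


def annotate_peptides(
    peptide_seqs: Mapping[str, str],
    peptide_to_protein: Mapping[str, str],
    proteins: Mapping[str, ProteinRecord],
) -> pd.DataFrame:
    """Locate and classify a peptide table against its proteins.

    Returns a frame indexed by peptide id with columns ``protein``, ``start``,
    ``end``, ``terminus_class`` and ``domain``. Peptides with ambiguous
    locations are dropped with a logged warning rather than multiply counted.
    """
    records = {}
    n_ambiguous = 0
    for pid, seq in peptide_seqs.items():
        acc = peptide_to_protein.get(pid)
        if acc is None or acc not in proteins:
            continue
        prot = proteins[acc]
        try:
            start = locate(seq, prot)
        except AmbiguousLocationError:
            n_ambiguous += 1
            continue
        except PeptideLookupError:
            continue
        end = start + len(seq) - 1
        records[pid] = {
            "protein": acc,
            "start": start,
            "end": end,
            "terminus_class": classify_termini(seq, start, prot).value,
            "domain": map_domain(start, end, prot),
        }
    if n_ambiguous:
        logger.warning(
            "dropped %d peptides with ambiguous protein locations", n_ambiguous
        )
    return pd.DataFrame.from_dict(records, orient="index")


# ---------------------------------------------------------------------------
# io


def write_fasta(proteins: list[ProteinRecord], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.accession, description="")
        for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path, domains_path: str | Path | None = None) -> list[ProteinRecord]:
    """Read proteins; optional sidecar TSV (accession, domain_name, start, end)."""
    domains: dict[str, list[tuple[str, int, int]]] = {}
    if domains_path is not None:
        tab = pd.read_csv(domains_path, sep="\t")
        for _, row in tab.iterrows():
            domains.setdefault(row["accession"], []).append(
                (str(row["domain_name"]), int(row["start"]), int(row["end"]))
            )
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # Biopython partial-line warnings
        for rec in SeqIO.parse(str(path), "fasta"):
            out.append(
                ProteinRecord(
                    accession=rec.id,
                    sequence=str(rec.seq).upper(),
                    domains=tuple(domains.get(rec.id, ())),
                )
            )
    return out


def write_domains(proteins: list[ProteinRecord], path: str | Path) -> None:
    rows = [
        {"accession": p.accession, "domain_name": name, "start": s, "end": e}
        for p in proteins
        for name, s, e in p.domains
    ]
    pd.DataFrame(rows, columns=["accession", "domain_name", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )
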