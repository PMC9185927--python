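"""Feature x sample abundance container with sample metadata.

The matrix holds peptide- or protein-level label-free quantification values.
Missing quantifications are ``NaN`` in ``values``; the boolean mask is derived,
never stored separately, so the two can not drift apart. A ``scale_tag``
records where the matrix sits in the raw -> log2 -> log2_scaled progression and
every operation declares which scale it accepts.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

SCALE_RAW = "raw"
SCALE_LOG2 = "log2"
SCALE_LOG2_SCALED = "log2_scaled"
_SCALES = (SCALE_RAW, SCALE_LOG2, SCALE_LOG2_SCALED)

#: required per-sample metadata columns
META_COLUMNS = ("donor", "treatment", "batch", "compartment", "replicate")

TREATMENTS = ("N", "D", "IC", "ICD")


@dataclasses.dataclass
class AbundanceMatrix:
    """Features x samples intensity matrix plus aligned sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample id.
        ``NaN`` marks a missing (unquantified) cell.
    sample_meta
        DataFrame indexed by sample id with columns ``donor``, ``treatment``,
        ``batch``, ``compartment`` and ``replicate``, in the same order as the
        columns of ``values``.
    scale_tag
        One of ``raw``, ``log2`` or ``log2_scaled``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    scale_tag: str = SCALE_RAW

    def __post_init__(self) -> None:
        if self.scale_tag not in _SCALES:
            raise InputError(f"unknown scale_tag {self.scale_tag!r}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise InputError(f"duplicate feature ids: {dupes[:5]}")
        if self.values.columns.duplicated().any():
            raise InputError("duplicate sample ids")
        missing_meta = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing_meta:
            raise InputError(f"sample_meta lacks columns {missing_meta}")
        if list(self.sample_meta.index) != list(self.values.columns):
            raise InputError("sample_meta index must match value columns in order")

    # -- views -------------------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean frame, True where the cell is missing."""
        return self.values.isna()

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.values.copy(), self.sample_meta.copy(), self.scale_tag
        )

    def require_scale(self, *tags: str) -> None:
        if self.scale_tag not in tags:
            raise InputError(
                f"operation requires scale {tags}, matrix is {self.scale_tag!r}"
            )

    # -- subsetting --------------------------------------------------------

    def subset_features(self, ids: Sequence[str]) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.values.loc[list(ids)], self.sample_meta.copy(), self.scale_tag
        )

    def subset_samples(self, ids: Iterable[str]) -> "AbundanceMatrix":
        ids = list(ids)
        return AbundanceMatrix(
            self.values[ids], self.sample_meta.loc[ids], self.scale_tag
        )

    def select_compartment(self, compartment: str) -> "AbundanceMatrix":
        keep = self.sample_meta.index[self.sample_meta["compartment"] == compartment]
        if len(keep) == 0:
            raise InputError(f"no samples in compartment {compartment!r}")
        return self.subset_samples(keep)

    # -- io ----------------------------------------------------------------

    def to_tsv(self, values_path: str | Path, meta_path: str | Path,
               header_comment: str | None = None) -> None:
        """Write the matrix and its metadata as TSV (NaN written as empty)."""
        values_path, meta_path = Path(values_path), Path(meta_path)
        with open(values_path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write(f"# scale_tag={self.scale_tag}\n")
            self.values.rename_axis("feature_id").to_csv(fh, sep="\t", na_rep="")
        with open(meta_path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.sample_meta.rename_axis("sample_id").to_csv(fh, sep="\t")

    @classmethod
    def read_tsv(cls, values_path: str | Path, meta_path: str | Path) -> "AbundanceMatrix":
        values = pd.read_csv(values_path, sep="\t", comment="#", index_col=0)
        scale = SCALE_RAW
        with open(values_path) as fh:
            for line in fh:
                if line.startswith("# scale_tag="):
                    scale = line.strip().split("=", 1)[1]
                if not line.startswith("#"):
                    break
        meta = pd.read_csv(meta_path, sep="\t", comment="#", index_col=0)
        n_zero = int((values == 0).sum().sum())
        if n_zero:
            import warnings

            warnings.warn(
                f"{n_zero} zero intensities read as observed values, not missing",
                stacklevel=2,
            )
        meta = meta.loc[values.columns]
        return cls(values, meta, scale)


def observed_counts(m: AbundanceMatrix) -> pd.Series:
    """Number of samples in which each feature is quantified."""
    return m.values.notna().sum(axis=1)


def check_complete(m: AbundanceMatrix) -> None:
    if m.values.isna().any().any():
        n = int(m.values.isna().sum().sum())
        raise InputError(f"matrix has {n} missing cells; impute first")


def as_float_array(m: AbundanceMatrix) -> np.ndarray:
    return m.values.to_numpy(dtype=float)
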