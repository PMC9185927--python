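"""Exception types shared across the pipeline."""


class OcproteoError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OcproteoError, ValueError):
    """An invalid parameter value; the message names the offending field."""


class InputError(OcproteoError, ValueError):
    """Malformed or inconsistent input data."""


class PeptideLookupError(OcproteoError, KeyError):
    """A peptide sequence was not found in its claimed parent protein."""


class AmbiguousLocationError(OcproteoError, ValueError):
    """A peptide occurs at more than one position in its parent protein.

    Carries every (1-based) start position so the caller can decide.
    """

    def __init__(self, sequence: str, accession: str, positions: tuple):
        self.positions = tuple(positions)
        super().__init__(
            f"peptide {sequence!r} occurs at positions {self.positions} in {accession}"
        )


class JoinError(OcproteoError, ValueError):
    """Samples could not be matched to their metadata / biochemistry records."""


class ConfoundingError(OcproteoError, ValueError):
    """Batch labels are aliased with the experimental design."""
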