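"""Exception hierarchy for the toolkit.

All toolkit-specific failures derive from :class:`TspegError` so callers can
catch one base class at pipeline boundaries.
"""


class TspegError(Exception):
    """Base class for all toolkit errors."""


class AlphabetError(TspegError):
    """A sequence contains characters outside {A, C, G, T, N}."""


class PatternError(TspegError):
    """A PAM pattern is not a valid 3-letter IUPAC motif."""


class EditConsistencyError(TspegError):
    """An edit's ref_allele does not match the reference at its interval."""


class DesignError(TspegError):
    """A construct cannot be built (e.g. windows run off the sequence end)."""


class WrongArchitectureError(DesignError):
    """The edit lies on the wrong side of the cut for the requested construct.

    Canonical pegRNAs write downstream (+) edits into the non-target strand;
    tsp-pegRNA / ActRNA:t write upstream (-) edits into the target strand.
    """


class PrimingFailureError(TspegError):
    """PBS does not pair exactly with the genomic primer terminus."""

    def __init__(self, message: str, mismatch_positions=None):
        super().__init__(message)
        self.mismatch_positions = list(mismatch_positions or [])


class GenomeSizeError(TspegError):
    """Input genome exceeds the configured brute-force size cap."""


class FastqParseError(TspegError):
    """A FASTQ record is malformed; carries the record index."""

    def __init__(self, message: str, record_index: int | None = None):
        super().__init__(message)
        self.record_index = record_index
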