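"""Sequence primitives shared by every other module.

Conventions used throughout the toolkit:

* Coordinates are 0-based, half-open intervals on the forward strand.
* A cleavage (cut) is an integer *inter-base* coordinate: the blunt
  double-strand break generated by Cas9 sits 3 nt upstream of the NGG PAM,
  so a forward-strand PAM starting at ``p`` cuts at ``p - 3`` and a
  reverse-strand PAM occupying forward interval ``[p, p + 3)`` cuts at
  ``p + 6``.
* The "+1" position of the prime-editing window is the base occupying
  ``[cut, cut + 1)`` in PAM-strand orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, EditConsistencyError, PatternError

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC code -> set of concrete reference bases it matches.  An N in the
# reference is treated as unknown: it matches only the pattern wildcard N,
# never a fixed base.
IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGTN"),
}

Strand = Literal["forward", "reverse"]


def _validate_dna(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"invalid DNA characters: {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; N maps to N."""
    seq = _validate_dna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceSequence:
    """A named DNA sequence over {A, C, G, T, N}, upper-cased on input."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        seq = _validate_dna(self.seq)
        if len(seq) < 1:
            raise ValueError("reference sequence must have length >= 1")
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class PamSite:
    """A PAM occurrence with its blunt-cut coordinate.

    ``pam_start``/``pam_end`` delimit the 3-nt PAM in forward-strand
    coordinates regardless of strand; ``pam_seq`` is the motif as read on
    the PAM strand.  ``cut`` is the inter-base coordinate of the blunt DSB
    in forward coordinates.
    """

    cut: int
    strand: Strand
    pam_start: int
    pam_end: int
    pam_seq: str

    @property
    def pam_interval(self) -> tuple[int, int]:
        return (self.pam_start, self.pam_end)

    def usable(self, ref_len: int) -> bool:
        """Whether the cut lies inside the sequence, so designs can anchor."""
        return 0 <= self.cut <= ref_len

    def protospacer_interval(self) -> tuple[int, int]:
        """Forward-strand interval of the 20-nt protospacer (may be out of bounds)."""
        if self.strand == "forward":
            return (self.pam_start - 20, self.pam_start)
        return (self.pam_end, self.pam_end + 20)


@dataclass(frozen=True)
class EditSpec:
    """An intended insertion, deletion, or substitution on the forward strand.

    ``start``/``end`` are a half-open interval; an insertion has
    ``start == end`` (an inter-base coordinate).  ``ref_allele`` is empty
    for insertions, ``alt_allele`` empty for deletions.
    """

    kind: Literal["insertion", "deletion", "substitution"]
    start: int
    end: int
    ref_allele: str = ""
    alt_allele: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref_allele", _validate_dna(self.ref_allele))
        object.__setattr__(self, "alt_allele", _validate_dna(self.alt_allele))
        if self.kind == "insertion":
            if self.start != self.end:
                raise ValueError("insertion must have start == end")
            if self.ref_allele:
                raise ValueError("insertion must have empty ref_allele")
            if not self.alt_allele:
                raise ValueError("insertion needs a nonempty alt_allele")
        elif self.kind == "deletion":
            if self.end <= self.start:
                raise ValueError("deletion interval must be nonempty")
            if self.alt_allele:
                raise ValueError("deletion must have empty alt_allele")
        elif self.kind == "substitution":
            if self.end <= self.start:
                raise ValueError("substitution interval must be nonempty")
            if not self.alt_allele:
                raise ValueError("substitution needs a nonempty alt_allele")
        else:
            raise ValueError(f"unknown edit kind {self.kind!r}")

    def validate(self, ref: ReferenceSequence) -> None:
        """Check the edit against a reference; raise on inconsistency."""
        if not (0 <= self.start <= self.end <= len(ref)):
            raise EditConsistencyError(
                f"edit interval [{self.start}, {self.end}) outside reference "
                f"of length {len(ref)}"
            )
        if self.kind != "insertion":
            observed = ref.seq[self.start : self.end]
            if self.ref_allele and observed != self.ref_allele:
                raise EditConsistencyError(
                    f"ref_allele {self.ref_allele!r} != reference slice "
                    f"{observed!r} at [{self.start}, {self.end})"
                )

    @property
    def span(self) -> tuple[int, int]:
        """Reference interval touched by the edit (zero-length for insertions)."""
        return (self.start, self.end)

    def mirror(self, ref_len: int) -> "EditSpec":
        """The same edit expressed on the reverse-complemented reference."""
        return EditSpec(
            kind=self.kind,
            start=ref_len - self.end,
            end=ref_len - self.start,
            ref_allele=reverse_complement(self.ref_allele),
            alt_allele=reverse_complement(self.alt_allele),
        )


def _pattern_sets(pam: str) -> list[frozenset[str]]:
    pam = pam.upper()
    if len(pam) != 3:
        raise PatternError(f"PAM pattern must be 3 letters, got {pam!r}")
    try:
        return [IUPAC[c] for c in pam]
    except KeyError as exc:
        raise PatternError(f"non-IUPAC character in PAM pattern {pam!r}") from exc


def scan_pams(ref: ReferenceSequence, pam: str = "NGG") -> list[PamSite]:
    """All PAM occurrences on both strands of ``ref``.

    Reverse-strand PAMs are reported in forward coordinates (an NGG on the
    reverse strand appears as CCN on the forward strand).  Sites are sorted
    by cut coordinate, forward strand first on ties.  Sites whose cut falls
    outside ``[0, len(ref)]`` are still reported; use
    :meth:`PamSite.usable` to filter them for design.
    """
    fwd_sets = _pattern_sets(pam)
    # Reverse-strand occurrence at forward interval [p, p+3) reads, on the
    # PAM strand, revcomp(ref[p:p+3]); equivalently the forward slice must
    # match the reverse-complemented pattern.
    rev_sets = [
        frozenset(chr(_COMPLEMENT[ord(c)]) for c in s) for s in fwd_sets[::-1]
    ]

    seq = ref.seq
    sites: list[PamSite] = []
    for p in range(len(seq) - 2):
        window = seq[p : p + 3]
        if all(b in s for b, s in zip(window, fwd_sets)):
            sites.append(
                PamSite(
                    cut=p - 3,
                    strand="forward",
                    pam_start=p,
                    pam_end=p + 3,
                    pam_seq=window,
                )
            )
        if all(b in s for b, s in zip(window, rev_sets)):
            sites.append(
                PamSite(
                    cut=p + 6,
                    strand="reverse",
                    pam_start=p,
                    pam_end=p + 3,
                    pam_seq=reverse_complement(window),
                )
            )
    sites.sort(key=lambda s: (s.cut, s.strand != "forward"))
    return sites


def apply_edit(ref: ReferenceSequence, edit: EditSpec) -> str:
    """Reference with the edit spliced in; the ground-truth edited sequence."""
    edit.validate(ref)
    return ref.seq[: edit.start] + edit.alt_allele + ref.seq[edit.end :]


def edited_interval(edit: EditSpec) -> tuple[int, int]:
    """Interval occupied by the alt allele in edited-sequence coordinates."""
    return (edit.start, edit.start + len(edit.alt_allele))


# --- FASTA I/O -------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ReferenceSequence]:
    """Read a multi-record FASTA file; sequences are upper-cased."""
    return [
        ReferenceSequence(name=rec.id, seq=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(refs: Iterable[ReferenceSequence], path: str | Path) -> None:
    """Write references as wrapped (60-column) upper-case FASTA."""
    records = [
        SeqRecord(Seq(r.seq), id=r.name, description="") for r in refs
    ]
    SeqIO.write(records, str(path), "fasta")
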