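"""Exhaustive mismatch-tolerant off-target enumeration and priming-risk QC.

Candidate off-target sites are every both-strand 23-mer whose 3-nt PAM
matches the configured pattern and whose 20-nt protospacer is within a
Hamming distance budget of the guide spacer (no bulges; PAM bases are not
counted as mismatches).  For prime-editing constructs, each candidate DSB
end can additionally be annotated with the number of PBS/primer mismatches
the construct would face there: a handful of priming mismatches is what
prevents reverse-transcription-driven insertion at off-target cuts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DesignError, GenomeSizeError
from .guide_design import GuideConstruct
from .seqcore import IUPAC, ReferenceSequence, reverse_complement, _pattern_sets

PROTOSPACER_LEN = 20
SITE_LEN = 23  # protospacer + PAM

_BASE_CODE = {b: i for i, b in enumerate("ACGTN")}


@dataclass(frozen=True)
class OffTargetSite:
    """A candidate off-target 23-mer (protospacer + PAM).

    ``start``/``end`` are forward-strand coordinates of the full 23-mer;
    ``site_seq`` is read on the PAM strand; ``mismatch_positions`` are
    1-based from the spacer 5' end.  ``cut`` is the blunt-DSB inter-base
    coordinate in forward coordinates.
    """

    ref_name: str
    start: int
    end: int
    strand: str
    site_seq: str
    mismatch_count: int
    mismatch_positions: tuple[int, ...]
    cut: int
    pbs_priming_mismatches: int | None = None


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _scan_one_strand(
    seq: str, spacer: str, max_mismatches: int, pam_sets
) -> list[tuple[int, int, tuple[int, ...]]]:
    """(window start, mismatch count, positions) on one strand of ``seq``."""
    n = len(seq)
    if n < SITE_LEN:
        return []
    arr = _encode(seq)
    windows = np.lib.stride_tricks.sliding_window_view(arr, SITE_LEN)
    proto = windows[:, :PROTOSPACER_LEN]
    sp = _encode(spacer)
    mm = (proto != sp).sum(axis=1)

    pam = windows[:, PROTOSPACER_LEN:]
    pam_ok = np.ones(len(windows), dtype=bool)
    for j, allowed in enumerate(pam_sets):
        col_ok = np.zeros(len(windows), dtype=bool)
        for b in allowed:
            if b == "N":
                continue  # reference N never satisfies a fixed PAM base
            col_ok |= pam[:, j] == ord(b)
        if "N" in allowed and len(allowed) == 5:
            col_ok[:] = True  # pattern wildcard matches anything
        pam_ok &= col_ok

    hits = np.flatnonzero(pam_ok & (mm <= max_mismatches))
    out = []
    for p in hits:
        positions = tuple(
            int(i) + 1
            for i in np.flatnonzero(proto[p] != sp)
        )
        out.append((int(p), int(mm[p]), positions))
    return out


def enumerate_offtargets(
    genome: Sequence[ReferenceSequence] | ReferenceSequence,
    spacer: str,
    max_mismatches: int = 4,
    pam: str = "NGG",
    size_cap: int = 100_000_000,
) -> list[OffTargetSite]:
    """Every both-strand candidate site within the mismatch budget.

    Sorted by mismatch count, then reference, coordinate, and strand.
    Genomes above ``size_cap`` total bases are refused (brute force is
    intended for desk-scale synthetic genomes and single loci).
    """
    if isinstance(genome, ReferenceSequence):
        genome = [genome]
    spacer = spacer.upper()
    if len(spacer) != PROTOSPACER_LEN:
        raise ValueError(f"spacer must be {PROTOSPACER_LEN} nt, got {len(spacer)}")
    total = sum(len(r) for r in genome)
    if total > size_cap:
        raise GenomeSizeError(
            f"genome of {total} bp exceeds the {size_cap} bp brute-force cap; "
            "scan per-contig or raise size_cap"
        )
    pam_sets = _pattern_sets(pam)

    sites: list[OffTargetSite] = []
    for ref in genome:
        for p, count, positions in _scan_one_strand(
            ref.seq, spacer, max_mismatches, pam_sets
        ):
            sites.append(
                OffTargetSite(
                    ref_name=ref.name,
                    start=p,
                    end=p + SITE_LEN,
                    strand="forward",
                    site_seq=ref.seq[p : p + SITE_LEN],
                    mismatch_count=count,
                    mismatch_positions=positions,
                    cut=p + PROTOSPACER_LEN - 3,
                )
            )
        rc = reverse_complement(ref.seq)
        L = len(ref)
        for p, count, positions in _scan_one_strand(rc, spacer, max_mismatches, pam_sets):
            start = L - p - SITE_LEN
            sites.append(
                OffTargetSite(
                    ref_name=ref.name,
                    start=start,
                    end=start + SITE_LEN,
                    strand="reverse",
                    site_seq=rc[p : p + SITE_LEN],
                    mismatch_count=count,
                    mismatch_positions=positions,
                    # PAM occupies forward [start, start+3); blunt cut 3 nt
                    # upstream of the PAM on the PAM (reverse) strand.
                    cut=start + 6,
                )
            )
    sites.sort(
        key=lambda s: (s.mismatch_count, s.ref_name, s.start, s.strand != "forward")
    )
    return sites


def pbs_priming_mismatches(
    construct: GuideConstruct,
    site: OffTargetSite,
    genome: Sequence[ReferenceSequence] | ReferenceSequence,
) -> tuple[int, list[int]]:
    """PBS/primer mismatches the construct would face at a candidate cut.

    The hypothetical primer uses the same geometry as on-target: the
    non-target-strand upstream terminus for a canonical pegRNA, the
    target-strand downstream terminus for tsp-pegRNA / ActRNA:t.  Returns
    the count and 1-based positions from the PBS 5' border.
    """
    if isinstance(genome, ReferenceSequence):
        genome = [genome]
    by_name = {r.name: r for r in genome}
    ref = by_name.get(site.ref_name)
    if ref is None:
        raise ValueError(f"site names unknown reference {site.ref_name!r}")
    pbs = construct.parts.get("pbs")
    if pbs is None:
        raise ValueError("construct carries no PBS")
    n = len(pbs)
    cut = site.cut
    canonical = construct.construct_type == "pegrna"

    # Expected PBS sequence at this site, in PBS orientation.
    if site.strand == "forward":
        if canonical:
            lo, hi = cut - n, cut
            segment = ref.seq[lo:hi] if lo >= 0 else None
            expected = reverse_complement(segment) if segment else None
        else:
            lo, hi = cut, cut + n
            expected = ref.seq[lo:hi] if hi <= len(ref) else None
            if expected is not None and len(expected) < n:
                expected = None
    else:
        if canonical:
            # rc(rc(forward slice)): expected PBS equals the forward slice.
            lo, hi = cut, cut + n
            expected = ref.seq[lo:hi] if hi <= len(ref) else None
        else:
            lo, hi = cut - n, cut
            expected = reverse_complement(ref.seq[lo:hi]) if lo >= 0 else None
    if expected is None or len(expected) < n:
        raise DesignError("cut too close to a contig edge for the PBS window")

    positions = [i + 1 for i in range(n) if pbs[i] != expected[i]]
    return len(positions), positions


def sites_to_frame(sites: Sequence[OffTargetSite]):
    """BED-like table (0-based half-open) of candidate sites."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "chrom": s.ref_name,
                "start": s.start,
                "end": s.end,
                "strand": "+" if s.strand == "forward" else "-",
                "site_seq": s.site_seq,
                "mismatch_count": s.mismatch_count,
                "mismatch_positions": ",".join(map(str, s.mismatch_positions)),
                "cut": s.cut,
                "pbs_priming_mismatches": s.pbs_priming_mismatches,
            }
            for s in sites
        ]
    )
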