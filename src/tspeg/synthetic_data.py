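"""Synthetic inputs for exercising and testing the toolkit.

Everything the pipelines consume can be generated here with no external
download: i.i.d. random genomes (optionally GC-weighted), SNV/indel
variant panels with guaranteed flanks, amplicon read mixtures with exact
outcome proportions, and genomes with planted off-target sites.  All
generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqcore import EditSpec, ReferenceSequence, apply_edit

BASES = np.array(list("ACGT"))

MIXTURE_CATEGORIES = ("accurate", "imprecise_prime_edit", "indel", "unedited")


@dataclass(frozen=True)
class ReadMixtureSpec:
    """Composition of a simulated amplicon library.

    ``proportions`` maps outcome categories to fractions summing to 1.
    With ``exact_allocation`` (default) category counts follow
    largest-remainder rounding of ``n_reads * proportion``, so classifier
    tests have exact expectations; otherwise counts are multinomial.
    ``per_base_error`` is the substitution-error rate per sequenced base.
    The quality model is a constant Phred score, or two-level where a
    fraction of reads is emitted at a low mean quality (to exercise the
    Q30 filter).
    """

    proportions: dict[str, float]
    n_reads: int
    per_base_error: float = 0.0
    seed: int = 0
    exact_allocation: bool = True
    quality_model: str = "constant"  # or "two_level"
    q_high: int = 37
    q_low: int = 20
    low_fraction: float = 0.1

    def __post_init__(self) -> None:
        unknown = set(self.proportions) - set(MIXTURE_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown mixture categories: {sorted(unknown)}")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {total}")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not 0.0 <= self.per_base_error <= 0.1:
            raise ValueError("per_base_error must be in [0, 0.1]")
        if self.quality_model not in ("constant", "two_level"):
            raise ValueError("quality_model must be 'constant' or 'two_level'")


def simulate_genome(
    length: int,
    gc_fraction: float = 0.5,
    seed: int | None = None,
    name: str = "synthetic",
) -> ReferenceSequence:
    """I.i.d. random genome with P(G) = P(C) = gc_fraction / 2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    seq = rng.choice(BASES, size=length, p=[at, gc, gc, at])
    return ReferenceSequence(name=name, seq="".join(seq))


def simulate_variant_panel(
    ref: ReferenceSequence,
    n: int,
    kinds: tuple[str, ...] = ("substitution",),
    seed: int | None = None,
    flank: int = 30,
) -> list[EditSpec]:
    """``n`` random valid edits with at least ``flank`` bp on each side.

    SNVs by default; small (1 bp) insertions and deletions when requested
    via ``kinds``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(ref) < 2 * flank + 1:
        raise ValueError(
            f"reference of {len(ref)} bp too short for {flank} bp flanks"
        )
    rng = np.random.default_rng(seed)
    out: list[EditSpec] = []
    for _ in range(n):
        kind = kinds[rng.integers(len(kinds))]
        pos = int(rng.integers(flank, len(ref) - flank))
        if kind == "substitution":
            ref_base = ref.seq[pos]
            choices = [b for b in "ACGT" if b != ref_base]
            alt = choices[rng.integers(3)]
            out.append(
                EditSpec("substitution", pos, pos + 1, ref_allele=ref_base,
                         alt_allele=alt)
            )
        elif kind == "insertion":
            alt = str(BASES[rng.integers(4)])
            out.append(EditSpec("insertion", pos, pos, alt_allele=alt))
        elif kind == "deletion":
            out.append(
                EditSpec("deletion", pos, pos + 1, ref_allele=ref.seq[pos])
            )
        else:
            raise ValueError(f"unknown edit kind {kind!r}")
    return out


def simulate_proximal_edit(
    ref: ReferenceSequence,
    site,
    side: str,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    kinds: tuple[str, ...] = ("insertion", "deletion", "substitution"),
    max_offset: int = 6,
) -> EditSpec:
    """A random edit inside the +window (``side='plus'``) or -window
    (``side='minus'``) of a cleavage site, never spanning the cut.

    Used to exercise the design/round-trip machinery: plus-side edits are
    valid canonical-pegRNA targets, minus-side edits valid tsp-pegRNA /
    ActRNA:t targets.  Offsets are drawn uniformly from 1..``max_offset``;
    edit lengths are 1-3 nt.
    """
    if side not in ("plus", "minus"):
        raise ValueError("side must be 'plus' or 'minus'")
    rng = rng if rng is not None else np.random.default_rng(seed)
    kind = kinds[int(rng.integers(len(kinds)))]
    off = int(rng.integers(0, max_offset))
    length = int(rng.integers(1, 4)) if kind == "insertion" else int(rng.integers(1, 3))
    cut = site.cut
    downstream_forward = (side == "plus") == (site.strand == "forward")
    if kind == "insertion":
        pos = cut + off if downstream_forward else cut - off
        pos = min(max(pos, 0), len(ref))
        alt = "".join(rng.choice(BASES, size=length))
        return EditSpec("insertion", pos, pos, alt_allele=alt)
    if downstream_forward:
        start = cut + off
        end = start + length
    else:
        end = cut - off
        start = end - length
    start, end = max(start, 0), min(end, len(ref))
    if end <= start:
        start, end = max(0, end - 1), end if end > 0 else 1
    ref_allele = ref.seq[start:end]
    if kind == "deletion":
        return EditSpec("deletion", start, end, ref_allele=ref_allele)
    alt = "".join(
        "ACGT"[("ACGT".index(b) + 1 + int(rng.integers(3))) % 4] for b in ref_allele
    )
    return EditSpec("substitution", start, end, ref_allele=ref_allele, alt_allele=alt)


def _largest_remainder(proportions: dict[str, float], n: int) -> dict[str, int]:
    raw = {k: v * n for k, v in proportions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    remainders = sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in remainders[:short]:
        counts[k] += 1
    return counts


def _random_indel(seq: str, lo: int, hi: int, rng, edit: EditSpec | None = None) -> str:
    """Random 1-10 nt insertion or deletion with its left edge in [lo, hi).

    When an intended ``edit`` with new bases is given, insertion candidates
    that could realize that edit (an inserted segment near the edit position
    containing the leading half of the alt allele) are rejected, so a read
    labelled "indel" never carries the intended edit by coincidence.
    """
    while True:
        length = int(rng.integers(1, 11))
        pos = int(rng.integers(lo, hi))
        if rng.random() < 0.5 and pos + length <= len(seq):
            return seq[:pos] + seq[pos + length :]
        ins = "".join(rng.choice(BASES, size=length))
        if edit is not None and edit.alt_allele:
            # An insertion inside a repeat can slide: compute the leftmost
            # and rightmost equivalent positions so proximity to the edit is
            # judged on the whole equivalence interval, not the sampled pos.
            left, lins = pos, ins
            while left > 0 and seq[left - 1] == lins[-1]:
                lins = lins[-1] + lins[:-1]
                left -= 1
            right, rins = pos, ins
            while right < len(seq) and seq[right] == rins[0]:
                rins = rins[1:] + rins[0]
                right += 1
            alt = edit.alt_allele
            near = (
                left - (length + len(alt) + 2)
                <= edit.start
                <= right + (length + len(alt) + 2)
            )
            core = alt[: (len(alt) + 1) // 2]
            if near and core in ins + ins:  # rotations can realign the bases
                continue
            # An inserted segment of exactly the intended length right at the
            # edit position reads as pure mismatches against the edited
            # amplicon, which the decision rules cannot call an indel.
            if edit.kind == "insertion" and length == len(alt) and near:
                continue
        return seq[:pos] + ins + seq[pos:]


def _one_base_indel(seq: str, positions: list[int], rng) -> str:
    pos = positions[int(rng.integers(len(positions)))]
    if rng.random() < 0.5 and pos < len(seq):
        return seq[:pos] + seq[pos + 1 :]
    ins = str(BASES[rng.integers(4)])
    return seq[:pos] + ins + seq[pos:]


def _add_substitution_errors(seq: str, rate: float, rng) -> str:
    if rate <= 0.0:
        return seq
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def simulate_amplicon_reads(
    ref_amplicon: ReferenceSequence | str,
    edited_amplicon: str,
    spec: ReadMixtureSpec,
    cut: int,
    edit: EditSpec,
) -> tuple[list[SeqRecord], list[str]]:
    """FASTQ records with per-read truth labels for a programmed mixture.

    ``accurate`` reads are the edited amplicon; ``unedited`` the reference;
    ``indel`` the reference with a random 1-10 nt indel near the cut;
    ``imprecise_prime_edit`` the edited amplicon with 1-2 extra 1-nt
    indels near the cut but outside the intended edit span (the intended
    edit stays intact).  Per-base substitution errors are then applied at
    ``spec.per_base_error``.  Read order is shuffled; labels are returned
    parallel to the records.
    """
    ref_seq = (
        ref_amplicon.seq
        if isinstance(ref_amplicon, ReferenceSequence)
        else ref_amplicon.upper()
    )
    rng = np.random.default_rng(spec.seed)
    if spec.exact_allocation:
        counts = _largest_remainder(
            {k: spec.proportions.get(k, 0.0) for k in MIXTURE_CATEGORIES},
            spec.n_reads,
        )
    else:
        keys = list(MIXTURE_CATEGORIES)
        draw = rng.multinomial(
            spec.n_reads, [spec.proportions.get(k, 0.0) for k in keys]
        )
        counts = dict(zip(keys, (int(x) for x in draw)))

    # Window for simulated repair outcomes: tight around the cut so planted
    # indels always land inside the classifier's quantification window.
    lo = max(0, cut - 10)
    hi = min(len(ref_seq) - 1, cut + 10)
    delta = len(edit.alt_allele) - (edit.end - edit.start)
    cut_e = cut + delta if cut >= edit.end else cut
    es, ee = edit.start, edit.start + len(edit.alt_allele)
    imprecise_positions = [
        p
        for p in range(max(0, cut_e - 10), min(len(edited_amplicon), cut_e + 10))
        if not (es - 1 <= p <= ee)  # keep the intended edit and its junctions intact
    ]

    sequences: list[str] = []
    labels: list[str] = []
    for category, count in counts.items():
        for _ in range(count):
            if category == "accurate":
                seq = edited_amplicon
            elif category == "unedited":
                seq = ref_seq
            elif category == "indel":
                seq = _random_indel(ref_seq, lo, hi, rng, edit)
                while seq == ref_seq or seq == edited_amplicon:
                    seq = _random_indel(ref_seq, lo, hi, rng, edit)
            else:  # imprecise_prime_edit
                # Regenerate until a net length change remains: a paired
                # insertion+deletion can cancel to a clean or mismatch-only
                # read, which would no longer be an imperfect edit.
                while True:
                    seq = edited_amplicon
                    for _ in range(int(rng.integers(1, 3))):
                        seq = _one_base_indel(seq, imprecise_positions, rng)
                    if len(seq) != len(edited_amplicon):
                        break
            seq = _add_substitution_errors(seq, spec.per_base_error, rng)
            sequences.append(seq)
            labels.append(category)

    order = rng.permutation(len(sequences))
    records: list[SeqRecord] = []
    shuffled_labels: list[str] = []
    for rank, idx in enumerate(order):
        seq = sequences[idx]
        if spec.quality_model == "two_level" and rng.random() < spec.low_fraction:
            q = spec.q_low
        else:
            q = spec.q_high
        rec = SeqRecord(
            Seq(seq),
            id=f"read_{rank:06d}",
            description="",
            letter_annotations={"phred_quality": [q] * len(seq)},
        )
        records.append(rec)
        shuffled_labels.append(labels[idx])
    return records, shuffled_labels


@dataclass(frozen=True)
class PlantedSite:
    """Location and content of a planted off-target site."""

    start: int
    end: int
    site_seq: str
    mismatch_positions: tuple[int, ...]


def plant_offtarget(
    genome: ReferenceSequence,
    spacer: str,
    n_mismatches: int,
    seed: int | None = None,
) -> tuple[ReferenceSequence, PlantedSite]:
    """Write a mismatched protospacer copy + NGG into the genome.

    Exactly ``n_mismatches`` substitutions at random spacer positions,
    followed by an NGG PAM (random N), at a random forward-strand
    location.  Returns the modified genome and the planted location.
    """
    spacer = spacer.upper()
    if n_mismatches > len(spacer):
        raise ValueError("n_mismatches cannot exceed the spacer length")
    rng = np.random.default_rng(seed)
    site_len = len(spacer) + 3
    if len(genome) < site_len:
        raise ValueError("genome shorter than a planted site")
    start = int(rng.integers(0, len(genome) - site_len + 1))
    positions = sorted(
        int(p) for p in rng.choice(len(spacer), size=n_mismatches, replace=False)
    )
    proto = list(spacer)
    for p in positions:
        choices = [b for b in "ACGT" if b != proto[p]]
        proto[p] = choices[int(rng.integers(3))]
    pam = str(BASES[rng.integers(4)]) + "GG"
    site_seq = "".join(proto) + pam
    new_seq = genome.seq[:start] + site_seq + genome.seq[start + site_len :]
    planted = PlantedSite(
        start=start,
        end=start + site_len,
        site_seq=site_seq,
        mismatch_positions=tuple(p + 1 for p in positions),
    )
    return ReferenceSequence(genome.name, new_seq), planted
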