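"""Amplicon read classification into prime-editing outcome categories.

Each quality-filtered read is globally aligned (affine gaps, both
orientations) to the reference amplicon and to the intended edited
amplicon, and assigned to one of:

* ``accurate`` — best alignment to the edited amplicon, intended edit
  fully present, no indels inside the quantification window (isolated
  point mismatches are tolerated as sequencing error);
* ``imprecise_prime_edit`` — intended edit present (or, for insertions, at
  least a configurable prefix fraction of its new bases) but imperfect:
  extra indels in the window ("imperfect HDR");
* ``indel`` — an indel inside the window without the intended edit;
* ``unedited`` — matches the reference amplicon without window indels;
* ``ambiguous`` — equal-score ties the rules above do not resolve.

The quantification window is the union of the cut coordinate and the
intended edit span, extended by ``indel_window_halfwidth`` (default 30 bp)
on each side.  Frequencies are reported over aligned reads; low-quality
and unalignable reads are counted separately as ``filtered``.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner

from .errors import FastqParseError
from .seqcore import EditSpec, ReferenceSequence, reverse_complement

CATEGORIES = ("accurate", "imprecise_prime_edit", "indel", "unedited", "ambiguous")


@dataclass(frozen=True)
class ClassifierConfig:
    """Quantification rules for amplicon outcome counting.

    Defaults: reads kept at mean Phred >= 30; a 30 bp half-width
    quantification window; alignment scores 5 / -4 / -8 / -2 (match,
    mismatch, gap open, gap extend); per-position SNV calls below 0.1%
    of reads discarded.
    """

    min_mean_quality: float = 30.0
    indel_window_halfwidth: int = 30
    match_score: float = 5.0
    mismatch_score: float = -4.0
    gap_open_score: float = -8.0
    gap_extend_score: float = -2.0
    snv_frequency_floor: float = 0.001
    insertion_prefix_fraction: float = 0.5
    min_score_fraction: float = 0.3  # of the perfect-match score; below -> unalignable

    def __post_init__(self) -> None:
        if self.indel_window_halfwidth < 0:
            raise ValueError("indel_window_halfwidth must be >= 0")
        if not 0.0 <= self.snv_frequency_floor <= 1.0:
            raise ValueError("snv_frequency_floor must be in [0, 1]")


@dataclass
class OutcomeTable:
    """Per-amplicon outcome counts and frequencies.

    ``frequencies`` are over aligned reads and sum to 1 across the five
    categories; ``filtered`` counts quality-failed plus unalignable reads.
    """

    counts: dict[str, int]
    filtered: int
    total_reads: int

    @property
    def aligned_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[str, float]:
        n = self.aligned_reads
        return {k: (v / n if n else 0.0) for k, v in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        freqs = self.frequencies
        return pd.DataFrame(
            {
                "category": list(self.counts),
                "count": list(self.counts.values()),
                "frequency": [freqs[k] for k in self.counts],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "counts": self.counts,
            "frequencies": self.frequencies,
            "filtered": self.filtered,
            "total_reads": self.total_reads,
            "aligned_reads": self.aligned_reads,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# --- FASTQ handling --------------------------------------------------------

def read_fastq(path: str | Path) -> list:
    """Phred+33 FASTQ records (optionally gzipped) as Biopython SeqRecords."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    try:
        with opener(path, "rt") as fh:
            return list(SeqIO.parse(fh, "fastq"))
    except ValueError as exc:
        raise FastqParseError(f"malformed FASTQ in {path}: {exc}") from exc


def filter_reads(reads: Sequence, cfg: ClassifierConfig | None = None):
    """Split reads into (kept, filtered) by mean Phred quality.

    The threshold is inclusive: a read whose mean quality equals
    ``min_mean_quality`` is kept.
    """
    cfg = cfg or ClassifierConfig()
    kept, filtered = [], []
    for i, rec in enumerate(reads):
        quals = rec.letter_annotations.get("phred_quality")
        if quals is None:
            raise FastqParseError("record lacks quality scores", record_index=i)
        if len(quals) and float(np.mean(quals)) >= cfg.min_mean_quality:
            kept.append(rec)
        else:
            filtered.append(rec)
    return kept, filtered


# --- alignment machinery ---------------------------------------------------

def _make_aligner(cfg: ClassifierConfig) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = cfg.match_score
    aligner.mismatch_score = cfg.mismatch_score
    aligner.open_gap_score = cfg.gap_open_score
    aligner.extend_gap_score = cfg.gap_extend_score
    return aligner


@dataclass
class _Events:
    """Differences between a read and an amplicon, in amplicon coordinates."""

    score: float
    mismatches: list[int]                 # amplicon positions
    deletions: list[tuple[int, int]]      # amplicon intervals absent from read
    insertions: list[tuple[int, str]]     # (amplicon inter-base pos, read bases)
    covered: tuple[int, int]              # amplicon interval spanned by the read

    def indel_in(self, window: tuple[int, int]) -> bool:
        w0, w1 = window
        for d0, d1 in self.deletions:
            if d0 < w1 and d1 > w0:
                return True
        return any(w0 <= p <= w1 for p, _ in self.insertions)

    def mismatch_in(self, window: tuple[int, int]) -> bool:
        w0, w1 = window
        return any(w0 <= p < w1 for p in self.mismatches)


def _align_events(aligner: PairwiseAligner, amplicon: str, read: str) -> _Events:
    aln = aligner.align(amplicon, read)[0]
    t_blocks, q_blocks = aln.aligned
    mismatches: list[int] = []
    deletions: list[tuple[int, int]] = []
    insertions: list[tuple[int, str]] = []
    prev_t = prev_q = None
    for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks):
        if prev_t is not None:
            if t0 > prev_t:
                deletions.append((prev_t, t0))
            if q0 > prev_q:
                insertions.append((t0, read[prev_q:q0]))
        for i in range(t1 - t0):
            if amplicon[t0 + i] != read[q0 + i]:
                mismatches.append(t0 + i)
        prev_t, prev_q = t1, q1
    covered = (
        (int(t_blocks[0][0]), int(t_blocks[-1][1])) if len(t_blocks) else (0, 0)
    )
    return _Events(
        score=aln.score,
        mismatches=mismatches,
        deletions=deletions,
        insertions=insertions,
        covered=covered,
    )


def _best_orientation(aligner, amplicon: str, read: str) -> tuple[_Events, str]:
    fwd = _align_events(aligner, amplicon, read)
    rev = _align_events(aligner, amplicon, reverse_complement(read))
    return (fwd, "forward") if fwd.score >= rev.score else (rev, "reverse")


# --- windows and edit presence ---------------------------------------------

def _windows(edit: EditSpec, cut: int, ref_len: int, edited_len: int,
             hw: int) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
    """(ref window, edited window, edit span in edited coords)."""
    delta = len(edit.alt_allele) - (edit.end - edit.start)
    cut_e = cut + delta if cut >= edit.end else cut
    es, ee = edit.start, edit.start + len(edit.alt_allele)
    w_ref = (max(0, min(cut, edit.start) - hw), min(ref_len, max(cut, edit.end) + hw))
    w_ed = (max(0, min(cut_e, es) - hw), min(edited_len, max(cut_e, ee) + hw))
    return w_ref, w_ed, (es, ee)


def _edit_presence(
    ev: _Events, span: tuple[int, int], edit: EditSpec, prefix_fraction: float
) -> tuple[bool, bool]:
    """(fully present, partially present) of the intended edit vs the edited amplicon."""
    es, ee = span
    if es == ee:  # deletion edit: inspect the junction
        j0, j1 = max(0, es - 1), ee + 1
        covered = ev.covered[0] <= j0 and ev.covered[1] >= j1
        clean = (
            covered
            and not ev.mismatch_in((j0, j1))
            and not ev.indel_in((j0, j1 - 1))
        )
        return clean, clean
    covered = ev.covered[0] <= es and ev.covered[1] >= ee
    clean_span = (
        covered
        and not ev.mismatch_in((es, ee))
        and not any(d0 < ee and d1 > es for d0, d1 in ev.deletions)
        and not any(es < p < ee for p, _ in ev.insertions)
    )
    if clean_span:
        return True, True
    if edit.kind == "insertion" and covered:
        # Leading run of intact new bases, as aligned to the edited amplicon.
        prefix = 0
        for p in range(es, ee):
            if p in ev.mismatches or any(d0 <= p < d1 for d0, d1 in ev.deletions):
                break
            prefix += 1
        return False, prefix / (ee - es) >= prefix_fraction
    return False, False


def _partial_insertion_vs_ref(
    ev: _Events, edit: EditSpec, window: tuple[int, int], prefix_fraction: float
) -> bool:
    """A >= prefix_fraction prefix of an insertion's new bases, seen as an
    inserted segment when the read is aligned to the *reference* amplicon."""
    if edit.kind != "insertion":
        return False
    alt = edit.alt_allele
    for pos, bases in ev.insertions:
        if not (window[0] <= pos <= window[1]):
            continue
        prefix = 0
        for a, b in zip(alt, bases):
            if a != b:
                break
            prefix += 1
        if prefix / len(alt) >= prefix_fraction and prefix < len(alt):
            return True
    return False


# --- classification --------------------------------------------------------

def classify_read(
    read,
    ref_amplicon: ReferenceSequence | str,
    edited_amplicon: str,
    edit: EditSpec,
    cut: int,
    cfg: ClassifierConfig | None = None,
    _aligner: PairwiseAligner | None = None,
) -> tuple[str, dict]:
    """Assign one read to an outcome category.

    ``read`` may be a string or a SeqRecord; both orientations are tried
    against both amplicons and the best-scoring alignment drives the
    decision.  Returns ``(category, detail)`` where detail records scores,
    orientation, and the events used.
    """
    cfg = cfg or ClassifierConfig()
    aligner = _aligner or _make_aligner(cfg)
    ref_seq = ref_amplicon.seq if isinstance(ref_amplicon, ReferenceSequence) else ref_amplicon
    seq = str(read.seq) if hasattr(read, "seq") else str(read)
    seq = seq.upper()

    ev_r, ori_r = _best_orientation(aligner, ref_seq, seq)
    ev_e, ori_e = _best_orientation(aligner, edited_amplicon, seq)
    w_ref, w_ed, span_e = _windows(
        edit, cut, len(ref_seq), len(edited_amplicon), cfg.indel_window_halfwidth
    )

    detail = {
        "score_ref": ev_r.score,
        "score_edited": ev_e.score,
        "orientation_ref": ori_r,
        "orientation_edited": ori_e,
    }

    floor = cfg.min_score_fraction * cfg.match_score * len(seq)
    if max(ev_r.score, ev_e.score) < floor:
        return "filtered", {**detail, "reason": "unalignable"}

    def via_edited() -> str:
        full, partial = _edit_presence(ev_e, span_e, edit, cfg.insertion_prefix_fraction)
        if full and not ev_e.indel_in(w_ed):
            return "accurate"
        if full or partial:
            return "imprecise_prime_edit"
        if ev_e.indel_in(w_ed):
            return "indel"
        return "ambiguous"

    def via_ref() -> str:
        if _partial_insertion_vs_ref(ev_r, edit, w_ref, cfg.insertion_prefix_fraction):
            return "imprecise_prime_edit"
        if ev_r.indel_in(w_ref):
            return "indel"
        return "unedited"

    if ev_e.score > ev_r.score:
        return via_edited(), detail
    if ev_r.score > ev_e.score:
        return via_ref(), detail
    a, b = via_edited(), via_ref()
    return (a if a == b else "ambiguous"), detail


def summarize_outcomes(
    reads: Iterable,
    ref_amplicon: ReferenceSequence | str,
    edited_amplicon: str,
    edit: EditSpec,
    cut: int,
    cfg: ClassifierConfig | None = None,
) -> OutcomeTable:
    """Quality-filter then classify every read; aggregate into an OutcomeTable."""
    cfg = cfg or ClassifierConfig()
    reads = list(reads)
    have_quals = reads and hasattr(reads[0], "letter_annotations")
    if have_quals:
        kept, quality_filtered = filter_reads(reads, cfg)
    else:
        kept, quality_filtered = reads, []
    aligner = _make_aligner(cfg)
    counts = {cat: 0 for cat in CATEGORIES}
    n_unalignable = 0
    for rec in kept:
        cat, _ = classify_read(
            rec, ref_amplicon, edited_amplicon, edit, cut, cfg, _aligner=aligner
        )
        if cat == "filtered":
            n_unalignable += 1
        else:
            counts[cat] += 1
    return OutcomeTable(
        counts=counts,
        filtered=len(quality_filtered) + n_unalignable,
        total_reads=len(reads),
    )


def snv_floor_filter(
    frequencies: pd.DataFrame | dict, cfg: ClassifierConfig | None = None
) -> pd.DataFrame | dict:
    """Drop per-position variant calls strictly below the frequency floor.

    Entries at exactly the floor are retained (variants occurring at
    frequencies below 0.1% of reads are excluded; 0.1% itself is kept).
    """
    cfg = cfg or ClassifierConfig()
    if isinstance(frequencies, pd.DataFrame):
        return frequencies[
            frequencies["frequency"] >= cfg.snv_frequency_floor
        ].reset_index(drop=True)
    return {
        k: v for k, v in frequencies.items() if v >= cfg.snv_frequency_floor
    }
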