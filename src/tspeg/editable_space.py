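"""Editing-window geometry and variant-panel coverage surveys.

A nuclease prime editor installs edits relative to the blunt Cas9 cut.
Downstream positions (+1, +2, ...) are reachable by a canonical pegRNA
writing into the non-target strand; upstream positions (-1, -2, ...) are
reachable only by target-strand designs (tsp-pegRNA or sgRNA + ActRNA:t).
Positions within 6 bp of the cut on either side form the favorable editing
windows surveyed here: for each variant in a panel we ask whether *any*
cleavage site on either strand places the variant inside the +6 window,
the -6 window, both, or neither.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .seqcore import (
    EditSpec,
    PamSite,
    ReferenceSequence,
    scan_pams,
)
from .errors import EditConsistencyError

logger = logging.getLogger(__name__)

PROTOSPACER_LEN = 20


@dataclass(frozen=True)
class WindowConfig:
    """Editing-window parameters.

    ``plus_window``/``minus_window`` give the number of favorable positions
    downstream (+1..+plus_window) and upstream (-1..-minus_window) of the
    cut, both defaulting to 6.  With ``require_full_protospacer`` a site
    only counts if its full 20-nt protospacer lies inside the sequence.
    """

    plus_window: int = 6
    minus_window: int = 6
    pam_pattern: str = "NGG"
    require_full_protospacer: bool = True

    def __post_init__(self) -> None:
        if self.plus_window < 0 or self.minus_window < 0:
            raise ValueError("window sizes must be >= 0")


@dataclass(frozen=True)
class EditOffset:
    """Cut-relative offsets of an edit at one cleavage site.

    Offsets are measured in PAM-strand orientation to the most cut-proximal
    altered base on each side; the +1 base occupies ``[cut, cut+1)`` on the
    PAM strand.  An insertion exactly at the cut is simultaneously +1 and
    -1.  A side with no altered base has offset ``None``.
    """

    site: PamSite
    plus_offset: int | None
    minus_offset: int | None


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant tied to a named reference, with optional panel metadata."""

    ref_name: str
    edit: EditSpec
    id: str | None = None
    significance: str | None = None


@dataclass
class WindowReport:
    """Per-edit coverage report across all cleavage sites of a reference."""

    covered_plus: bool
    covered_minus: bool
    qualifying: list[tuple[EditOffset, int]]  # (offsets, best in-window |offset|)
    offsets: list[EditOffset]  # all usable sites

    @property
    def best(self) -> EditOffset | None:
        return self.qualifying[0][0] if self.qualifying else None


@dataclass
class CoverageSummary:
    """Aggregate window coverage over a variant panel.

    Fractions are over the surveyed (non-skipped) variants.
    ``minus_only`` is the headline quantity for target-strand editing: the
    share of variants reachable only through the upstream (-6) window.
    """

    n_variants: int
    covered_plus: float
    covered_minus: float
    covered_both: float
    minus_only: float
    neither: float
    per_variant: pd.DataFrame
    n_skipped: int = 0
    skipped: list[tuple[AnnotatedVariant, str]] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        self.per_variant.to_csv(path, sep="\t", index=False)

    def report(self) -> str:
        lines = [
            f"variants surveyed: {self.n_variants} (skipped: {self.n_skipped})",
            f"covered by plus window:  {self.covered_plus:.1%}",
            f"covered by minus window: {self.covered_minus:.1%}",
            f"covered by both:         {self.covered_both:.1%}",
            f"minus-window only:       {self.minus_only:.1%}",
            f"neither window:          {self.neither:.1%}",
        ]
        return "\n".join(lines)


def edit_offsets(edit: EditSpec, site: PamSite) -> EditOffset:
    """Cut-relative offsets of ``edit`` at ``site`` in PAM-strand orientation."""
    c = site.cut
    plus: int | None = None
    minus: int | None = None
    if edit.kind == "insertion":
        p = edit.start
        if p == c:
            plus, minus = 1, -1
        elif site.strand == "forward":
            if p > c:
                plus = p - c + 1
            else:
                minus = p - c - 1
        else:
            if p < c:
                plus = c - p + 1
            else:
                minus = -(p - c + 1)
    else:
        first, last = edit.start, edit.end - 1  # altered reference bases
        if site.strand == "forward":
            if last >= c:
                plus = max(first, c) - c + 1
            if first < c:
                minus = min(last, c - 1) - c
        else:
            if first < c:
                plus = c - min(last, c - 1)
            if last >= c:
                minus = -(max(first, c) - c + 1)
    return EditOffset(site=site, plus_offset=plus, minus_offset=minus)


def _site_warning_count(site: PamSite, ref_len: int) -> int:
    """Light-weight QC count used only for ranking ties."""
    n = 0
    if site.cut < PROTOSPACER_LEN or ref_len - site.cut < PROTOSPACER_LEN:
        n += 1  # cut close to a sequence edge; flanking windows may clip
    return n


def usable_sites(
    ref: ReferenceSequence, cfg: WindowConfig | None = None
) -> list[PamSite]:
    """Cleavage sites of ``ref`` eligible for design under ``cfg``."""
    cfg = cfg or WindowConfig()
    sites = [s for s in scan_pams(ref, cfg.pam_pattern) if s.usable(len(ref))]
    if cfg.require_full_protospacer:
        sites = [
            s
            for s in sites
            if s.protospacer_interval()[0] >= 0
            and s.protospacer_interval()[1] <= len(ref)
        ]
    return sites


def classify_edit(
    edit: EditSpec,
    ref: ReferenceSequence,
    cfg: WindowConfig | None = None,
    sites: list[PamSite] | None = None,
) -> WindowReport:
    """Window coverage of one edit across every cleavage site of ``ref``.

    Qualifying sites (those placing the edit inside either window) are
    ranked by the smallest in-window |offset|, breaking ties by fewer QC
    warnings, then lower cut coordinate, then forward strand first.
    ``sites`` may carry precomputed :func:`usable_sites` output so panel
    surveys scan each reference only once.
    """
    cfg = cfg or WindowConfig()
    edit.validate(ref)
    if sites is None:
        sites = usable_sites(ref, cfg)
    offsets = [edit_offsets(edit, s) for s in sites]

    covered_plus = False
    covered_minus = False
    qualifying: list[tuple[EditOffset, int]] = []
    for off in offsets:
        in_plus = off.plus_offset is not None and off.plus_offset <= cfg.plus_window
        in_minus = (
            off.minus_offset is not None and -off.minus_offset <= cfg.minus_window
        )
        covered_plus = covered_plus or in_plus
        covered_minus = covered_minus or in_minus
        best: int | None = None
        if in_plus:
            best = off.plus_offset
        if in_minus and (best is None or -off.minus_offset < best):
            best = -off.minus_offset
        if best is not None:
            qualifying.append((off, best))
    qualifying.sort(
        key=lambda item: (
            item[1],
            _site_warning_count(item[0].site, len(ref)),
            item[0].site.cut,
            item[0].site.strand != "forward",
        )
    )
    return WindowReport(
        covered_plus=covered_plus,
        covered_minus=covered_minus,
        qualifying=qualifying,
        offsets=offsets,
    )


def _as_annotated(
    variants: Sequence[AnnotatedVariant | EditSpec], default_ref: str
) -> list[AnnotatedVariant]:
    out = []
    for v in variants:
        if isinstance(v, EditSpec):
            v = AnnotatedVariant(ref_name=default_ref, edit=v)
        out.append(v)
    return out


def survey_variants(
    refs: Sequence[ReferenceSequence] | ReferenceSequence,
    variants: Sequence[AnnotatedVariant | EditSpec],
    cfg: WindowConfig | None = None,
) -> CoverageSummary:
    """Aggregate :func:`classify_edit` over a variant panel.

    Variants whose ref allele does not match the reference (or that name an
    unknown reference) are skipped and logged, not counted in the fractions.
    """
    cfg = cfg or WindowConfig()
    if isinstance(refs, ReferenceSequence):
        refs = [refs]
    by_name = {r.name: r for r in refs}
    default_ref = refs[0].name if len(refs) == 1 else ""
    annotated = _as_annotated(variants, default_ref)

    site_cache: dict[str, tuple[list[PamSite], list[int]]] = {}
    rows = []
    skipped: list[tuple[AnnotatedVariant, str]] = []
    n_plus = n_minus = n_both = 0
    for i, var in enumerate(annotated):
        ref = by_name.get(var.ref_name)
        if ref is None:
            skipped.append((var, f"unknown reference {var.ref_name!r}"))
            logger.warning("skipping variant %d: unknown reference %s", i, var.ref_name)
            continue
        if var.ref_name not in site_cache:
            cached = usable_sites(ref, cfg)
            site_cache[var.ref_name] = (cached, [s.cut for s in cached])
        all_sites, cuts = site_cache[var.ref_name]
        # Only sites whose cut is within window range of the edit can qualify.
        reach = max(cfg.plus_window, cfg.minus_window) + 1
        lo = bisect.bisect_left(cuts, var.edit.start - reach)
        hi = bisect.bisect_right(cuts, var.edit.end + reach)
        try:
            report = classify_edit(var.edit, ref, cfg, sites=all_sites[lo:hi])
        except EditConsistencyError as exc:
            skipped.append((var, str(exc)))
            logger.warning("skipping variant %d: %s", i, exc)
            continue
        p, m = report.covered_plus, report.covered_minus
        n_plus += p
        n_minus += m
        n_both += p and m
        if p and m:
            category = "both"
        elif p:
            category = "plus_only"
        elif m:
            category = "minus_only"
        else:
            category = "neither"
        best = report.best
        rows.append(
            {
                "variant_index": i,
                "ref_name": var.ref_name,
                "id": var.id,
                "kind": var.edit.kind,
                "start": var.edit.start,
                "end": var.edit.end,
                "covered_plus": p,
                "covered_minus": m,
                "category": category,
                "best_cut": best.site.cut if best else None,
                "best_strand": best.site.strand if best else None,
                "best_plus_offset": best.plus_offset if best else None,
                "best_minus_offset": best.minus_offset if best else None,
            }
        )

    n = len(rows)
    columns = [
        "variant_index", "ref_name", "id", "kind", "start", "end",
        "covered_plus", "covered_minus", "category", "best_cut",
        "best_strand", "best_plus_offset", "best_minus_offset",
    ]
    per_variant = pd.DataFrame(rows, columns=columns)
    if n == 0:
        fr_plus = fr_minus = fr_both = fr_minus_only = fr_neither = 0.0
    else:
        fr_plus = n_plus / n
        fr_minus = n_minus / n
        fr_both = n_both / n
        fr_minus_only = fr_minus - fr_both
        fr_neither = (per_variant["category"] == "neither").sum() / n
    return CoverageSummary(
        n_variants=n,
        covered_plus=fr_plus,
        covered_minus=fr_minus,
        covered_both=fr_both,
        minus_only=fr_minus_only,
        neither=fr_neither,
        per_variant=per_variant,
        n_skipped=len(skipped),
        skipped=skipped,
    )


def dedupe_variants(
    variants: Sequence[AnnotatedVariant],
    significance_filter: frozenset[str] | set[str] | None = frozenset({"Pathogenic"}),
) -> list[AnnotatedVariant]:
    """De-duplicate a panel by variant ID, then filter by significance.

    The first occurrence of each ID is kept (records without an ID are
    never collapsed).  With the default filter only records labelled
    Pathogenic survive; pass ``None`` to keep all labels.
    """
    seen: set[str] = set()
    out: list[AnnotatedVariant] = []
    for v in variants:
        if v.id is not None:
            if v.id in seen:
                continue
            seen.add(v.id)
        out.append(v)
    if significance_filter is not None:
        out = [v for v in out if v.significance in significance_filter]
    return out


def expected_plus_coverage(plus_window: int) -> float:
    """Approximate closed-form +window coverage on an i.i.d. uniform genome.

    A uniformly random SNV is inside the +window of some NGG site when at
    least one of ``2 * plus_window`` (both strands) specific dinucleotide
    slots is GG, each with probability 1/16, giving
    ``1 - (15/16) ** (2 * plus_window)`` under slot independence.

    The slots overlap and are positively correlated, so this is an upper
    bound: for the default 6-bp window the exact per-position coverage
    (by enumeration over the relevant bases) is ~0.494 for the +window
    and ~0.484 for the -window, versus 0.539 from this formula.
    """
    return 1.0 - (15.0 / 16.0) ** (2 * plus_window)


# --- panel I/O -------------------------------------------------------------

def read_variants_tsv(path: str | Path) -> list[AnnotatedVariant]:
    """Read a plain TSV panel: name, position, ref, alt, id, significance.

    ``position`` is 0-based; an empty ref allele denotes an insertion at
    that inter-base coordinate, an empty alt a deletion.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        pos = int(row["position"])
        ref_a = row.get("ref", "").strip()
        alt_a = row.get("alt", "").strip()
        if not ref_a:
            edit = EditSpec("insertion", pos, pos, alt_allele=alt_a)
        elif not alt_a:
            edit = EditSpec("deletion", pos, pos + len(ref_a), ref_allele=ref_a)
        else:
            edit = EditSpec(
                "substitution", pos, pos + len(ref_a), ref_allele=ref_a,
                alt_allele=alt_a,
            )
        out.append(
            AnnotatedVariant(
                ref_name=row["name"],
                edit=edit,
                id=row.get("id") or None,
                significance=row.get("significance") or None,
            )
        )
    return out


def read_variants_vcf(path: str | Path) -> list[AnnotatedVariant]:
    """Read SNV/indel records from a VCF (CHROM/POS/REF/ALT; 1-based POS).

    The usual anchor-base convention is unwound: ``A -> AG`` becomes an
    insertion, ``AG -> A`` a deletion; same-length alleles become a
    substitution.  Multi-allelic records contribute one variant per ALT.
    """
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            pos0 = rec.pos - 1
            ref_a = rec.ref.upper()
            for alt in rec.alts or ():
                alt = alt.upper()
                if len(ref_a) == len(alt):
                    edit = EditSpec(
                        "substitution", pos0, pos0 + len(ref_a),
                        ref_allele=ref_a, alt_allele=alt,
                    )
                elif len(alt) > len(ref_a) and alt.startswith(ref_a):
                    edit = EditSpec(
                        "insertion", pos0 + len(ref_a), pos0 + len(ref_a),
                        alt_allele=alt[len(ref_a):],
                    )
                elif len(ref_a) > len(alt) and ref_a.startswith(alt):
                    edit = EditSpec(
                        "deletion", pos0 + len(alt), pos0 + len(ref_a),
                        ref_allele=ref_a[len(alt):],
                    )
                else:
                    edit = EditSpec(
                        "substitution", pos0, pos0 + len(ref_a),
                        ref_allele=ref_a, alt_allele=alt,
                    )
                out.append(
                    AnnotatedVariant(
                        ref_name=rec.chrom, edit=edit, id=rec.id,
                        significance=_clnsig(rec),
                    )
                )
    return out


def _clnsig(rec) -> str | None:
    sig = rec.info.get("CLNSIG") if "CLNSIG" in rec.info else None
    if sig is None:
        return None
    if isinstance(sig, (tuple, list)):
        sig = sig[0]
    return str(sig)
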