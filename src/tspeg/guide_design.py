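"""Construction of guide/template molecules and the in-silico editing oracle.

Five construct types are built around a chosen cleavage site and edit:

* ``sgrna`` — a plain cleaving guide (20-nt spacer + scaffold).
* ``pegrna`` — canonical prime-editing guide: spacer, scaffold, RTT, PBS
  (5'->3'; PBS at the 3' terminus).  Its 3' extension is antisense to the
  PAM strand, so reverse transcription writes downstream (+) edits into
  the non-target strand.
* ``tsp_pegrna`` — target-strand-programming pegRNA: same part order, but
  PBS and RTT carry *sense* (PAM-strand) polarity so they pair with the
  target strand around the cut, and reverse transcription writes upstream
  (-) edits into the target strand.
* ``actrna_t`` — accessory template RNA paired with a cleaving sgRNA: a
  non-cleaving 15-nt spacer plus the identical sense-polarity RTT+PBS
  extension of the tsp-pegRNA.
* ``hdr_ssdna`` — single-stranded HDR donor with 35-nt homology arms
  complementary to the target strand.

All geometry is computed in a single PAM-strand frame: reverse-strand
sites are mirror-transformed onto the forward strand, designed there, and
the result mapped back — the strand-symmetry property tests rely on this.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .editable_space import edit_offsets
from .errors import DesignError, PrimingFailureError, TspegError, WrongArchitectureError
from .seqcore import (
    EditSpec,
    PamSite,
    ReferenceSequence,
    apply_edit,
    reverse_complement,
)

# Canonical SpCas9 sgRNA scaffold, written in DNA alphabet.  Treated as an
# opaque, configurable token throughout; no logic depends on its content.
DEFAULT_SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC"
)

SPACER_LEN = 20
ANCHOR_SPACER_LEN = 15


@dataclass(frozen=True)
class DesignParams:
    """Tunable design geometry.

    ``pbs_len`` (default 13) and ``homology_len`` (default 20) follow
    routine prime-editing practice; ``hdr_arm_len`` (default 35) sizes the
    ssDNA donor homology arms.  ``output_alphabet`` selects DNA (default,
    for oligo ordering) or RNA transliteration on emission.
    """

    pbs_len: int = 13
    homology_len: int = 20
    scaffold: str = DEFAULT_SCAFFOLD
    hdr_arm_len: int = 35
    output_alphabet: str = "DNA"

    def __post_init__(self) -> None:
        if self.pbs_len < 1 or self.homology_len < 1 or self.hdr_arm_len < 1:
            raise ValueError("pbs_len, homology_len, hdr_arm_len must be >= 1")
        if self.output_alphabet not in ("DNA", "RNA"):
            raise ValueError("output_alphabet must be 'DNA' or 'RNA'")


@dataclass
class GuideConstruct:
    """A designed construct with its parts itemized 5'->3'."""

    construct_type: str
    parts: dict[str, str]  # insertion-ordered: 5'->3'
    site: PamSite
    edit: EditSpec | None
    params: DesignParams
    qc_warnings: list[str] = field(default_factory=list)

    @property
    def full_seq(self) -> str:
        return "".join(self.parts.values())

    def emit_seq(self) -> str:
        """Sequence in the configured output alphabet (RNA for RNA constructs)."""
        seq = self.full_seq
        if self.params.output_alphabet == "RNA" and self.construct_type != "hdr_ssdna":
            seq = seq.replace("T", "U")
        return seq

    @property
    def spacer(self) -> str | None:
        return self.parts.get("spacer")

    @property
    def extension(self) -> str | None:
        """3' extension (RTT + PBS) for pegRNA-like constructs."""
        if "rtt" in self.parts and "pbs" in self.parts:
            return self.parts["rtt"] + self.parts["pbs"]
        return None


# --- PAM-strand frame ------------------------------------------------------

@dataclass(frozen=True)
class _Frame:
    """A design problem mirror-transformed so the site is forward-strand."""

    ref: ReferenceSequence
    site: PamSite
    edit: EditSpec | None
    mirrored: bool


def _to_frame(
    ref: ReferenceSequence, site: PamSite, edit: EditSpec | None = None
) -> _Frame:
    if site.strand == "forward":
        return _Frame(ref=ref, site=site, edit=edit, mirrored=False)
    L = len(ref)
    mirrored_site = PamSite(
        cut=L - site.cut,
        strand="forward",
        pam_start=L - site.pam_end,
        pam_end=L - site.pam_start,
        pam_seq=site.pam_seq,
    )
    mirrored_ref = ReferenceSequence(ref.name, reverse_complement(ref.seq))
    mirrored_edit = edit.mirror(L) if edit is not None else None
    return _Frame(ref=mirrored_ref, site=mirrored_site, edit=mirrored_edit, mirrored=True)


def _slice(frame: _Frame, start: int, end: int, what: str) -> str:
    if start < 0 or end > len(frame.ref):
        raise DesignError(
            f"{what} window [{start}, {end}) runs outside the sequence "
            f"(length {len(frame.ref)})"
        )
    return frame.ref.seq[start:end]


# --- constructs ------------------------------------------------------------

def design_sgrna(
    ref: ReferenceSequence, site: PamSite, params: DesignParams | None = None
) -> GuideConstruct:
    """Cleaving sgRNA: the 20 nt immediately 5' of the PAM, plus scaffold."""
    params = params or DesignParams()
    frame = _to_frame(ref, site)
    p = frame.site.pam_start
    spacer = _slice(frame, p - SPACER_LEN, p, "protospacer")
    return GuideConstruct(
        construct_type="sgrna",
        parts={"spacer": spacer, "scaffold": params.scaffold},
        site=site,
        edit=None,
        params=params,
    )


def design_pegrna(
    ref: ReferenceSequence,
    site: PamSite,
    edit: EditSpec,
    params: DesignParams | None = None,
) -> GuideConstruct:
    """Canonical pegRNA for a downstream (+) edit.

    PBS is the reverse complement of the ``pbs_len`` PAM-strand bases
    immediately upstream of the cut; RTT is the reverse complement of the
    *edited* PAM-strand sequence from the cut through the edit plus
    ``homology_len`` bases beyond its far edge, so the edit-proximal bases
    sit at the RTT 3' end, adjacent to the PBS.
    """
    params = params or DesignParams()
    edit.validate(ref)
    frame = _to_frame(ref, site, edit)
    cut, fedit = frame.site.cut, frame.edit
    assert fedit is not None
    if fedit.start < cut:
        raise WrongArchitectureError(
            "edit lies upstream of the cut; a canonical pegRNA writes only "
            "downstream (+) edits — use design_tsp_pegrna instead"
        )
    spacer = _slice(frame, frame.site.pam_start - SPACER_LEN, frame.site.pam_start,
                    "protospacer")
    pbs = reverse_complement(_slice(frame, cut - params.pbs_len, cut, "PBS"))
    edited = apply_edit(frame.ref, fedit)
    far_edge = fedit.start + len(fedit.alt_allele)  # edited coords
    if far_edge + params.homology_len > len(edited):
        raise DesignError("RTT homology window runs past the sequence end")
    rtt = reverse_complement(edited[cut : far_edge + params.homology_len])
    return GuideConstruct(
        construct_type="pegrna",
        parts={"spacer": spacer, "scaffold": params.scaffold, "rtt": rtt, "pbs": pbs},
        site=site,
        edit=edit,
        params=params,
    )


def design_tsp_pegrna(
    ref: ReferenceSequence,
    site: PamSite,
    edit: EditSpec,
    params: DesignParams | None = None,
) -> GuideConstruct:
    """tsp-pegRNA for an upstream (-) edit.

    The 3' extension has sense (PAM-strand) polarity: PBS equals the
    ``pbs_len`` PAM-strand bases immediately downstream of the cut (pairing
    antiparallel with the target-strand 3' terminus), and RTT equals the
    edited PAM-strand sequence from ``homology_len`` bases beyond the
    edit's far upstream edge through the cut.
    """
    params = params or DesignParams()
    edit.validate(ref)
    frame = _to_frame(ref, site, edit)
    cut, fedit = frame.site.cut, frame.edit
    assert fedit is not None
    if fedit.kind == "insertion":
        if fedit.start > cut:
            raise WrongArchitectureError(
                "insertion lies downstream of the cut; use design_pegrna"
            )
    elif fedit.end > cut:
        raise WrongArchitectureError(
            "edit extends downstream of the cut; a tsp-pegRNA writes only "
            "upstream (-) edits — use design_pegrna instead"
        )
    spacer = _slice(frame, frame.site.pam_start - SPACER_LEN, frame.site.pam_start,
                    "protospacer")
    pbs = _slice(frame, cut, cut + params.pbs_len, "PBS")
    if fedit.start - params.homology_len < 0:
        raise DesignError("RTT homology window runs past the sequence start")
    edited = apply_edit(frame.ref, fedit)
    delta = len(fedit.alt_allele) - (fedit.end - fedit.start)
    rtt = edited[fedit.start - params.homology_len : cut + delta]
    return GuideConstruct(
        construct_type="tsp_pegrna",
        parts={"spacer": spacer, "scaffold": params.scaffold, "rtt": rtt, "pbs": pbs},
        site=site,
        edit=edit,
        params=params,
    )


def _orthogonal_15mer(ref: ReferenceSequence, seed: int = 0xA5) -> str:
    """Deterministically pick a 15-mer absent from ref (either strand)."""
    rng = random.Random(seed)
    rc = reverse_complement(ref.seq)
    while True:
        cand = "".join(rng.choice("ACGT") for _ in range(ANCHOR_SPACER_LEN))
        if cand not in ref.seq and cand not in rc:
            return cand


def design_actrna_t(
    ref: ReferenceSequence,
    site: PamSite,
    edit: EditSpec,
    params: DesignParams | None = None,
    anchor_policy: str = "genomic_downstream",
    orthogonal_spacer: str | None = None,
) -> tuple[GuideConstruct, GuideConstruct]:
    """Dual-RNA design: cleaving sgRNA + ActRNA:t for an upstream (-) edit.

    The ActRNA:t carries a 15-nt non-cleaving spacer and the identical
    sense-polarity RTT+PBS extension a tsp-pegRNA would carry for the same
    edit.  Under ``genomic_downstream`` the 15-mer anchors next to an
    opposite-strand PAM 10-65 bp downstream of the cut; since anchorage
    position is empirically irrelevant, absence of a qualifying PAM falls
    back to an orthogonal 15-mer with a logged notice.
    """
    params = params or DesignParams()
    if anchor_policy not in ("genomic_downstream", "orthogonal"):
        raise ValueError(f"unknown anchor_policy {anchor_policy!r}")
    sg = design_sgrna(ref, site, params)
    tsp = design_tsp_pegrna(ref, site, edit, params)
    warnings: list[str] = []

    anchor: str | None = None
    if anchor_policy == "genomic_downstream":
        anchor = _find_downstream_anchor(ref, site)
        if anchor is None:
            warnings.append(
                "no opposite-strand PAM 10-65 bp downstream of the cut; "
                "falling back to an orthogonal anchor spacer"
            )
    if anchor is None:
        if orthogonal_spacer is not None:
            if len(orthogonal_spacer) != ANCHOR_SPACER_LEN:
                raise DesignError("orthogonal anchor spacer must be 15 nt")
            anchor = orthogonal_spacer.upper()
        else:
            anchor = _orthogonal_15mer(ref)

    act = GuideConstruct(
        construct_type="actrna_t",
        parts={
            "spacer": anchor,
            "scaffold": params.scaffold,
            "rtt": tsp.parts["rtt"],
            "pbs": tsp.parts["pbs"],
        },
        site=site,
        edit=edit,
        params=params,
        qc_warnings=warnings,
    )
    return sg, act


def _find_downstream_anchor(
    ref: ReferenceSequence, site: PamSite, min_dist: int = 10, max_dist: int = 65
) -> str | None:
    """15-mer next to an opposite-strand PAM 10-65 bp downstream of the cut."""
    frame = _to_frame(ref, site)
    seq, cut = frame.ref.seq, frame.site.cut
    # Opposite strand in the frame = reverse strand = CCN on the frame-forward
    # sequence; its 15-nt protospacer lies 3' of the CCN in forward coords.
    best: tuple[int, str] | None = None
    for p in range(max(0, cut + min_dist), min(len(seq) - 2, cut + max_dist + 1)):
        if seq[p] == "C" and seq[p + 1] == "C":
            start, end = p + 3, p + 3 + ANCHOR_SPACER_LEN
            if end > len(seq):
                continue
            spacer = reverse_complement(seq[start:end])
            dist = p - cut
            if best is None or dist < best[0]:
                best = (dist, spacer)
    return best[1] if best else None


def design_hdr_ssdna_donor(
    ref: ReferenceSequence,
    site: PamSite,
    edit: EditSpec,
    params: DesignParams | None = None,
) -> GuideConstruct:
    """ssDNA HDR donor complementary to the target strand.

    Emitted in PAM-strand orientation (the complement of the target
    strand): ``hdr_arm_len`` left arm + alt allele + ``hdr_arm_len`` right
    arm, centered on the edit.
    """
    params = params or DesignParams()
    edit.validate(ref)
    frame = _to_frame(ref, site, edit)
    fedit = frame.edit
    assert fedit is not None
    left = _slice(frame, fedit.start - params.hdr_arm_len, fedit.start, "left arm")
    right = _slice(frame, fedit.end, fedit.end + params.hdr_arm_len, "right arm")
    return GuideConstruct(
        construct_type="hdr_ssdna",
        parts={"left_arm": left, "edit": fedit.alt_allele, "right_arm": right},
        site=site,
        edit=edit,
        params=params,
    )


# --- in-silico prime-editing round trip ------------------------------------

def _check_priming(pbs_pairing_ok: list[bool]) -> None:
    mismatches = [i + 1 for i, ok in enumerate(pbs_pairing_ok) if not ok]
    if mismatches:
        raise PrimingFailureError(
            f"PBS/primer mismatch at PBS position(s) {mismatches} "
            "(1-based from the PBS 5' border)",
            mismatch_positions=mismatches,
        )


def simulate_prime_edit(ref: ReferenceSequence, construct: GuideConstruct) -> str:
    """Reconstruct cut -> prime -> resolve for a pegRNA-like construct.

    Cuts the reference at the construct's site, verifies exact PBS pairing
    with the appropriate 3' primer terminus (non-target-strand upstream
    fragment for a canonical pegRNA; target-strand downstream fragment for
    tsp-pegRNA / ActRNA:t), copies the RTT into a virtual 3' flap and
    resolves it against the reference by its terminal homology.  Returns
    the edited duplex as a forward-strand string.
    """
    if construct.construct_type not in ("pegrna", "tsp_pegrna", "actrna_t"):
        raise TspegError(
            f"cannot simulate prime editing for a {construct.construct_type}"
        )
    frame = _to_frame(ref, construct.site)
    seq, cut = frame.ref.seq, frame.site.cut
    pbs, rtt = construct.parts["pbs"], construct.parts["rtt"]
    k = min(construct.params.homology_len, len(rtt))

    if construct.construct_type == "pegrna":
        # Primer: 3' terminus of the upstream non-target-strand fragment.
        if cut - len(pbs) < 0:
            raise DesignError("cut too close to the sequence start for the PBS")
        expected = reverse_complement(seq[cut - len(pbs) : cut])
        _check_priming([a == b for a, b in zip(pbs, expected)])
        flap = reverse_complement(rtt)  # extends the PAM strand from the cut
        tail = flap[-k:]
        m = seq.find(tail, cut)
        if m < 0:
            raise TspegError("flap homology not found downstream of the cut")
        edited = seq[:cut] + flap + seq[m + k :]
    else:
        # Primer: 3' terminus of the downstream target-strand fragment,
        # which pairs antiparallel with the sense-polarity PBS.
        if cut + len(pbs) > len(seq):
            raise DesignError("cut too close to the sequence end for the PBS")
        expected = seq[cut : cut + len(pbs)]
        _check_priming([a == b for a, b in zip(pbs, expected)])
        flap = rtt  # sense polarity: already PAM-strand orientation
        head = flap[:k]
        m = seq.rfind(head, 0, cut)
        if m < 0:
            raise TspegError("flap homology not found upstream of the cut")
        edited = seq[:m] + flap + seq[cut:]

    return reverse_complement(edited) if frame.mirrored else edited


# --- construct QC ----------------------------------------------------------

PBS_5PRIME_CRITICAL = 6  # PBS positions (from the 5' border) where mismatches
                         # are poorly tolerated and can abolish priming


def qc_construct(construct: GuideConstruct, ref: ReferenceSequence) -> list[str]:
    """Advisory warnings for a designed construct.

    Reports (a) PBS/genomic-primer mismatches with 1-based positions from
    the PBS 5' border (5'-proximal mismatches are flagged critical, as
    they can nearly abolish reverse-transcription priming), (b) runs of
    >= 4 consecutive T (U6 terminator risk), (c) a spacer not starting
    with G (U6 expression efficiency), and (d) a cut within 20 nt of a
    sequence edge.
    """
    warnings: list[str] = []
    frame = _to_frame(ref, construct.site)
    seq, cut = frame.ref.seq, frame.site.cut

    pbs = construct.parts.get("pbs")
    if pbs is not None:
        if construct.construct_type == "pegrna":
            lo = cut - len(pbs)
            expected = (
                reverse_complement(seq[lo:cut]) if lo >= 0 else None
            )
        else:
            hi = cut + len(pbs)
            expected = seq[cut:hi] if hi <= len(seq) else None
        if expected is None:
            warnings.append("PBS window runs outside the sequence")
        else:
            for i, (a, b) in enumerate(zip(pbs, expected)):
                if a != b:
                    pos = i + 1
                    tag = " (5'-critical)" if pos <= PBS_5PRIME_CRITICAL else ""
                    warnings.append(
                        f"PBS mismatch vs genomic primer at PBS position {pos}{tag}"
                    )

    if construct.construct_type != "hdr_ssdna" and "TTTT" in construct.full_seq:
        warnings.append("poly-T run (>=4 T) in transcribed construct: U6 terminator risk")

    spacer = construct.spacer
    if spacer and construct.construct_type != "hdr_ssdna" and not spacer.startswith("G"):
        warnings.append("spacer does not start with G (U6 expression efficiency)")

    if cut < 20 or len(seq) - cut < 20:
        warnings.append("cut within 20 nt of a sequence edge")

    return warnings


# --- batch output ----------------------------------------------------------

def design_sheet(constructs: list[GuideConstruct]):
    """One-row-per-construct design sheet as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for c in constructs:
        off = (
            edit_offsets(c.edit, c.site) if c.edit is not None else None
        )
        rows.append(
            {
                "construct_type": c.construct_type,
                "cut": c.site.cut,
                "strand": c.site.strand,
                "pam": c.site.pam_seq,
                "plus_offset": off.plus_offset if off else None,
                "minus_offset": off.minus_offset if off else None,
                **{f"part_{k}": v for k, v in c.parts.items()},
                "full_seq": c.emit_seq(),
                "warnings": "; ".join(c.qc_warnings),
            }
        )
    return pd.DataFrame(rows)
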