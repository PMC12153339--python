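# Methods

## Coordinate model

All genomic arithmetic uses 0-based, half-open intervals on the forward
strand. A Cas9 cleavage is an integer inter-base coordinate: for a
forward-strand PAM occupying `[p, p+3)` the blunt cut is at `p - 3`; for a
reverse-strand PAM (CCN on the forward strand at `[p, p+3)`) it is at
`p + 6`. Editing-window positions are counted in PAM-strand orientation:
the "+1" base occupies `[cut, cut+1)` on the PAM strand, "-1" the base
immediately upstream. An insertion exactly at the cut is simultaneously
+1 (for non-target-strand writing) and -1 (for target-strand writing);
this is the limiting case used for edits that span the cut, which report
offsets (+1, -1). For multi-base substitutions and deletions the offset of
a side is measured to the most cut-proximal altered base on that side —
the convention consistent with single-position numbering, since no
published definition exists for multi-base edits.

Every design routine works in a single PAM-strand frame: a reverse-strand
site is mirror-transformed (reference reverse-complemented, coordinates
reflected, the edit mirrored), designed as a forward-strand problem, and
mapped back. Strand symmetry is therefore structural, and is additionally
asserted by tests.

## Construct geometry

With cut `c`, PBS length `b` (default 13) and RTT homology length `h`
(default 20), on the PAM-strand frame and writing `E` for the edited
sequence:

* canonical pegRNA (downstream/+ edits, written into the non-target
  strand): `PBS = revcomp(ref[c-b : c])`; `RTT = revcomp(E[c : far+h])`
  where `far` is the downstream edge of the edit in edited coordinates.
  The extension `RTT + PBS` is a contiguous substring of the reverse
  complement of the edited PAM strand.
* tsp-pegRNA (upstream/- edits, written into the target strand):
  `PBS = ref[c : c+b]` and `RTT = E[near-h : c']` in *sense* polarity,
  where `near` is the upstream edge of the edit and `c'` the cut in edited
  coordinates. The extension is a contiguous substring of the edited PAM
  strand itself — the "opposite strand polarity" made literal. With
  `b = h` the two extensions are exact reverse complements for the same
  cut-site insertion, which is asserted on random loci.
* ActRNA:t: a 15-nt non-cleaving spacer plus the identical tsp extension,
  paired with the 20-nt cleaving sgRNA. The default anchor policy picks a
  15-mer adjacent to an opposite-strand PAM 10-65 bp downstream of the
  cut; since anchorage position is empirically irrelevant, absence of a
  qualifying PAM falls back to a deterministic orthogonal 15-mer absent
  from the reference (logged as a construct warning).
* HDR ssDNA donor: 35-nt homology arms flanking the alt allele, emitted
  complementary to the target strand (PAM-strand orientation).

Constructs are emitted in DNA alphabet by default (oligo-ordering
convention); RNA output transliterates T→U. The scaffold is a single
configurable constant treated as an opaque token. 5'-G prepending for U6
expression is not performed; a missing leading G is a QC warning only.

## In-silico round trip

`simulate_prime_edit` replays the model mechanism: cut the reference at
the construct's site; verify the PBS pairs *exactly* with the appropriate
primer 3' terminus (upstream non-target-strand fragment for canonical,
downstream target-strand fragment for tsp/ActRNA:t — any mismatch raises
a priming failure listing positions from the PBS 5' border); copy the RTT
as a 3' flap; resolve the flap against the reference by locating its
terminal homology block (`h`-mer) nearest the cut on the far side. For
every designed construct this reconstruction must equal
`apply_edit(ref, edit)` exactly; this round trip is the package's primary
internal oracle and is exercised on hundreds of random
(locus, site, edit) triples per test run. Resolution by homology search
can in principle be ambiguous if the flap's terminal `h`-mer recurs
adjacent to the cut (e.g. perfect tandem repeats); with the default
20-bp homology on random or genomic sequence this is not observed.

## Editing-window survey

`survey_variants` classifies each panel variant against every usable
cleavage site of its reference (full 20-nt protospacer required by
default; sites are prefiltered by cut proximity, which is exact because a
site farther than `window+1` from the edit cannot qualify) and aggregates
five fractions: covered by +window, by -window, by both, -window only,
and neither. Variants whose stated ref allele contradicts the reference
are skipped and logged. Candidate sites for one edit are ranked by
smallest in-window offset, then fewer QC flags, lower cut, forward strand.

On an i.i.d. uniform genome the probability that a random SNV is covered
by a 6-bp window is often approximated as `1 - (15/16)^12` (twelve
dinucleotide slots, each GG with probability 1/16). The slots overlap and
are positively correlated, so the formula (0.539) overestimates: exact
enumeration over the relevant bases gives 0.494 for the +window and 0.484
for the -window. The tests assert the exact values; the closed form is
retained as a documented upper bound. Real-genome coverage additionally
depends on GC content and PAM clustering, so synthetic-panel fractions do
not transfer to curated clinical variant sets.

## Outcome classification

Reads pass a mean-Phred ≥ 30 filter (inclusive), then are globally
aligned — affine gaps, scores 5 / -4 / -8 / -2, both orientations — to
the reference and to the intended edited amplicon. The quantification
window is the union of the cut and the intended edit span extended by a
30-bp half-width ("extend 30 bp" is read as a half-width; configurable).
Decision order, driven by the better-scoring amplicon:

1. **accurate** — intended edit fully present, no indels in the window.
   Isolated point mismatches are tolerated as sequencing error: a
   mismatch-strict rule would misclassify ~6% of reads at a realistic
   0.1% per-base error (window ≈ 60 bp) and would make the
   imprecise category unreachable in the stated decision order.
2. **imprecise prime edit** ("imperfect HDR") — the intended edit (or at
   least a 50% prefix of an insertion's new bases; threshold
   configurable) present, but with extra indels in the window.
3. **indel** — a window indel without the intended edit.
4. **unedited** — matches the reference without window indels.
5. **ambiguous** — equal-score ties not resolved above.

Frequencies are reported over aligned reads (the five categories
partition them); quality-failures and unalignable reads are counted as
filtered. Per-position SNV calls below 0.1% of reads are discarded;
exactly 0.1% is retained. This is a standalone implementation of these
quantification rules, not a wrapper around an existing amplicon-analysis
tool, and exact parity with any such tool's internals is not claimed.

## Synthetic data

Generators are deterministic under a fixed seed. Genomes are i.i.d. with
configurable GC. Read mixtures allocate category counts by largest
remainder (exact expectations for classifier tests; multinomial optional):
accurate = edited amplicon; unedited = reference; indel = reference with
a random 1-10-nt indel within ±10 bp of the cut (well inside the
quantification window, mirroring Cas9 repair outcomes); imprecise =
edited amplicon with 1-2 extra 1-nt indels near the cut but outside the
intended edit span. Substitution sequencing errors are then applied per
base. Two label-purity rules keep truth labels semantically valid:
"indel" candidates are rejected if the random insertion could realize the
intended edit (it contains the leading half of the alt allele near the
edit position, or is an equal-length insertion at the edit position,
which reads as pure mismatches against the edited amplicon); insertion
positions are first canonicalized over their repeat-equivalence interval,
since an insertion inside a homopolymer or tandem repeat slides and can
reach the edit site from several base pairs away; "imprecise"
candidates are regenerated until a net length change remains (a paired
insertion+deletion can cancel). With these rules the error-free confusion
matrix is exactly diagonal for the 1-nt cut-site insertion configuration
used in the quantitative tests; rare (<1%) label/class disagreements
remain possible for multi-base and deletion intended edits, where
alignment degeneracy blurs the category boundary — a known limitation.
The generators model neither sequencer-specific error profiles nor PCR
duplicates, so passing tests demonstrate correctness of the decision
rules, not robustness to real instrument noise.

## Off-target scanning

Candidate enumeration is exhaustive: every both-strand 23-mer window with
a pattern-matched PAM and spacer Hamming distance ≤ 4 (default; PAM bases
never counted), vectorized with numpy sliding windows, capped at 100 Mb
total (desk-scale by design; no bulge support, no position weighting —
candidates are taken as nominated). Mismatch positions are 1-based from
the spacer 5' end. `pbs_priming_mismatches` rebuilds the hypothetical
primer at a candidate cut with on-target geometry (upstream NTS 13-mer
for canonical, downstream TS 13-mer for tsp/ActRNA:t) and counts
PBS/primer disagreements — the quantity that predicts whether
reverse transcription can fire at an off-target break. An N in the
reference never matches a fixed PAM base; pattern N matches anything.

## Parameters at a glance

| parameter | default | meaning |
|---|---|---|
| `pbs_len` | 13 nt | primer-binding site length |
| `homology_len` | 20 nt | RTT homology beyond the edit |
| `hdr_arm_len` | 35 nt | ssDNA donor arm length |
| `plus_window`/`minus_window` | 6 bp | favorable editing windows |
| `min_mean_quality` | Q30 | read filter (inclusive) |
| `indel_window_halfwidth` | 30 bp | quantification window half-width |
| alignment scores | 5/-4/-8/-2 | match/mismatch/gap open/extend |
| `snv_frequency_floor` | 0.1% | per-position variant floor |
| `max_mismatches` | 4 | off-target Hamming budget |
| anchor PAM distance | 10-65 bp | ActRNA:t genomic anchor search |

## Problem sizes

The verification suite uses 1 Mb for PAM density, 500 random triples for
the round trip, 100 loci for the polarity identity, 50 references × 20
variants for the survey-vs-brute-force equivalence (plus a 500-SNV panel
on 20 kb in the acceptance script), n = 2000 reads for classifier
recovery, and a 100-kb genome for planted off-target recovery — sizes at
which the brute-force oracles remain exact and the statistical tests have
the power the tolerances assume.
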