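# tspeg — target-strand prime-editing design toolkit

SpCas9-based prime editors write edits by reverse transcription from the
3'-OH end exposed at the nick/cut placed 3 nt upstream of an NGG PAM. A
canonical pegRNA extends the **non-target strand (NTS)**, so only positions
*downstream* of the cut (+1, +2, ...) are editable, and efficiency collapses
beyond about +6. Because NGG PAMs occur on average only once per 8 bp
(both strands), many intended edit positions — including a large share of
pathogenic SNVs — have no cleavage site that places them inside this
"+6 window".

Target-strand editing inverts the geometry. A **tsp-pegRNA**
(target-strand-programming pegRNA) keeps the ordinary 20-nt cleaving spacer
but carries a 3' extension of *opposite strand polarity*: its PBS and RTT
are complementary to the **target strand (TS)** around the cut, so reverse
transcription extends the downstream TS fragment and writes edits *upstream*
of the cut (-1 ... -6). The same extension can instead ride on an
**ActRNA:t** — a non-cleaving accessory RNA with a shortened 15-nt spacer —
paired with a plain cleaving sgRNA (a dual-RNA design; the anchoring 15-mer
turns out to be functionally irrelevant, so orthogonal spacers work too).
Together the +6 and -6 windows roughly double the editable space around
each cleavage site.

This package is a desk-scale toolkit for scientists designing and analyzing
such experiments. It provides:

* **seqcore** — 0-based half-open coordinates, inter-base cut positions,
  both-strand IUPAC PAM scanning, edit application, FASTA I/O.
* **editable_space** — +N/-N window geometry (`edit_offsets`,
  `classify_edit`) and panel-scale coverage surveys (`survey_variants`,
  VCF/TSV input, de-duplication and significance filtering).
* **guide_design** — sequence-exact construction of sgRNA, canonical
  pegRNA, tsp-pegRNA, sgRNA+ActRNA:t pairs, and 35-bp-arm ssDNA HDR
  donors (defaults: 13 bp PBS, 20 bp RTT homology), plus
  `simulate_prime_edit`, an in-silico cut → prime → resolve oracle that
  verifies every design reproduces the intended edited sequence, and
  advisory QC (PBS/primer integrity with 5'-critical flagging, poly-T
  runs, spacer 5'-G, edge proximity).
* **outcome_classify** — standalone amplicon-read classification into
  accurate / imprecise prime edit / indel / unedited / ambiguous, with a
  mean-Q30 filter, affine-gap global alignment against both the reference
  and the edited amplicon, a 30-bp half-width quantification window, and
  a 0.1% SNV frequency floor.
* **offtarget** — exhaustive both-strand Hamming enumeration of candidate
  off-target sites (≤4 mismatches, PAM-matched) and PBS priming-mismatch
  annotation at candidate cuts (a handful of priming mismatches is what
  suppresses reverse-transcription-driven insertions off-target).
* **synthetic_data** — seeded generators for random genomes, variant
  panels, programmed read mixtures with truth labels, and planted
  off-target sites; every pipeline is testable without any download.
* **cli** — `tspeg design|survey|classify|offtarget|simulate` with a
  reproducibility manifest per run.

## Worked example

A 60-mer toy locus with a forward-strand PAM `TGG` starting at position 25,
hence a blunt cut at inter-base 22, and a 1-nt insertion `A` exactly at the
cut (position +1 on the NTS, -1 on the TS):

```python
from tspeg import (ReferenceSequence, EditSpec, scan_pams,
                   design_pegrna, design_tsp_pegrna,
                   simulate_prime_edit, apply_edit)

ref = ReferenceSequence(
    "TOYREF", "AACCGGTCACCTTGAAGATGCTGAATGGCATTGCAGGATCTCCAAGTTACGGAACCTAGC")
site = [s for s in scan_pams(ref) if s.strand == "forward" and s.pam_start == 25][0]
edit = EditSpec("insertion", 22, 22, alt_allele="A")
tsp = design_tsp_pegrna(ref, site, edit)
peg = design_pegrna(ref, site, edit)
```

Output of printing the parts:

```
cut: 22 strand: forward PAM: TGG
spacer: GTCACCTTGAAGATGCTGAA
tsp PBS: GAATGGCATTGCA
tsp RTT: CCGGTCACCTTGAAGATGCTA
canonical PBS: AGCATCTTCAAGG
canonical RTT: GAGATCCTGCAATGCCATTCT
round trip ok: True
```

Reading the numbers: the tsp-pegRNA PBS is the 13 reference bases
immediately *downstream* of the cut in sense orientation (it pairs
antiparallel with the TS 3' terminus), and its RTT is the 20 bases of
upstream homology plus the inserted `A`, again in sense orientation — both
are literal substrings of the edited top strand. The canonical pegRNA's
PBS/RTT are the reverse complements of the mirrored windows (antisense
polarity; substrings of the edited bottom strand). `simulate_prime_edit`
replays cut, PBS priming, reverse transcription and flap resolution and
returns exactly `apply_edit(ref, edit)` for both architectures.

The same design is available from the shell:

```bash
tspeg design --ref toy.fa --edit ins:22:A --mode tsp --out-dir designs/
```

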