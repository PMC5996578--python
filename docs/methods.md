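# Methods

This note documents the models and procedures behind `neuropep`, the
parameters that matter, the synthetic benchmark's scope, and the
numerical choices made where the design was genuinely open.

## ORF model

Transcripts are translated in all six frames with the standard genetic
code; any codon containing N renders as X (no ambiguity resolution), and
stops render as `*`. Two extraction dialects are offered: `stop_to_stop`
(maximal stop-free stretches with leading residues retained, the default,
matching classical getorf behaviour) and `atg_to_stop` (first Met of each
stretch). Coordinates are 0-based half-open on the forward strand and
include the terminating stop codon; 1-based conversion happens only at
report boundaries. Default minimum ORF length is 60 residues —
full-length neuropeptide precursors are rarely shorter than ~60–90 aa —
and is configurable for short-precursor searches.

## Homology stage

The translated search is exact affine-gap Smith–Waterman (Gotoh) under
BLOSUM62 with gap open 11 / extend 1 (a gap of length k costs
`11 + k`), the standard protein-search scoring. The reference
implementation is a pure-Python DP with a deterministic traceback
(diagonal > vertical > horizontal on ties); panel searches screen scores
with Biopython's C `PairwiseAligner` under the identical scheme — the
optimal score is the same by construction, and the test suite asserts
agreement with an independent cubic DP.

Two guards substitute for BLAST's statistics, which are not reproduced
here:

- **Low-complexity masking.** Homopolymer runs longer than 5 in queries
  are masked to X. Without this, shared poly-Leu signal-peptide cores
  dominate the hit list, exactly as unmasked low-complexity segments do
  in real translated searches.
- **Raw-score threshold, default 170.** Calibrated at design time on the
  synthetic benchmark: shuffled-composition nulls and the chained-repeat
  noise produced by tandem-repeat queries against repeat-bearing
  non-homologs stay ≤ ~130, while genuine full-length precursor matches
  score ≥ ~210. `calibrate_min_score()` re-runs the shuffled-null
  calibration for any panel/database pair. E-values are not computed.

## Signal-peptide heuristic

Discriminative predictors are external programs; the built-in heuristic
uses four features of classical signal-peptide anatomy, applied to each
candidate ORF:

1. initiator Met present (a signal peptide is a feature of a translated
   protein's N-terminus, not of a read-through fragment);
2. hydrophobic h-region: best 8-residue mean Kyte–Doolittle hydropathy
   within residues 1–30 must exceed 2.0 (canonical cores score ~3–4.5;
   random-composition windows have mean −0.49, sd ≈ 1.0);
3. c-region: a small residue (A/G/S/C/T) at both −1 and −3 of a cleavage
   point scanned over residues 15–40 (earliest match reported);
4. cleaved, not anchored: the 30 residues after the cleavage point must
   be < 50% strongly hydrophobic (C/F/I/L/V). This is the classic
   secretory-signal vs signal-anchor distinction; without it, ORFs that
   are hydrophobic along their whole length (antisense read-through,
   membrane-like junk) pass trivially.

External predictions can replace the heuristic entirely via a 3-column
table (id, has_signal, cleavage_after).

## Cleavage-site grammar

Maximal K/R runs are resolved longest-first, left-to-right: runs ≥ 4
report a single tetrabasic (furin-type) site; runs of 2–3 a dibasic site,
with a run-of-3's trailing Arg eligible as monobasic; an isolated Arg is
monobasic only when another basic residue lies 2, 4 or 6 positions
N-terminal (the −3/−5/−7 convertase context rule). Lys alone is never a
monobasic site.

**Monobasic sites are annotated but not cleaved by default.** Single-Arg
contexts frequently fall inside genuine bioactive peptides (the C-termini
of NPF- and luqin-type peptides contain them), so cleaving every
monobasic site would destroy exactly the peptides the site scanner is
meant to liberate. Processing cuts di-/tetrabasic sites;
`cleave_monobasic=True` opts into cutting everything. Repeat detection
segments fragments the same way.

## Prohormone processing

The precursor is partitioned exactly into signal, cleavage motifs,
amidation glycines, trimmed basics and peptide fragments; concatenating
the partition reconstructs the precursor byte-for-byte (a tested
invariant). Rules:

- flanking basic residues trimmed, at most 4 per terminus (the
  tetrabasic maximum);
- a fragment-terminal Gly immediately preceding a cleaved basic site is
  removed and the peptide flagged amidated;
- N-terminal Gln/Glu annotates potential pyroglutamate (fromQ −17.02655
  Da, fromE −18.01056 Da); the modification is *potential*, mirroring
  variable modifications in MS searches, and rendering can show either
  form;
- fragments shorter than 3 residues after trimming are discarded (the
  shortest classical units are tetrapeptides; a floor of 3 avoids
  discarding unreported tripeptides);
- consecutive Cys are paired (1–2, 3–4, …) as disulfide candidates, an
  odd count leaving the last unpaired;
- with zero cleavable sites the whole pro-region is released once,
  flagged `uncleaved`.

## Family rulebook

Families are declarative rules over (sequence, amidated): C-terminal
motifs with `x` wildcards (RFamide `RF`, luqin `WRPQGRF`, NPF `GRPRF`,
CCK/SK `GGGRF`, myomodulin `xxxMLRL`, FxRIamide `xSSFxRI`, buccalin
`GxL`), whole-peptide patterns (`[ARTKS]PGW` tetrapeptides, `FMRF`),
cysteine spacing (allatostatin C: two Cys with exactly 6 between) and
tryptophan spacing (molluscan allatostatin B: N-terminal Trp within the
first two residues, C-terminal Trp-amide, 4 or 5 residues between —
insect spacings of 6–7 are rejected). Rules ship as a plain TSV and are
user-editable; peptides matching nothing are reported `unclassified`
rather than guessed. Frequency matrices take pre-aligned equal-length
input (a C-terminal padding helper is provided); multiple sequence
alignment itself is out of scope.

## MS confirmation

The interface is a filtered search-engine table, not spectra. A match
requires exact sequence equality (Leu/Ile distinct by default, since
identifications are database-driven; a collapse switch exists),
amidation agreement, and pyroglutamate licensed by the predicted
N-terminus (a potential pyroGlu matches observations with or without the
modification). When an observed mass is present, the computed
monoisotopic mass (pyteomics residue masses + water, modification deltas:
amidation −0.98402, Met oxidation +15.99491, dioxidation +31.98983,
N-term acetyl +42.01057) must agree within 10 ppm. The significance
filter is strictly score > 20. Matching is injective per observation;
ties resolve to the lexicographically first precursor and smallest start
coordinate, logged. The 0.05 Da fragment-ion tolerance is carried as
metadata only — no fragment matching is performed.

## NG86 selection analysis

Synonymous/non-synonymous site counting follows Nei–Gojobori: per codon
position, the synonymous fraction among single-nucleotide changes,
excluding changes to stop codons from the denominator; sites averaged
over the two sequences. Multi-hit codons average substitution
classifications over all orderings of the differing positions, skipping
pathways through stop codons (falling back to all pathways if every one
is blocked). Both proportions receive the Jukes–Cantor correction; a
proportion ≥ 3/4 is reported NaN and flagged saturated. The ratio is
undefined when Ks is 0 or saturated. Classes: > 1 strong positive,
(0.5, 1] moderate-positive candidate, ≤ 0.5 purifying; both boundaries
exactly as conventionally printed. Alignments are caller-provided; gap
codons are stripped pairwise. The YN-style transition/transversion and
codon-frequency corrections are deliberately not approximated — NG86 is
implemented in full and audited against a pathway-enumerating oracle.

## Synthetic benchmark

The generator emulates the architecture of molluscan precursors, not
their nucleotide statistics:

- 20 templates spanning the canonical layouts: a tetrabasic-split
  two-domain FMRFamide-type precursor with a 24-copy repeat domain,
  single-copy amidated peptides (luqin-, GnRH-, NPF-style), a
  pyroglutamate candidate (CCK/SK-style), Cys-bridged peptides
  (conopressin-, insulin-like), non-amidated repeat domains (FCAP-,
  pedal-peptide-style), and short pro-region filler domains that pad
  precursors to realistic length;
- reverse translation uses one fixed codon per amino acid
  (alphabetically first, except Ser→TCA so that, like Leu→CTA, it reads
  as a stop on the reverse strand — real antisense strands are
  stop-dense, and this keeps spurious minus-strand ORFs short);
- 5'UTRs end in an in-frame stop immediately before the start codon, as
  upstream-ORF stops do in real UTRs, making the embedded ORF boundary
  exact;
- decoys stress the criteria one at a time: class (a) signal-bearing
  proteins whose mature region is free of K/R (no cleavage
  architecture), class (b) repeat- and site-bearing proteins with a
  hydrophilic N-terminus (no signal);
- default scale 20 precursors + 200 decoys, noise 0 — desk-scale in
  seconds; `noise` applies uniform per-base substitutions up to 0.2;
- the expected-peptide manifest is computed from the template grammar,
  independently of the processing engine, so round-trip tests compare
  two code paths.

The emulated MS table samples each expected peptide at
`detection_rate = 0.3` (a plausible single-run peptidome sampling depth,
chosen a priori), applies potential pyroglutamate half the time, jitters
masses within ±5 ppm, scores true peptides above the 20 threshold and
adds `decoy_peptide_rate = 0.05` random rows with scores straddling it.
Because multi-copy precursors are almost certain to be sampled at least
once, precursor-level confirmation on the benchmark comes out around
65–75%, higher than peptide-level detection.

What passing the benchmark does **not** show: robustness to assembly
artifacts (chimeras, frameshifts), to precursors whose peptides carry
terminal basic residues (the trimming rule would truncate them — such
peptides exist in real data and the templates avoid them), to
low-complexity real UTRs, or to genuine SignalP-grade signal-peptide
variation. The generator's signals are canonical by construction.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen to exercise
every code path in seconds: oracle equivalence on 100 random alignment
pairs (length ≤ 25), 50 random transcripts, 300 cleavage strings and 50
codon-pair sequences; the conservation invariant on 1000 random
precursors; the discovery benchmark at 20 precursors + 200 decoys; the
binomial sampling check over 1000 seeds × 160 peptides.

## Known limitations

- The signal heuristic is a transparent stand-in, not a trained model;
  on real data, feed external predictions through the signal table.
- Raw-score homology filtering needs recalibration when query panels or
  databases change character; no E-values.
- Cleavage is rule-based; quantitative convertase-preference models and
  manual-curation exceptions are out of scope (all rulebook sites are
  reported, so downstream filtering can emulate curation).
- Family rules operate on single sequences; assignments that require
  cross-species alignment context are reported unclassified.
- No FDR estimation for MS matching; the score filter is taken at face
  value.
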