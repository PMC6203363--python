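# Methods

`mircompare` re-annotates a reference miRNA set in a second, closely
related genome and reports what changed: lost loci, copy-number
differences, mature/seed substitutions, cluster/polycistron structure,
and the downstream consequences for seed-match target sets. This note
describes the models, the tunable parameters, and the choices made where
the design was genuinely open.

## Homology recovery

Two searches run side by side:

* **Exact mature mapping.** Every mature is located on both strands with
  zero mismatches at full length (minus-strand hits via the reverse
  complement, reported on the forward axis). Exactness is the point:
  a mature that no longer maps exactly is the first sign of a mature
  polymorphism.
* **Local precursor alignment.** Smith–Waterman with BLASTN-like scores
  (match +2, mismatch −3, gap open −5, extend −2; Biopython's
  `PairwiseAligner`). Query coverage — aligned query span over query
  length — is binned `100` (≥ 0.995, tolerating one clipped terminal
  base), `80–99`, `70–79`, or `rejected` (< 0.70). Chromosomes up to
  50 kb are scanned by full Smith–Waterman; larger ones are fronted by an
  exact 11-mer seed-and-extend step (seeds every 5 nt along the query,
  hits clustered by diagonal, each cluster aligned in a local window).
  The seeding is a speed heuristic only; near-identical loci — the regime
  this comparison operates in — always contain exact 11-mers.

Around each mature anchor, two flank windows are excised — mature on the
5′ arm (`[start−15, end+150)`) or on the 3′ arm (`[start−150, end+15)`)
— plus a third window, the precursor hit span itself (±10 nt). The 15-nt
short-side headroom leaves room for the terminal loop under either arm
hypothesis. All three windows are folded and the best accepted one
(lowest MFEI) becomes the locus; windows containing `N` are discarded.

## The folding model and the precursor gate

Secondary structure is computed by Zuker-style dynamic programming under
a frozen nearest-neighbor model authored for this package: Watson–Crick
and GU pairs, stacking energies per adjacent pair, tabulated
hairpin/bulge/internal loop penalties with `1.75·RT·ln(n/n₀)`
extrapolation, and an affine multiloop penalty (multibranched folds are
scored so they can be *rejected*, not scored precisely). The all-unpaired
structure has energy 0, so MFE ≤ 0 always. An exhaustive enumeration
oracle over all pseudoknot-free structures (feasible to ~20 nt) checks
the DP exactly; acceptance of the model is internal consistency plus
threshold behaviour, not byte-agreement with any external folder.

The model was calibrated once and frozen: with literature-typical stack
values, ~1.3% of random 160-nt windows at 42% GC passed the full
precursor gate, which would flood a genome scan with false hairpins.
Internal-loop penalties were raised by 1.5 kcal/mol, bulges by 1.0, and
every GU-involving stack capped at −0.7 kcal/mol (wobble-rich helices
are precisely what random low-GC sequence uses to imitate a stem).
After freezing: 0/600 random windows accepted, 0 false candidates in a
30-kb scan, and designed hairpins still pass 300/300 with worst-case
MFEI −0.995.

A candidate is accepted as a precursor iff, after trimming, **all** of:

| rule | value | notes |
| --- | --- | --- |
| trimmed stem length | 52–148 nt | the documented precursor size range |
| MFEI | ≤ −0.85 | MFEI = (MFE/len·100)/GC%, GC on the 0–100 scale, computed on the trimmed stem |
| topology | single stem-loop | exactly one terminal loop in the trimmed helix |
| mature placement | one arm | no overlap with the terminal loop |
| mature pairing | ≥ 0.6 | fraction of mature bases paired; tuned once on the synthetic bed, then frozen |

**Trimming** matters: a 185-nt flank window usually folds with the real
hairpin wrapped inside long-range background pairs. The gate therefore
searches every helix of the fold whose subtree is a single stem-loop and
trims to the widest one that contains the mature and fits the length cap
— the precursor's own stem, not the window's accidental superstructure.
MFEI is computed from that stem's energy, span and GC alone.

## De novo scanning

Overlapping 160-nt windows every 20 nt (≥ 87% overlap between
neighbours, so no 52–148-nt locus falls between windows) are folded on
both strands. Every single-stem-loop helix of 52–148 nt in a window is a
candidate; its putative mature is the ~21-nt window on either arm
maximising paired fraction (ties: 5′ arm, then left-most). Candidates
passing the same gate are merged across windows *and strands* (a
hairpin's reverse complement is itself a hairpin) keeping the lowest
MFEI, exon-overlapping candidates are dropped, and candidates containing
a known mature verbatim are labelled `matches-known`. No trained
classifier is involved — the deterministic structural gate is the entire
criterion, which is exactly what makes the scan reproducible.

## Comparison layers

* **Variants.** Recovered locus matures are aligned globally to their
  reference mature (match +1, mismatch −1, gap −2); substitutions are
  indexed 1-based on the reference. The *seed region* for mutation
  classification is positions 2–9 (configurable); the *site heptamer*
  for target scanning is positions 2–8 (TargetScan convention). These
  are deliberately two separate constants. Region labels always come
  from the sequences; where a published table's labels contradict its
  own printed sequences, the sequences win.
* **CNV.** Families are precursor names with one trailing `-<digits>`
  copy suffix stripped (letter suffixes are distinct families; a bare
  family number like `mir-219` is never stripped). A CNV record is
  emitted when a family present in both genomes has differing locus
  counts; a family absent from the target is "not found", not CNV.
* **Annotation assembly.** Loci overlapping an exon by ≥ 1 bp (either
  strand) are dropped; duplicates (same chrom+strand, reciprocal overlap
  ≥ 0.9) collapse to the lowest MFEI. Accounting partitions the
  reference set: conserved + not_found = total, with CNV / polymorphic /
  seed-mutated as non-exclusive flags.
* **Clusters.** Single-linkage chaining per chromosome+strand at
  intergenic (end-to-start) gap ≤ d, d defaulting to 1 kb. A multi-member
  cluster is polycistronic iff a promoter-motif PWM scores ≥ 0.80
  (normalized so the best possible match is 1.0) in the 500-nt
  strand-aware upstream window of its 5′-most member *and* no qualifying
  hit sits in any intergenic gap. The PWM is pluggable; the default is
  built from the generator's 15-nt consensus with match probability
  0.85. The neural promoter model this gate stands in for is not
  reproduced — the single-upstream-promoter *logic* is what the
  polycistron call needs.
* **Targets.** Canonical site classes (8mer > 7mer-m8 > 7mer-A1 > 6mer),
  highest class per locus, UTRs scanned sense-strand only. A UTR is a
  target when it carries ≥ 1 site of class 7mer or better; 6mers alone
  are too noisy to call. Allele diffs report common/lost/gained UTR
  sets, which depend on the seed alone by construction.
* **Phylogenies.** Center-star multiple alignment (center = minimal
  summed pairwise edit distance; merged once-a-gap-always-a-gap),
  p-distance (Jukes–Cantor behind a flag), Saitou–Nei NJ with a
  deterministic lowest-index tie-break and negative branch estimates
  clamped to 0, and column-resampling bootstrap supports (default 1000
  replicates; a CLI parameter).

## The synthetic test bed

The generator emulates the real inputs of the comparison at desk scale:
~1 Mb across 4 chromosomes of i.i.d. background at 42% GC (bovine-like;
low enough that spurious hairpins essentially never pass the MFEI gate),
hosting by default 20 designed hairpin families (stems 26–40 bp at 75%
GC, loops 8–14 nt, matures 20–23 nt, precursors 52–148 nt by
construction), 3 seed mutations (positions 2–9) and 3 mature mutations
(positions ≥ 10), 2 CNV families (+2 and −1 copies), 2 three-member
clusters — one with the promoter motif planted upstream only, one
promoterless decoy — 5 exons with 2 embedded decoy precursor copies, and
30 600-nt UTRs carrying 3 reference-allele and 2 variant-allele 8mer
sites per seed-mutated miRNA. UTR background is scrubbed of chance
seed-cores for the tracked alleles, so the planted sites are the
complete site inventory and target-diff checks can be exact. Everything
is a pure function of the seed; planted segments are disjoint with
≥ 200-nt spacing.

What the bed does **not** emulate: repeat content and segmental
duplications, chromosome-scale genomes, realistic UTR composition and
conservation, transcription. Passing the recovery criteria therefore
demonstrates the pipeline's logic (mapping, gating, trimming,
accounting, diffing) under controlled truth — not its error profile on
real assemblies, where alignment ambiguity and repeat-borne hairpins
dominate.

## Numerical and degenerate-input choices

* DP interior loops capped at 30 unpaired nt total (standard speed cap;
  irrelevant at oracle sizes). The DP core is numba-compiled; the
  traceback is Python and is verified to re-score to the DP optimum
  exactly.
* Foldable window lengths 12–200 nt; `N` anywhere in a window discards
  it before folding. Tie-breaks in traceback prefer hairpin closure,
  then near-stack interior decompositions, left-most-first; any
  deterministic rule is acceptable and this one is documented.
* MFEI of a GC-free window is undefined (NaN) and can never pass the
  threshold; MFE 0 gives MFEI 0, which also fails.
* Equal-score overlapping alignments resolve left-most, then `+` strand.
  Ortholog stability comparisons tie at |ΔMFEI| < 0.005.
* Problem sizes in the test suite (1 Mb bed, 18-mer oracle batches,
  2–5 kb de novo genomes, 4–8-taxon trees) were chosen so the full suite
  and the acceptance script each complete in a few minutes on one CPU;
  the same code runs unchanged at larger sizes.

## Known limitations

* The energy model is package-frozen, not Turner 2004: absolute MFE
  values are not comparable with MFold/ViennaRNA output, only the
  gate behaviour is (by design).
* Mature-anchor placement uses local alignment and tolerates ≤ 2-nt
  length drift; highly diverged matures (< 80% alignable) drop the hit.
* The de novo scan reports a hairpin locus without resolving its
  transcribed strand (both strands fold); strand resolution needs
  expression data, which is out of scope.
* The published mature-pair table used in the acceptance layer carries
  region labels that contradict its printed sequences for several rows;
  this package classifies from sequences, so its seed-pair count for
  that table (10 with the 2–9 window) differs from the published tally
  of 8. The discrepancy is asserted, not hidden, in the acceptance
  suite.
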