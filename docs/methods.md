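# Methods

## Candidate site discovery

A morpholino binds the RNA whose sense sequence contains the reverse
complement of the probe. Instead of a heuristic homology search, the scan
is exhaustive: every length-25 window of every molecule is compared
ungapped against the reverse complement of the probe
(`antisense_compatible`) and against the probe itself
(`sense_incompatible` — detectable homology, but a duplex geometry that
cannot form on that RNA). Three molecule classes are scanned:

* **mature** — exons concatenated in transcript orientation,
* **pre_mRNA** — the full gene span in transcript orientation (splice
  morpholinos act on unspliced message, so introns must be visible),
* **genomic** — the bare contigs, so that hits outside any annotated
  gene are still seen (rule 1 of the screen exists precisely for them).

A window is reported when it has at most `max_mismatches` (default 5)
mismatches and a longest perfect complementary run of at least
`min_perfect_run` (default 12) nt. Overlapping windows of one orientation
are merged keeping the fewest-mismatch placement; records duplicated
across molecules (an exonic hit appears on mature, pre-mRNA and contig
alike) are de-duplicated with precedence mature > pre_mRNA > genomic,
comparing genomic footprints. The scan is ungapped by design: morpholino
hybridization does not tolerate gaps in practice, and 25-nt windows at
≤5 mismatches dominate any word-seeded homology search parameterization,
so screening is conservative.

Internally all coordinates are 0-based half-open; files and reports are
1-based inclusive (GFF3 convention). The conversion happens once, at the
io boundary, and is round-trip tested.

## The five-rule decision tree

Each site is evaluated totally (every rule recorded even after the first
failure, so reports carry the complete trail); the verdict is the first
failing rule:

1. **named gene** — the genomic footprint overlaps a gene feature
   carrying a Name (ID as fallback). Overlap, not containment.
2. **orientation** — only `antisense_compatible` sites can act.
3. **mechanism** — translation blocking if the footprint overlaps the
   5′UTR or the 25 nt window starting at the A of the annotated ATG;
   otherwise splice blocking if it overlaps the first/last 5 nt of any
   intron or the 2 nt of an exon adjacent to an intron. All windows are
   compared as genomic footprints, which makes mature, pre-mRNA and
   genomic records uniform and makes "spans a junction" a consequence
   rather than a special case (any junction-spanning site necessarily
   overlaps the edge windows on both sides). Exon edges at transcript
   termini carry no window — no splicing occurs there. Translation takes
   precedence when both mechanisms qualify.
4. **Tm** — retained iff duplex Tm ≥ 70 °C. The threshold itself is
   retained (exclusion is strictly below), because the screening rule
   excludes hits with Tm *below* the cut.

Overlap semantics (rule 3) is a deliberate choice: a partially
overlapping 25-mer still occludes a scanning ribosome or spliceosome
component, so containment would under-call. Multi-isoform genes are
classified per transcript and the most severe verdict is reported
(confirmed > excludable_step4 > excluded_step3 > …) — the conservative
option for deciding whether to order a probe. Sites on the probe's
intended target are flagged `on_target` and never counted as
off-targets.

Widening any window or lowering the Tm threshold can only move verdicts
toward "confirmed", never away — this monotonicity is tested over seeded
genomes.

## Duplex melting temperature

The vendor's algorithm used for the original 70 °C criterion is
proprietary and unpublished. The package substitutes a fully specified
two-state nearest-neighbor model:

    Tm(K) = 1000·ΔH / (ΔS + R·ln(C_T/4)),  then −273.15 °C
    + 16.6·log10([Na+])  (monovalent salt correction)
    − 5 °C per mismatch  (linear penalty)

ΔH/ΔS stack parameters are the published RNA/DNA-hybrid values
(Sugimoto et al. 1995, as also shipped by Biopython), with one
modification: each stack is averaged with its reverse-complement partner.
A morpholino backbone is neither DNA nor RNA, so neither strand
assignment of the hybrid table is "correct"; symmetrizing makes the
model independent of which duplex strand names the fragment and
preserves the expected monotonicities (appending a G:C pair never lowers
Tm — verified exhaustively over all octamers in the test suite).
Defaults: [Na⁺] = 0.1 M, C_T = 0.25 µM, penalty 5 °C/mismatch; all
configurable through `TmParameters`. Fragments shorter than 8 nt are
rejected (the NN sum is meaningless there).

Absolute Tm values are model-dependent; what the pipeline preserves is
the *role* of the 70 °C retention threshold. Under these parameters the
threshold corresponds to GC-rich 25-mers (≈ 55 %+ GC), which is where
the synthetic generator samples probes for classes whose definition
requires a retained Tm.

## Synthetic world

`SimConfig` defaults describe a deliberately small, fully structured
genome: 10 genes on alternating strands, 2–3 exons of 150–300 nt,
introns of 120–240 nt with canonical GT..AG dinucleotides, 5′UTRs of
40–80 nt, CDS opening with ATG, 200–400 nt intergenic spacers
(≈ 25 kb total). One transcript per gene; multi-isoform behaviour is
exercised by a hand-written two-isoform fixture in the tests.

Six truth classes are planted (default 5 sites each), one probe per
site, none in the reserved intended-target gene:

| class | construction | expected verdict |
|---|---|---|
| intergenic | revcomp(probe) in a spacer, ≥12 nt from genes | excluded_step1 |
| wrong_orientation | probe itself deep in an intron | excluded_step2 |
| translation_blocking | revcomp(probe) at CDS+5 on the mature transcript | confirmed |
| splice_blocking | revcomp(probe) at intron 5′ edge +2 nt | confirmed |
| positional_null | revcomp(probe) deep in an intron (≥8 nt from edges), Tm ≥ 70 | excluded_step3 |
| low_tm | mutated revcomp(probe) at intron 3′ edge, mutations until Tm < 70 | excludable_step4 |

Placements never touch ATG/GT/AG landmarks; low_tm mutations sit in the
first 12 positions so a 13-nt perfect run keeps the site detectable.
Probes are rejection-sampled (GC drawn from `gc_range`) so each class's
Tm constraint holds by construction. After surgery the genome is
re-scanned with the production scanner and the dataset is rejected
unless every probe recovers exactly its planted site with the expected
label; on rejection probes are redrawn from a fresh seeded stream. This
guard is what makes the ground truth *exact* rather than probabilistic —
surgery or an unlucky probe draw can in principle create a stray
qualifying site (at this scale roughly one dataset in twenty needs a
second draw).

Readout tables emulate the knockdown experiment's structure, not real
biology: 30 larvae per group; ordinal P1–P4 + dead draws per larva; MFI
from a normal truncated at 0 (control 100 ± 10 AU, severe knockdowns
45 ± 12, mild 85 ± 12 — figure-scale values chosen once, since the
source reports MFI graphically); qPCR Ct pairs with a housekeeper at
Ct ≈ 16, a baseline ΔCt of 6 cycles, and 0.15-cycle Gaussian noise per
measurement (typical replicate scatter). The configured knockdown truths
are the study's reported efficiencies: 30, 33, 32 and 81 %. A group's
own target gene shifts ΔCt by −log₂(1 − knockdown); other panel genes
stay at baseline. What a green recovery test establishes is therefore
that the ΔΔCt estimator is unbiased at this noise level and replicate
count — not that any real morpholino achieves those efficiencies. Dead
larvae receive a phenotype row but no MFI row, matching the separation
of death counts from grading and intensity statistics.

## Alignment

Quadratic-space Gotoh with three state matrices; a gap run of length L
costs open + (L−1)·extend, end gaps are penalized like any others, and
traceback ties break deterministically diagonal > up > left. Scoring
defaults mirror the EMBOSS stretcher conventions the ortholog comparison
used: BLOSUM62 with 12/2 (protein) and EDNAFULL (+5/−4, ambiguity codes
scored via the matrix, never rejected) with 16/4 (nucleotide). Identity
counts equal residues, similarity counts columns with positive
substitution score, gaps counts gap columns; all as percentages of the
alignment length. The implementation is cross-checked two ways:
exhaustive enumeration of every alignment for short pairs, and
Biopython's `PairwiseAligner` (same convention) at realistic lengths.
Exact reproduction of published ortholog percentages additionally
requires the exact accession versions of the sequences, which are inputs
to `similarity_table`, not bundled. A linear-space variant is not
provided; at these lengths (≤ a few kb) the quadratic DP is sufficient.

## Statistics

ANOVA is the classical SS decomposition (asserted exact to 1e-9
relative); for two groups F = t² and the p-values coincide with the
pooled-variance t-test to 1e-9, which the tests exploit as an algebraic
oracle. Tukey's test uses the Tukey–Kramer statistic
q = |m_i − m_j| / sqrt(MSW/2 · (1/n_i + 1/n_j)) with the adjusted p from
scipy's studentized-range distribution; the test suite validates it
against an independent double-quadrature of the distribution's defining
integral (Gauss–Legendre, ~1e-12 accurate) to 1e-6. Significance tiers
follow the standard star convention (\* ≤ 0.05 down to \*\*\*\* ≤ 0.0001).

ΔΔCt assumes equal amplification efficiencies of target and housekeeper
(the standard interpretation when only fold change vs a control group is
stated). Efficiency = (1 − 2^(−ΔΔCt))·100 % is strictly decreasing in
fold change and invariant under any global Ct shift.

## Known limitations

* The Tm scale is a substitute model; only the 70 °C threshold's role,
  not absolute agreement with the vendor tool, is preserved.
* The scan is ungapped and window-based; bulged duplexes are invisible
  by design.
* Synthetic genomes have uniform base composition — no repeats, GC
  isochores or paralogy, so the planted-recovery results say nothing
  about screening specificity in repeat-rich genomes.
* The readout generator models group effects and replicate noise only;
  no batch effects, dropout or amplification-efficiency drift.
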