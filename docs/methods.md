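# Methods

## Panel model

A panel covers each region of interest (ROI) with a chain of amplicons
whose *insert* intervals (0-based half-open, primer binding sites
included) overlap their neighbours.  Invariants enforced and tested:

- the union of inserts covers every ROI base;
- every primer binding site that falls inside the ROI lies within the
  insert of an adjacent amplicon, so primer-masked alleles are always
  observable from the neighbour;
- within an amplicon the forward and reverse primers carry different
  universal tags, and at every junction the two inner primers share one —
  a 2-colouring that exists for chains of any length by strict
  alternation;
- insert sizes and overlap lengths stay within configured bounds
  (defaults 263–380 bp and 49–193 bp, preferred insert 331 bp).

Tiling is deterministic: the amplicon count is chosen nearest the
preferred-size/preferred-overlap regime (defaults 331/100 bp), then one
insert size is shared by the whole chain and overlaps are equalised to
within one base.  ROI intervals are padded by 60 bp so that terminal
primers (up to 30 nt, with up to 25 nt of placement slop) bind outside
the targeted bases; short intervals shrink the padding just enough to
fit a single amplicon.

Primer selection scans every (shift, length) candidate at an amplicon
end — lengths 18–30 nt, 5' ends movable 25 nt inward or 20 nt outward
(outward capped by the insert-size bound) — and keeps candidates with
nearest-neighbour Tm within 60 ± 3 °C, homopolymer runs ≤ 4, and no
masked SNP with minor allele frequency above 0.09% under the last ten
3'-end bases (strand-aware).  Ranking is |Tm − 60|, GC clamp, smallest
displacement, left-most start, length.  The melting model is the
SantaLucia unified nearest-neighbour set at 50 mM monovalent salt,
1.5 mM Mg²⁺ (Owczarzy correction) and 250 nM oligo; under these
conditions typical gene-specific primers designed for a 60 °C annealing
step — including the published 2-plex primers this package carries as
constants — fall inside the window.  The 0.09% MAF ceiling is kept as
configured even though it is unusually strict; it is a parameter, not a
derived quantity.

At each junction the first *k* bases of the inner forward primer's
gene-specific sequence (F2^, default k = 12, allowed 4–16) are inserted
between tag and gene part of the inner reverse primer; the mirrored
(R1^) orientation is available per junction.  The overlap product's
terminal stem is therefore `len(tag) + k` by construction.  On random
references the stem finder may report one or two extra bases when the
flanking sequence happens to extend the duplex; tests assert the
designed length as a lower bound on synthetic panels and exact equality
on the published oligos.

## Terminal-stem detection

`find_terminal_stem` returns the largest L for which the 5' prefix of
length L equals the reverse complement of the 3' suffix of length L —
perfect Watson–Crick pairing only, no G·U wobble, no bulges, because the
engineered stems are exact by design.  No free-energy model is used;
full secondary-structure prediction is out of scope.

## PCR kinetics

All kinetics are expected-copy (deterministic); no stochastic molecule
counting.  Three layers:

1. **Closed form.** Under constant annealing and 100% efficiency the
   four species of an overlapping pair grow as n·2ⁿ, n·2ⁿ, n²·2ⁿ
   (overlap) and 2ⁿ (spanning).
2. **Branching recurrence.** Per cycle, the spanning product doubles
   from itself, each target gains from itself and the spanning product,
   and the overlap gains from itself and all three longer species.  With
   unit efficiencies this gives A1 = n·2ⁿ⁻¹ and A3 = n(n+1)·2ⁿ⁻², which
   match the closed form's growth *orders* but not its constant factors;
   the overlap-to-target ratio is (n+1)/2, linear in n.  Tests therefore
   compare ratios and growth orders between the two layers, not absolute
   copies.
3. **Two-stage stem-gated model.** Stage 1 (default 5 cycles at 60 °C)
   runs the branching recurrence with gene-specific priming on genomic
   template.  Stage 2 (remaining cycles at 72 °C) grows each species
   exponentially from its own pool, primed only at its fully formed
   tagged ends — gene-specific internal priming is treated as shut off
   by the raised annealing temperature.  Each end's per-cycle efficiency
   is `logistic((Tm_accessible − T_anneal + ΔT)/s) · exp(−λ·length)`,
   where the accessible portion of a binding site is the full oligo
   minus the product's terminal stem (measured by the stem finder), the
   limiting end governs (min of the two), Tm is the Wallace rule for
   robustness on very short accessible stubs, ΔT = 22 °C, s = 3 °C and
   λ = 0.002/bp.

The calibration (ΔT, s, λ) was chosen once so that the three qualitative
bench outcomes hold simultaneously: tag-only stems leave the overlap
product dominant regardless of stem length; primer-sequence stems
suppress it progressively with insert length, nearly completely from
~8–12 nt; and the long spanning product stays faint everywhere.  Because
a strongly inhibited overlap product is *frozen* while the spanning
product keeps slow exponential growth, the spanning species can end
above the overlap species in strong-insert runs — on a gel both are
simply invisible; tests assert the spanning product below both targets
in every run and below the overlap product wherever the overlap is
active.  No primer/dNTP depletion or plateau is modelled, so fractions
late in cycling are more extreme than a saturating reaction would show;
cycle counts are kept ≤ 40 so exponential growth stays within floating
point.

## Read simulation

Fragments are tagged amplicon molecules: full forward oligo + haplotype
interior + reverse complement of the reverse oligo.  Primer regions are
copied from the oligos (the polymerase copies the primer), so variants
under a primer site are invisible in that amplicon — exactly the effect
the overlap design compensates for.  Reads follow the 2 × 250 bp
convention; per-amplicon depth is log-normal (mean 1000×, σ_log = 0.5 by
default) to emulate amplification bias; substitution errors are seeded
Bernoulli draws whose constant Phred string encodes the error rate
(Q = −10·log₁₀ p); indel sequencing errors are not simulated
(indels enter via haplotypes).  Identical seeds give byte-identical
FASTQ.  What passing tests show is therefore calibration-correct
recovery under idealised error statistics — not robustness to real
instrument artefacts (context-dependent error, quality decay along the
read, chimeras, PCR duplicates).

## Analysis pipeline

Read pairs are assigned to amplicons by their primer+tag prefixes (exact
dictionary first, then a Hamming scan with ≤ 2 mismatches per mate;
ties stay unassigned).  Whole-genome mapping is deliberately replaced by
this panel-aware assignment plus banded local realignment against the
expected amplicon sequence: for a fixed panel the two are equivalent in
effect, and the pipeline becomes self-contained and testable.

Realignment is affine-gap Smith–Waterman (match +2, mismatch −4, gap
open −6, gap extend −1; a gap of length L costs 6 + L) banded ±48
diagonals around the anchored offset, which preserves optimality for
indels up to the band half-width — comfortably above the 40 bp maximum
deletion the pipeline is validated for.  An ungapped fast path (≤ 6
mismatches at the expected offset) handles the bulk of clean reads.

Pair merging follows standard consensus practice: positions seen by one
mate copy through; agreeing overlap bases get quality min(Q1+Q2, 60);
conflicting bases keep the higher-quality base with quality
max(|Q1−Q2|, 2); mates whose indel structure disagrees in the overlap
are dropped and counted.  The caps, floors and drop rule are package
choices — upstream descriptions of such pipelines leave them open.

Merged reads are soft-clipped to the non-primer segment (everything
downstream of the forward oligo's 3' end and upstream of the reverse
oligo's 3' end), then accumulated into per-segment pileups of
quality-weight sums and read counts, with deletion runs and insertions
aggregated as left-aligned indel alleles.  The quality weight of a base
is its correctness probability 1 − 10^(−Q/10).

Noise is estimated per segment as the mean and SD of quality-weighted
frequencies (qwf) over every (position, non-reference allele)
observation below a 5% ceiling; observations at or above the ceiling are
candidate variants and are excluded so true hets do not inflate the
background.  Pooling is per (position, allele), one observation each.
Candidates must exceed mean + 6·SD (a zero-SD segment falls back to
max(mean, 0.005)); PASS additionally requires ≥ 20 supporting reads
*and* ≥ 20% allele frequency — the stricter reading of the combined
filter, configurable.  The same variant seen from two overlapping
amplicons is reported once (PASS preferred, then depth).

Coverage is computed from merged (pair-collapsed) reads over the ROI;
uniformity is the fraction of ROI bases at ≥ 0.2× the mean depth, and
the relative-coverage table reports the eight thresholds 0.1×–1.0×.
Per-amplicon coverage is measured on the amplicon's non-overlapping
region.  Throughput projection converts kit reads per library into mean
amplicon coverage via the empirical 91,500 raw pairs ↔ 500× scaling
(treated as a given constant; it implies an on-amplicon pair efficiency
of roughly one half that is not derived here), floored to the nearest
100×, with minimum coverage defined as 0.2× of the mean — the flooring
rule matches the published kit table (1707→1700, 2846→2800).

## Numerical and test-scale choices

- Confidence intervals are exact Clopper–Pearson via the beta quantile;
  the all-success lower bound is (α/2)^(1/n).
- Variant normalisation is vt-style: shift left through repeats,
  re-anchor on the previous reference base; truth and calls normalise
  through the same routine so matching is exact.
- The end-to-end suite designs a 91-amplicon panel over a synthetic
  ~21 kb interval, injects SNVs plus 1–40 bp indels at 50%/100% allele
  fraction, and simulates ~1000× depth at 0.1% error — the assay's
  nominal operating point — asserting full sensitivity, zero false
  positives, ≥ 98% uniformity and allele fractions within 3 binomial σ.
- Aligner equivalence is checked on 200 random fixtures (indels ≤ 40 bp)
  against an independent brute-force dynamic program.

## Known limitations

- The kinetics model is qualitative by construction: no thermodynamic
  (ΔG) strand-displacement model, no competition for shared primers or
  polymerase between junctions at panel level, no plateau.
- The stem detector ignores mismatched/bulged stems; engineered stems
  are exact, but naturally occurring near-complementary ends would be
  under-reported.
- The caller targets germline allele fractions (≥ 20%); it is not a
  somatic low-VAF caller.
- No annotation (HGVS/VEP) and no mapping to a real genome build; panel
  coordinates are the coordinate system.
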