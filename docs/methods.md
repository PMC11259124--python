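# Methods

## Scope and model

`ptvburden` implements a gene-burden test for premature terminating
variants (PTVs) in a single gene: starting from called small variants
with per-sample genotype evidence, it classifies molecular consequence
on one transcript, filters genotypes and variants, collapses to
per-individual carrier status, and contrasts carrier frequency between a
case cohort and one or more presumed-healthy control panels with a 2×2
odds ratio. The pipeline deliberately begins *after* variant calling:
alignment, SNV/indel calling, CNV calling from coverage, and learned
splice-effect prediction are out of scope.

## Consequence classification

A variant is mapped onto the transcript (VCF-style 1-based coordinates
with anchor bases; multi-allelic sites decomposed to biallelic records
first) and classified by this precedence:

1. **Canonical splice** — the edit touches the ±1/±2 intronic
   dinucleotides (GT donor / AG acceptor) of an intron inside the
   genomic CDS span. Disrupting a purely untranslated intron is not
   counted: it cannot truncate the protein. Variants spanning an
   exon/intron junction are splice calls if they alter any canonical
   base, otherwise they are judged by their CDS-overlapping length —
   a conservative PTV rule.
2. **Frameshift** — the net change in CDS length is not a multiple of 3.
3. Otherwise the edited CDS is re-translated (standard nuclear code,
   reading through the 3' UTR when hunting for a shifted stop) and
   classified as stop gain, stop loss, start loss, synonymous, missense,
   or in-frame indel by comparing the new peptide to the reference,
   accounting for the expected length change.

`is_ptv` is true exactly for stop gain, frameshift, and canonical
splice. Stop loss and in-frame changes are never PTVs. Selenoproteins
and non-standard codes are not supported.

### HGVS naming

Coding names are normalized the HGVS way: the minimal edit (shared
suffix trimmed before the shared prefix, preserving the VCF anchor
convention) is shifted 3'-most on the *transcript* strand, and an
insertion identical to the immediately preceding bases is written as a
duplication (`c.3580dup`, never `ins`). Intronic positions are written
relative to the nearest exon boundary (`c.3965+2`, `c.4724-1`); ties at
an intron midpoint anchor to the upstream exon. Protein names: stop
gains are `p.<Ref><pos>Ter`; frameshifts are
`p.<Ref><pos><New>fsTer<k>` where *k* counts codons from the first
changed residue (inclusive, so a stop at that residue is `fsTer1`) to
the new stop; a frameshift with no downstream stop before the transcript
end gets `fsTer?` plus a warning; canonical splice variants are `p.?`.
The naming engine is verified against an internal re-translation oracle
and a c.-name round-trip parser on synthetic transcripts; it does not
attempt to reproduce names that require a specific real reference
sequence, which is not packaged.

## Filters and collapsing

* **Genotype QC**: alt allele depth ≥ 20 and, for heterozygotes only,
  variant allele fraction ≥ 0.25. Both thresholds inclusive; zero total
  depth fails with reason "no coverage".
* **Rarity**: population MAF strictly < 0.001. A variant absent from
  the reference panel counts as MAF 0 and passes — novel variants must
  survive this filter.
* **CNV exon span**: an already-called CNV is flagged when it overlaps
  ≥ 3 *consecutive* exons; overlapping exons 1 and 3 but not 2 does not
  flag.
* **P/LP rule**: a deliberately minimal ACMG-style surrogate
  (PVS1-type truncation evidence plus novelty): a rare PTV with a prior
  report or ClinVar entry is pathogenic, a novel rare PTV is likely
  pathogenic, everything else is not reportable. A full ACMG engine is
  out of scope and this rule is not a substitute for clinical curation.
* **Collapsing**: a sample is a carrier iff it holds ≥ 1 qualifying
  genotype; multiples count once. Homozygous qualifying genotypes are
  counted as carriers (the contrast is carrier vs non-carrier) with a
  warning, since the analysis concerns monoallelic carriers.
  Relatedness inference is out of scope; manifests may carry an
  `exclude_related` flag that drops individuals before analysis.
  Because the rarity filter acts on variants and QC acts on genotypes,
  filter order cannot change the carrier set (tested).

## Burden statistics

The 2×2 table always derives non-carrier cells as N − carriers; they
are never inputs. The odds ratio is the cross-product (a·d)/(b·c); the
interval is Woolf's log-normal interval without continuity correction.
`z` defaults to the conventional two-decimal quantile (1.96 at 95%) —
this is what published epidemiological tables round with, and it is the
choice that reproduces all four packaged comparisons' printed bounds at
two decimals; the full-precision quantile (1.959964…) is available via
`exact_z=True` and differs only in the second decimal of wide
intervals. A zero cell makes the OR infinite/undefined and the CI an
error unless the Haldane–Anscombe +0.5 correction is explicitly enabled
(off by default; the headline values need no correction). Computation
is at full precision; rounding happens only in report serialization.
No multiple-testing adjustment is applied — the analysis is a
single-gene test against a small number of panels, reported
comparison-by-comparison.

Control panels are pooled by summing sizes and carrier counts under an
explicit no-overlap assumption. Subgroup re-analysis filters both
manifests by an arbitrary predicate (e.g. `age >= 17`) and recomputes
the table; the package does not assert any particular published
age-restricted summary value, because the cross-product estimator on the
corresponding published cells gives a different number (≈26.26 vs a
reported 25.07) and the estimator behind that summary is unstated. The
procedure itself is verified against a brute-force recount oracle.

Descriptive statistics use the median (mean of central two for even n),
arithmetic mean, and sample SD (n−1). Diagnostic yield counts an
individual once in the diagnosed numerator regardless of how many genes
were reported, while per-gene shares count once per gene over the
diagnosed denominator, so shares may exceed 100% in total.

## Packaged fixtures

Four tables and one count file transcribe the source study's published
data verbatim: the 36-patient carrier roster, the 14-variant catalogue
(7 stop gain / 5 frameshift / 2 canonical splice), the 24-patient
clinical-feature table, the per-variant control-panel counts, and the
four cohort-size/carrier-count comparisons. The transcription preserves
a known internal inconsistency (one roster variant absent from the
catalogue; a recurrence count of 6 vs 5 for another), which the loader
surfaces as warnings rather than silently resolving. The wall-thickness
column's computed mean (19.9 mm) also differs from its published rounded
summary (19 mm) although the SD matches; the package reports what it
computes. The per-sample diagnostic manifest is *synthetic* — only
aggregate tallies are published — constructed to match those aggregates
exactly (482 diagnosed of 2,366; 18 multi-gene patients; MYBPC3 196,
MYH7 120, TNNI3 59).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes
and nothing more: no linkage disequilibrium, relatedness, population
stratification, or read-level error. Its defaults are the study
conditions — 2,366 cases at a carrier frequency of 1.52%, 22,448
controls at 0.071%, heterozygous carriers with exactly one PTV drawn
uniformly from the pool (a multi-variant option exercises collapsing),
ages truncated-normal with mean 53, SD 17, minimum 17 years, 66% male.
Depths for passing heterozygotes are DP ~ uniform(45–80) with
AD ~ Binomial(DP, 0.5) resampled into the passing region; QC corruption
replaces them with a failing draw (AD < 20, or VAF ≤ 0.20 at adequate
depth) at a configurable rate. A configurable fraction of pool variants
is annotated at MAF 0.5% to exercise the rarity filter, and non-PTV
decoy variants (missense/synonymous/in-frame) are sprinkled per sample.
Synthetic transcripts have GT..AG introns, an ATG start, no internal
in-frame stop, and a terminal stop codon, so classification and splice
reference bases are exact. Everything is integer-seeded and
deterministic, with no iteration-order dependence.

Passing tests on these cohorts demonstrate that the pipeline's logic is
correct under its own assumptions (exact truth recovery with clean
data; null behaviour at equal frequencies; ~95% Woolf coverage; mean
estimated OR within 10% of the generating OR at full cohort scale over
200 replicates). They do not validate performance on real sequencing
artefacts, strand biases, panel ascertainment differences, or related
individuals.

## Problem sizes and numerical choices

The test suite and acceptance script size their simulations to be
decisive yet quick as a deliberate design choice: ≥1,000 random edits
across four synthetic transcripts (both strands) for the
classifier-vs-oracle check, 2,500 simulated 2×2 tables (n = 5,000 per
arm, true OR 3) for interval coverage, and 200 cohort replicates at the
full study sample sizes for parameter recovery. Degenerate inputs are
defined, not crashed: empty panels, zero denominators, and emptied
subgroups raise `ValueError`; variants outside the transcript span get
an "outside" descriptor; a single observation reports an undefined SD
as missing.
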