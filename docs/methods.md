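# Methods

## The problem

Mutation-accumulation (MA) experiments propagate many independent lines
from a single founder (here: selfed *Arabidopsis*-style diploids) and
sequence them after one or more generations.  Two signals have to be
separated in the resulting multi-sample variant calls: founder
("germline") variants, present in the seed stock and therefore shared by
several lines, and genuine heritable de novo mutations, which are private
to one line.  `mamutspec` implements the post-calling half of such a
study: locus-level quality filtering, singleton selection, zygosity-
weighted mutation-rate estimation, substitution-spectrum and
flanking-context analysis, InDel classification, region/deleteriousness
annotation, and the group statistics used to compare treatment arms.

## Filtering and singleton selection

A locus is dropped when its missing-call ("./.") fraction over all lines
exceeds 20%, or its heterozygous-call fraction exceeds 20%.  Both
comparisons are strict, so a locus at exactly the threshold survives.
The two filters address different failure modes — coverage dropout versus
systematic mis-genotyping (paralogy, mapping artifacts) — so the het
fraction is computed over non-missing calls by default; a config flag
switches the denominator to all lines, since call sets differ in whether
no-calls are materialized.

A singleton is a locus at which exactly one line carries a non-reference,
non-missing genotype.  Uniqueness is positional: two different alt
alleles at the same position in two lines disqualify both, because a
position hit in two lines is overwhelmingly a shared artifact rather
than two independent mutations.  Allele-aware uniqueness is available
behind a flag.  The owning line's genotype sets the zygosity.

## Rate estimator

A heterozygous mutation in a selfed line reaches homozygosity in the next
generation with probability ½, so the effective heritable count is

    E = N_hom + ½ · N_het

and the per-site rate is

    μ̂ = E / (D · S · L · g)

with S the denominator target size (default: reference non-N length),
L the number of lines, g the generations of accumulation, and D a diploid
site factor (default 2: both homologs are mutational targets).  Published
MA studies rarely state their denominator explicitly; every report
therefore prints the (S, D, L, g) actually used, and all four are
overridable — nothing is hard-coded.

## Group statistics

Per-line counts (zero-count lines included) are compared across treatment
groups by one-way ANOVA with Tukey HSD post-hoc tests (statsmodels), and
summarized by a compact letter display: groups sharing a letter are not
significantly different at α = 0.05.  Letters are assigned by the
insert-and-absorb algorithm after ordering groups by descending mean,
which makes the display a deterministic function of the significance
matrix.  Per-line fraction comparisons (e.g. transition fraction) against
a control group use two-sided two-sample t-tests, Welch by default
because group sizes become unequal once treatment sub-arms are merged;
lines with zero SNVs have no defined fraction and are excluded and
reported.  All-constant inputs raise a degenerate-input error rather than
emitting an undefined F statistic, except the fully-identical case, which
reports the trivial outcome (F = 0, one letter).

## Substitution spectrum and context

SNVs are classified into the 12 directed reference-strand classes
(A>C … T>G) with no reverse-complement collapsing, because C>T and G>A
behave differently in plant MA data and are reported separately.
Transitions are A↔G and C↔T; the purine→purine and pyrimidine→pyrimidine
subtotals are exactly the two transition pairs.  Flanking context uses
the reference (+) strand for every site, including mutated-G subsets (no
strand flipping); consensus calls break ties lexicographically and flag
them.  Sites closer than k (default 5) to a contig end are excluded from
context matrices — rather than N-padded — so each position row remains a
proper probability distribution; the excluded count is reported.

## InDel classification

InDel size is the allele-length difference after VCF anchor-base
stripping; sizes ≤ 3 bp are "short".  Replication slippage concentrates
InDels at homopolymers and short tandem repeats, so each InDel is tested
for adjacency of its affected interval (deletion: the deleted bases;
insertion: the insertion point) to a repeat tract with **no gap**:

* homopolymer: a single-base run of length ≥ 4 abutting either boundary,
  or a homopolymeric inserted/deleted sequence that extends an abutting
  run of the same base to ≥ 4;
* polynucleotide repeat: a tandem of unit 2–3 bp with ≥ 3 exact copies
  abutting either boundary, or an InDel sequence that is a whole number
  of copies of the abutting unit and extends it to ≥ 3 copies.

The thresholds are explicit knobs (CLI-tunable, printed in every report
header) chosen to make "adjacent" non-trivial on random sequence: a run
of 4 at a fixed boundary occurs with probability ≈ 2·(¼)³ ≈ 3% per side
on uniform sequence.  When both classes match, homopolymer takes
precedence (a homopolymer is a unit-1 repeat; precedence prevents double
counting).

## Region and intolerance calls

Each variant gets exactly one region with precedence
CDS (→ coding exon) > UTR > exon > intron > intergenic; InDels are
classified by any overlap of their affected interval.  Annotation-engine
output rarely documents a precedence order, so ours is explicit, and
variants overlapping more than one gene are flagged.  A variant is
"intolerant" iff it is an SNV with a supplied SIFT score < 0.05 (strict)
or an InDel overlapping coding sequence.  SIFT scores are inputs read
from a TSV; the package never computes them.

## The synthetic cohort generator

`ma_simulator` produces cohorts with the statistical structure the
analysis assumes, so every stage is verifiable against planted truth
without any external data:

* i.i.d. reference at configurable GC (default 36%), salted with
  homopolymer runs (5–8 bp) and di-/trinucleotide tandems (3–5 copies) at
  a configurable density (default 1 per 5 kb) — these tracts give the
  adjacency classifier its positive cases and are recorded for placement;
* founder variants shared by ≥ 2 lines (2 + geometric tail), which the
  singleton filter must remove completely;
* line-private de novo SNVs drawn class-first from a 12-class weight
  vector (default: transition fraction 0.60 split evenly within
  transition/transversion groups), with the position resampled until the
  reference base matches — realized class frequencies therefore converge
  to the weights regardless of base composition;
* InDels sized from a 1–28 bp distribution with 77.06% of mass on
  1–3 bp, insertion vs deletion at a configurable odds ratio (default
  0.76), and a configurable fraction (default 0.5) placed flush against
  a recorded tract boundary (either side; one slot per side).  Non-
  adjacent placements that would be accidentally adjacent are resampled,
  so the realized adjacency fraction tracks the configured one;
* optionally, a 3-mer motif written into the reference at −3…−1 of
  mutated C sites (reverse-complemented for G sites) with a given
  probability, for context-recovery tests.

**Rate semantics.** The configured `snv_rate`/`indel_rate` are the
*effective* (zygosity-weighted) heritable rates — the quantity μ̂
estimates, and the scale on which MA studies report.  The number of
planted records per line is Poisson with mean rate·D·S·g / w, where
w = hom_fraction + (1 − hom_fraction)/2, so the expected effective count
equals rate·D·S·g: the estimator is unbiased for the configured rate
while the observed homozygous record fraction stays at `hom_fraction`
(default 0.17).  Had the record count itself been Poisson(rate·D·S·g),
the estimator would recover only w ≈ 0.585 of the configured rate and
rate-recovery and zygosity-recovery could not hold simultaneously.
Heterozygous variants are emitted as het in the sampled generation; no
further Mendelian segregation is simulated — the ½-weighting is what the
recovery tests exercise, not Mendelian machinery.

Default cohort shape is 4 treatment groups × 40 lines on a 1 Mb,
5-contig genome, with effective rates (1.23 × 10⁻⁶ SNV, 1.35 × 10⁻⁷
InDel per site per line per generation at D = 2) chosen so per-line
singleton yields (≈ 4.2 SNVs, ≈ 0.46 InDels) match a realistic
Arabidopsis MA cohort at this genome size.  Everything derives from a
single integer seed; emission (FASTA, joint multi-sample VCF, groups TSV,
truth TSV) is byte-identical across runs.

What the generator does **not** emulate: read-level noise, genotyping
error, mapping artifacts, coverage variation, linked selection, and
Mendelian segregation across generations.  Passing recovery tests
therefore demonstrate correctness of the analysis logic under the
assumed statistical structure, not robustness to upstream calling error.

## Numerical and determinism choices

Coordinates are 1-based VCF/GFF conventions throughout; alleles are
normalized by shared-suffix then shared-prefix trimming, keeping the VCF
anchor base.  Multi-allelic records are split into one locus per alt
allele.  Report tables are written with fixed float formats and stable
sort keys so identical inputs give byte-identical bundles; the run
manifest records parameters, versions and SHA-256 input digests.
Consensus ties break lexicographically with an explicit flag.  Empty
inputs yield empty-but-valid outputs (header-only tables, blank
percentages) rather than NaNs.

## Problem sizes used in the verification suite

The suite verifies rate/zygosity recovery on 20 seeds of 40 lines × 1 Mb
(effective rate 5 × 10⁻⁶, D = 1 on both sides), spectrum recovery at
≈ 1,000 SNVs, InDel structure at ≈ 400 InDels, filter-oracle equivalence
on 100 random cohorts up to 400 loci × 50 lines, adjacency-oracle
equivalence on 10⁴ random fixtures, and statistics-oracle agreement on
100 random datasets.  These sizes give the binomial/Poisson bands stated
in each test comfortable power while keeping the whole suite under a
minute.

## Known limitations

* Uniqueness-based de novo detection cannot see recurrent mutation at a
  shared site (the analysis assumes such events are negligible).
* The adjacency thresholds are conventions; published supplementary
  definitions of "adjacent to a homopolymer/repeat" vary and are often
  unavailable.
* The rate denominator (S, D) is a modelling choice the user must own;
  results scale inversely with it, which is why it is always printed.
* Region calls use a single precedence over all transcripts; isoform-
  specific effect prediction is out of scope.
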