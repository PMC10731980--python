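# mamutspec

Post-variant-calling analysis for **mutation-accumulation (MA) cohorts**:
separate heritable de novo mutations from founder variants in a
multi-line cohort, estimate per-site mutation rates with zygosity
weighting, and characterize the mutation spectrum — substitution classes,
flanking sequence context, InDel sizes and repeat adjacency, genomic
region and deleteriousness — with the one-way ANOVA / Tukey HSD group
statistics such studies report.  A built-in synthetic cohort generator
makes every stage verifiable against planted ground truth.

It is written for researchers who already have variant calls (VCF) from
an MA-style experiment — many independently propagated lines from one
founder, e.g. single-seed-descent selfed plants — and need the downstream
analysis to be reproducible and testable.

## The model in brief

Variants shared by ≥ 2 lines are founder (germline) polymorphisms;
variants private to one line ("singletons", after locus-quality filters
on missing-call and heterozygosity fractions) are the proxy for heritable
de novo mutations.  Because a selfed heterozygote transmits its mutant
allele to homozygosity with probability ½, the effective mutation count
and rate are

    E = N_hom + ½·N_het          μ̂ = E / (D · S · L · g)

with S the target size in bp (default: reference non-N length), L lines,
g generations and D a diploid-site factor (default 2).  Every report
prints the denominator it used.  SNVs keep the 12 directed
reference-strand substitution classes (transitions = A↔G, C↔T); context
analysis builds position (−5…+5) × base frequency matrices around
mutated sites; InDels are classified by direction, size (short ≤ 3 bp)
and adjacency to homopolymer runs or 2–3 bp tandem repeats.  See
`docs/methods.md` for the full model, parameter defaults and limitations.

## Worked example

Simulate a default cohort (4 treatment groups × 40 diploid lines on a
1 Mb reference, founder variants plus line-private de novo mutations),
then filter it and estimate rates:

```
$ mamutspec simulate --out demo --seed 42
5051 planted variant records (2335 loci x 160 lines)

$ mamutspec filter --vcf demo/cohort.vcf --groups demo/groups.tsv \
      --out demo/singletons.tsv
2335 loci -> 2335 after filters -> 735 singletons

$ mamutspec rates --singletons demo/singletons.tsv \
      --reference demo/reference.fasta --groups demo/groups.tsv
group  n_lines  n_hom  n_het  effective_count   sites  generations  diploid_factor     rate
  all      160    116    619            425.5 1000000            1             2.0 0.000001
   CK       40     29    151            104.5 1000000            1             2.0 0.000001
  M33       40     38    162            119.0 1000000            1             2.0 0.000001
M30.5       40     26    158            105.0 1000000            1             2.0 0.000001
M24.5       40     23    148             97.0 1000000            1             2.0 0.000001
```

Reading the output: of 2,335 called loci, the 1,600 founder variants are
all removed by singleton selection (each is shared by ≥ 2 lines), leaving
735 line-private records.  In CK, 29 homozygous + 151 heterozygous
singletons give an effective count E = 29 + 151/2 = 104.5 and a rate of
104.5 / (2 × 10⁶ × 40 × 1) ≈ 1.3 × 10⁻⁶ per site per line per
generation — the effective rate the generator planted.  `mamutspec
spectrum`, `mamutspec indels` and `mamutspec run` (full report bundle
with a JSON manifest) continue from the same files; `mamutspec run
--gff ... --sift ...` adds region and intolerance calls.

The same operations are available as a library:

```python
import mamutspec as m

sim = m.simulate_cohort(m.SimulationConfig(seed=42))
singles = m.select_singletons(m.apply_locus_filters(sim.cohort))
spec = m.spectrum_table(singles)
print(spec.subtotals())          # transitions / transversions per group
```

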