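# allelebank

Selecting the fewest gamete-bank samples that carry a target share of a
population's allelic diversity.

## The problem

Gene banks of cryopreserved sperm are used to safeguard the genetic
variation of endangered, low-diversity populations — small-lake fishes are
a typical case.  When the bank is drawn on for breeding, using every stored
sample is wasteful and using arbitrary samples risks founder effects: many
donors in a bottlenecked population are genetically near-identical.  If the
donors' microsatellite genotype profiles are known, a better question can
be asked: *which smallest set of samples jointly carries (say) 100% of all
alleles detected across the whole bank?*

Formally this is a minimum set cover.  Let the bank hold N samples typed at
a panel of loci (disomic loci contribute 2 allele calls per sample,
tetrasomic loci 4).  The universe is the set of all distinct
(locus, allele) pairs detected across the bank; its size is the allelic
diversity nA.  Each sample s contributes the set A(s) of pairs its genotype
carries.  For a coverage target t ∈ (0, 100], a selection S is feasible
when

&nbsp;&nbsp;&nbsp;&nbsp;|⋃<sub>s∈S</sub> A(s)| ≥ ⌈(t/100) · nA⌉,

and we seek a feasible S of minimum cardinality N′.  `allelebank` ships
both the classic greedy approximation (repeatedly add the sample
contributing the most not-yet-covered alleles) and a branch-and-bound
solver that proves minimality — at bank scale (tens to a few hundred
low-diversity samples) exact solutions are routinely affordable.

The summary indicators are N, nA, nA/N (alleles per sample), N′, and
N′/N (the share of the bank needed for a full transfer), with ratios
printed half-up to two decimals.

## Input format

UTF-8 delimited text (comma, semicolon or tab; autodetected), one header
line, one row per sample.  Column 1 is the sample ID; the remaining columns
are allele calls grouped contiguously by locus — two columns per disomic
locus, four per tetrasomic locus.  The header carries the locus name over
its block (repeated on every column, or once followed by blanks); ploidy is
inferred from the block width.  Allele names are numbers (fragment
lengths); `0` or an empty cell means a missing call.  `.xlsx` files with
the same logical layout are also read.

## Worked example

`toy.csv` — four samples, two disomic loci and one tetrasomic locus:

```text
Sample,L1,L1,L2,L2,L3,L3,L3,L3
S1,1,2,1,1,1,2,3,3
S2,2,3,1,2,1,1,2,2
S3,1,1,2,2,4,4,4,4
S4,3,3,1,2,1,2,3,4
```

```sh
$ allelebank analyze toy.csv --mode exact --output toy.report.csv
Samples in input file (N):      4
Alleles detected (nA):          9
Alleles per sample (nA/N):      2.25
Samples selected (N'):          2
Share selected (N'/N):          50.00%
Achieved coverage:              100.00%
Solver:                         exact (optimal)
Selected samples:               S1, S4
Report written to:              toy.report.csv
```

The bank holds 9 distinct (locus, allele) pairs (3 at L1, 2 at L2, 4 at
L3).  No single sample carries all nine — the richest, S4, carries seven —
but S1 and S4 together do, so the minimal transfer set has N′ = 2 samples,
half the bank.  The report file has five sections, each openable in a
spreadsheet: (1) the input genotypes, (2) the alleles detected per locus
and across all loci, (3) the selected samples with their genotypes,
(4) the alleles they transfer, and (5) the summary above.

Python API equivalent:

```python
from allelebank import read_genotype_table, select_exact, summarize

table = read_genotype_table("toy.csv")
result = select_exact(table)           # CoverageTarget(100) by default
print(result.selected_ids)             # ('S1', 'S4')
print(summarize(table, result))
```

Synthetic fixtures in the same dialect (low-diversity populations: few
alleles per locus, one common allele with a rare tail) come from the
`simulate` subcommand or `allelebank.simulate`:

```sh
allelebank simulate --out bank.csv --samples 48 --loci 13 --tetrasomic 1 --seed 5
allelebank analyze bank.csv
```

## Limitations

- Coverage is a single pooled allele budget across loci, not a per-locus
  quota; weighted cover (sample quality, straw counts) and kinship-aware
  selection are out of scope.
- Ploidy is restricted to 2 and 4; other marker systems work whenever
  alleles are named by numbers.
- The greedy solver is deterministic and fast at any scale but only the
  branch-and-bound solver labels its result `optimal`.
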