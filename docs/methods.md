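# Methods

## Model

A gamete bank is a table of N samples typed at a fixed panel of
microsatellite loci.  Each locus is disomic (2 allele calls per sample) or
tetrasomic (4 calls); allele names are numeric labels, in practice PCR
fragment lengths.  Alleles are identified by (locus, label) pairs, so the
same number at two loci is two distinct alleles.  The allelic diversity nA
of the bank is the number of distinct pairs detected across all samples
and loci; missing calls (code `0` or blank) never enter any allele set,
and repeated calls within one genotype (homozygosity, tetrasomic repeats)
count once.

Selecting donors for a transfer of genetic variation is a minimum set
cover: sample s contributes the set A(s) of pairs it carries, and for a
coverage target t (percent) a selection S is feasible when
|⋃ A(s)| ≥ r, with r = ⌈(t/100)·nA⌉.  The default target is 100%, i.e.
every detected allele.  Coverage is a single pooled budget over all loci —
there is no per-locus quota — because the diversity measure itself is the
across-loci allele count.

## Solvers

**Greedy** adds, at each step, the sample with the largest number of
not-yet-covered pairs, until r pairs are covered.  Ties break toward the
earliest input row, so a given input file always yields the same
selection.  Greedy carries the standard ln(nA)+1 approximation guarantee
and is never labelled optimal.

**Exact** is depth-first branch and bound over samples in input order,
include-branch first, with allele sets packed into integer bitmasks.
The greedy solution seeds the incumbent; the initial bound is set one
above the greedy size so that the search always *re-discovers* the best
solution, which makes the returned optimum the lexicographically-first by
input order among equal-size optima (a branch leading to the lex-first
optimum is never pruned while the incumbent exceeds the optimal size).
Pruning uses (a) the incumbent bound, (b) suffix-union reachability (the
samples not yet considered cannot cover what is still missing), and
(c) the lower bound ⌈missing / (largest remaining set size)⌉.  Samples
adding no new allele at their decision point are never included — any
optimum containing such a sample could be shrunk, a contradiction — and
consequently all-missing samples are never selected.  A node-expansion
budget (default 2 × 10⁶) caps the search; on exhaustion the best-known
selection is returned with `optimal=False` and a `BudgetExhaustedWarning`.
NP-hardness of set cover means adversarial instances exist, but
low-diversity banks are far from them: an exact solve at N = 48, nA ≈ 30
takes milliseconds.

**Auto** mode uses the exact solver up to 40 samples and greedy beyond;
either can be forced.

## Degenerate inputs and numerical conventions

- nA = 0 (no non-missing calls): the empty target is vacuously met, the
  empty selection is returned and the achieved coverage reported as
  100.00%.  This is the package's convention for an edge case on which
  reasonable definitions differ (0/0 coverage).
- An empty table (header only) is a valid `GenotypeTable`; the CLI refuses
  it with a "no samples" error because an analysis of nothing is almost
  certainly a mistake.
- All printed ratios (nA/N, N′/N, coverage) are rounded half-up to two
  decimals, computed from exact integer fractions — e.g. 21/48 = 0.4375
  prints 0.44 and 5/48 = 10.4167% prints 10.42.  Python's banker's
  rounding is deliberately not used.
- `required_allele_count` takes the ceiling, so any feasible selection
  reaches at least the target percentage before rounding.

## Input dialect decisions

The source layout is a spreadsheet convention known from figure captions,
not a byte-level file standard, so the parser fixes a logical dialect:
header grouping by run length accepting both the repeated-name and the
name-plus-blanks conventions; ploidy = block width, restricted to {2, 4};
missing codes `0` and blank (configurable); delimiters tab/semicolon/comma
autodetected.  Short rows are padded with missing calls (spreadsheet
exports drop trailing blanks); any other shape or content error raises an
exception naming the row and column.  Writing always uses the
repeated-name header and the `0` missing code, and write→read is the
identity on valid tables (property-tested).

## Synthetic data

`simulate_population` draws each call slot independently from a per-locus
allele-frequency vector, with an optional per-call missing probability.
`low_diversity_spec` builds the default study condition: 48 samples,
13 loci, one tetrasomic, at most 5 alleles per locus, per-locus allele
counts 1 + Binomial(4, 0.3) (mean ≈ 2.2 alleles/locus, matching banks
where ~20–30 alleles are seen across a 13-locus panel), and geometric
frequency decay (ratio 0.35) giving one common allele and a rare tail —
the signature of bottlenecked populations.  Exact frequency spectra of any
real population are not modelled; what the generator emulates is low
richness and strong genotype sharing.  It does not emulate linkage,
genotyping error, allelic dropout, or population structure, so passing
tests show correctness of the accounting and optimisation on such tables,
not robustness to those artefacts.

`plant_cover_instance` constructs tables with a *known* minimum cover for
oracle testing: k carrier samples each receive one private allele present
in no other sample (so every full cover must contain all carriers), the
carriers jointly hold every allele in the table (a repair step places each
shared allele into a carrier slot whose current label occurs elsewhere,
so no repair erases another allele's sole copy), and non-carriers draw
only from the carrier-held shared pool.  The minimum 100%-cover size is
therefore exactly k by construction.

All randomness flows through one seeded NumPy generator per call;
selection code consumes no randomness, so identical inputs give
byte-identical reports.

## Verification

The test suite checks the parser (round-trip identity, totality on fuzzed
cells), the inventory invariants (permutation invariance, monotonicity
under added samples, conservation against per-sample sets), and the
solvers against two independent oracles: exhaustive increasing-size
enumeration over plain frozensets (200 random mixed-ploidy tables,
N ≤ 15, ≤ 25 alleles, mixed targets) and planted instances (k = 1..6,
n up to 15, 20 seeds each).  `scripts/acceptance.py` reruns the pipeline
at study scale — four simulated 48-sample populations and their pooled
192-sample bank (exact solver per population, auto/greedy on the pooled
bank) — and reports nA, N′, N′/N, achieved coverage and the oracle
agreement rates.  Problem sizes were chosen to mirror the bank-scale
setting while keeping the whole suite in a few seconds.

## Known limitations

- No weighted or constrained cover (straw counts, motility, kinship).
- Ploidies other than 2 and 4 are rejected.
- The exact solver's worst case is exponential; the budget mechanism
  degrades gracefully to the greedy answer rather than running unbounded.
- XLSX support is a convenience layer over the same logical dialect, not
  byte-compatibility with any particular spreadsheet tool's output.
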