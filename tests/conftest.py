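"""Shared fixtures: the toy table, a brute-force cover oracle, random tables."""

from __future__ import annotations

import io
import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest

from allelebank import GenotypeTable, read_genotype_table, sample_allele_set
from allelebank.simulate import LocusSpec, SimSpec, simulate_population

TOY_CSV = """Sample,L1,L1,L2,L2,L3,L3,L3,L3
S1,1,2,1,1,1,2,3,3
S2,2,3,1,2,1,1,2,2
S3,1,1,2,2,4,4,4,4
S4,3,3,1,2,1,2,3,4
"""


@pytest.fixture
def toy_table() -> GenotypeTable:
    """4 samples, loci L1/L2 disomic and L3 tetrasomic, 9 distinct alleles."""
    return read_genotype_table(io.StringIO(TOY_CSV))


def brute_force_min_cover(table: GenotypeTable, percent: float = 100.0) -> int:
    """Independent oracle: smallest subset reaching the coverage target.

    Enumerates subsets by increasing size over plain frozensets of
    (locus, allele) pairs — no bitmasks, no pruning, nothing shared with
    the solvers under test.
    """
    sets = [sample_allele_set(p, table.loci).alleles for p in table.samples]
    universe = frozenset().union(*sets) if sets else frozenset()
    required = math.ceil(Fraction(str(percent)) / 100 * len(universe))
    for size in range(len(sets) + 1):
        for combo in combinations(range(len(sets)), size):
            pooled = frozenset().union(*(sets[i] for i in combo)) if combo else frozenset()
            if len(pooled) >= required:
                return size
    raise AssertionError("unreachable: all samples always cover the universe")


def random_table(seed: int, max_samples: int = 15, max_pairs: int = 25) -> GenotypeTable:
    """A small random mixed-ploidy table for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    n_samples = int(rng.integers(1, max_samples + 1))
    loci = []
    budget = max_pairs
    n_loci = int(rng.integers(1, 6))
    for i in range(n_loci):
        if budget <= 0:
            break
        ploidy = int(rng.choice([2, 2, 2, 4]))
        n_alleles = int(rng.integers(1, min(5, budget) + 1))
        budget -= n_alleles
        freqs = rng.dirichlet(np.ones(n_alleles) * 0.8)
        loci.append(
            LocusSpec(
                name=f"L{i + 1}",
                ploidy=ploidy,
                frequencies=tuple(float(f) for f in freqs / freqs.sum()),
            )
        )
    missing_rate = float(rng.choice([0.0, 0.0, 0.1, 0.3]))
    spec = SimSpec(
        n_samples=n_samples,
        loci=tuple(loci),
        missing_rate=missing_rate,
        seed=int(rng.integers(2**31)),
    )
    return simulate_population(spec)
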