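"""Allele inventory: distinct alleles per locus and across all loci.

Alleles are identified by (locus, label) pairs — the same numeric label at
two loci counts as two distinct alleles.  The across-loci total is the nA
indicator used throughout the summary statistics; missing calls never enter
any allele set, and duplicated calls within one individual (homozygosity,
tetrasomic repeats) contribute a single allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ._rounding import ratio2
from .genotype_io import GenotypeTable, LocusDef, SampleProfile

__all__ = [
    "AlleleInventory",
    "SampleAlleleSet",
    "allele_inventory",
    "sample_allele_set",
    "alleles_per_sample",
    "sort_alleles",
]

AllelePair = tuple[str, str]  # (locus name, allele label)


def sort_alleles(labels: Iterable[str]) -> list[str]:
    """Sort allele labels numerically (labels are fragment-length numbers)."""
    return sorted(labels, key=lambda label: (int(label), label))


@dataclass(frozen=True)
class AlleleInventory:
    """Distinct alleles per locus and the across-loci total (nA)."""

    per_locus: dict[str, frozenset[str]]
    locus_order: tuple[str, ...]

    @property
    def per_locus_counts(self) -> dict[str, int]:
        return {name: len(alleles) for name, alleles in self.per_locus.items()}

    @property
    def total_nA(self) -> int:
        return sum(len(alleles) for alleles in self.per_locus.values())

    def pairs(self) -> frozenset[AllelePair]:
        """All (locus, allele) pairs in the inventory."""
        return frozenset(
            (locus, allele)
            for locus, alleles in self.per_locus.items()
            for allele in alleles
        )


@dataclass(frozen=True)
class SampleAlleleSet:
    """The distinct (locus, allele) pairs one sample carries."""

    sample_id: str
    alleles: frozenset[AllelePair]

    def __len__(self) -> int:
        return len(self.alleles)


def allele_inventory(table: GenotypeTable) -> AlleleInventory:
    """Inventory of distinct non-missing alleles, per locus and overall.

    Independent of sample order; an empty table yields zero counts.
    """
    per_locus: dict[str, set[str]] = {locus.name: set() for locus in table.loci}
    for profile in table.samples:
        for locus_name, calls in profile.calls.items():
            per_locus[locus_name].update(c for c in calls if c is not None)
    return AlleleInventory(
        per_locus={name: frozenset(alleles) for name, alleles in per_locus.items()},
        locus_order=table.locus_names,
    )


def sample_allele_set(
    profile: SampleProfile, loci: Sequence[LocusDef]
) -> SampleAlleleSet:
    """The set of (locus, allele) pairs a profile carries; duplicates collapse."""
    pairs = frozenset(
        (locus.name, call)
        for locus in loci
        for call in profile.calls[locus.name]
        if call is not None
    )
    return SampleAlleleSet(sample_id=profile.sample_id, alleles=pairs)


def alleles_per_sample(nA: int, N: int) -> float:
    """The nA/N indicator: alleles per sample, half-up rounded to 2 dp."""
    if N < 1:
        raise ValueError("alleles-per-sample ratio undefined for N = 0")
    return ratio2(nA, N)
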