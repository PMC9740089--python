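"""Synthetic genotype tables for low-diversity populations.

Two generators:

* :func:`simulate_population` draws genotypes independently per locus from
  declared allele-frequency vectors — the way a bottlenecked, low-variation
  population looks in a genotype table: few alleles per locus, one common
  allele with a rare tail, many shared genotypes.
* :func:`plant_cover_instance` builds set-cover instances with a known
  optimum: ``k`` carrier samples each hold at least one private allele no
  other sample carries, and together the carriers hold every allele in the
  table, so the minimum 100%-coverage selection is exactly the carriers.

All randomness flows through one ``numpy`` generator seeded per call;
selection code never consumes randomness, so fixtures are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genotype_io import (
    ALLOWED_PLOIDIES,
    Call,
    GenotypeTable,
    LocusDef,
    SampleProfile,
)

__all__ = [
    "LocusSpec",
    "SimSpec",
    "PlantedInstance",
    "simulate_population",
    "plant_cover_instance",
    "low_diversity_spec",
]


@dataclass(frozen=True)
class LocusSpec:
    """One simulated locus: name, ploidy, and its allele-frequency vector."""

    name: str
    ploidy: int
    frequencies: tuple[float, ...]
    labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.ploidy not in ALLOWED_PLOIDIES:
            raise ValueError(f"locus {self.name!r}: ploidy must be 2 or 4")
        if not self.frequencies:
            raise ValueError(f"locus {self.name!r}: empty frequency vector")
        if any(f < 0 for f in self.frequencies):
            raise ValueError(f"locus {self.name!r}: negative allele frequency")
        if not math.isclose(sum(self.frequencies), 1.0, abs_tol=1e-9):
            raise ValueError(
                f"locus {self.name!r}: frequencies sum to "
                f"{sum(self.frequencies)}, expected 1"
            )
        if self.labels is not None and len(self.labels) != len(self.frequencies):
            raise ValueError(f"locus {self.name!r}: one label per frequency required")

    def allele_labels(self) -> tuple[str, ...]:
        if self.labels is not None:
            return self.labels
        # fragment-length-style labels, distinct within the locus
        return tuple(str(100 + 2 * i) for i in range(len(self.frequencies)))


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one simulated population draw."""

    n_samples: int
    loci: tuple[LocusSpec, ...]
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        names = [locus.name for locus in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names in simulation spec")


@dataclass(frozen=True)
class PlantedInstance:
    """A table whose minimum 100%-cover size is known by construction."""

    table: GenotypeTable
    planted_k: int
    carrier_ids: tuple[str, ...]


def _locus_defs(loci: Sequence[LocusSpec]) -> tuple[LocusDef, ...]:
    defs = []
    col = 2
    for locus in loci:
        defs.append(
            LocusDef(
                name=locus.name,
                ploidy=locus.ploidy,
                column_span=(col, col + locus.ploidy - 1),
            )
        )
        col += locus.ploidy
    return tuple(defs)


def _sample_id(i: int, width: int) -> str:
    return f"S{i + 1:0{width}d}"


def simulate_population(spec: SimSpec) -> GenotypeTable:
    """Draw a genotype table from per-locus allele frequencies.

    Each call slot is an independent draw from its locus's frequency
    vector, masked missing with probability ``spec.missing_rate``.
    Identical specs (including seed) yield identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    width = max(2, len(str(spec.n_samples)))
    samples = []
    for i in range(spec.n_samples):
        calls: dict[str, tuple[Call, ...]] = {}
        for locus in spec.loci:
            labels = locus.allele_labels()
            draws = rng.choice(len(labels), size=locus.ploidy, p=locus.frequencies)
            slots: list[Call] = [labels[d] for d in draws]
            if spec.missing_rate > 0:
                mask = rng.random(locus.ploidy) < spec.missing_rate
                slots = [None if m else s for s, m in zip(slots, mask)]
            calls[locus.name] = tuple(slots)
        samples.append(SampleProfile(sample_id=_sample_id(i, width), calls=calls))
    table = GenotypeTable(loci=_locus_defs(spec.loci), samples=tuple(samples))
    table.validate()
    return table


def low_diversity_spec(
    n_samples: int = 48,
    n_loci: int = 13,
    n_tetrasomic: int = 1,
    max_alleles: int = 5,
    missing_rate: float = 0.0,
    seed: int = 0,
    decay: float = 0.35,
) -> SimSpec:
    """A bottlenecked-population spec: few alleles per locus, rare tails.

    Defaults mirror a small-lake fish bank panel: 48 samples typed at 13
    microsatellite loci, one of them tetrasomic, at most 5 alleles per
    locus.  Per-locus allele counts are drawn 1 + Binomial(max_alleles-1,
    0.3) (mean ~2.2), and frequencies decay geometrically (ratio ``decay``)
    so each locus has one common allele and a rare tail.
    """
    if n_loci < 1 or not 0 <= n_tetrasomic <= n_loci:
        raise ValueError("need n_loci >= 1 and 0 <= n_tetrasomic <= n_loci")
    rng = np.random.default_rng(seed)
    loci = []
    for i in range(n_loci):
        ploidy = 4 if i >= n_loci - n_tetrasomic else 2
        n_alleles = 1 + int(rng.binomial(max_alleles - 1, 0.3))
        raw = np.array([decay**j for j in range(n_alleles)])
        freqs = tuple(float(f) for f in raw / raw.sum())
        loci.append(LocusSpec(name=f"L{i + 1:02d}", ploidy=ploidy, frequencies=freqs))
    return SimSpec(
        n_samples=n_samples,
        loci=tuple(loci),
        missing_rate=missing_rate,
        seed=int(rng.integers(2**31)),
    )


def plant_cover_instance(
    k: int,
    n_samples: int,
    loci: Optional[Sequence[tuple[str, int]]] = None,
    seed: int = 0,
) -> PlantedInstance:
    """Build a table whose minimum 100%-cover has exactly ``k`` samples.

    ``k`` carrier samples are planted at random positions.  Each carrier
    holds one private allele (present in no other sample), so every full
    cover must include all carriers; the carriers jointly hold every allele
    in the table, so they alone suffice.  Non-carriers draw only from the
    shared alleles the carriers hold.  ``loci`` is a sequence of
    (name, ploidy) pairs; default five disomic loci.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_samples < k:
        raise ValueError("n_samples must be >= k")
    locus_shapes = list(loci) if loci is not None else [(f"P{i+1}", 2) for i in range(5)]
    if not locus_shapes:
        raise ValueError("at least one locus required")
    for name, ploidy in locus_shapes:
        if ploidy not in ALLOWED_PLOIDIES:
            raise ValueError(f"locus {name!r}: ploidy must be 2 or 4")

    rng = np.random.default_rng(seed)
    n_loci = len(locus_shapes)
    carrier_pos = sorted(rng.choice(n_samples, size=k, replace=False).tolist())
    # round-robin assignment of each carrier's private allele to a locus
    private_locus = [c % n_loci for c in range(k)]

    # shared pool per locus, sized to fit in the carriers' non-private slots
    shared_labels: list[list[str]] = []
    for li, (name, ploidy) in enumerate(locus_shapes):
        n_private_here = sum(1 for pl in private_locus if pl == li)
        free_slots = ploidy * k - n_private_here
        if free_slots < 1:
            raise ValueError(
                f"locus {name!r}: not enough carrier slots to place shared alleles"
            )
        n_shared = min(2, free_slots)
        shared_labels.append([str(100 + 2 * j) for j in range(n_shared)])

    # carrier genotypes: shared draws, then the private allele, then repair
    # so every shared allele occurs in at least one carrier
    carrier_calls: list[list[list[str]]] = []  # [carrier][locus][slot]
    private_slot: list[tuple[int, int]] = []  # (locus, slot) per carrier
    for c in range(k):
        per_locus = []
        for li, (name, ploidy) in enumerate(locus_shapes):
            pool = shared_labels[li]
            per_locus.append([pool[j] for j in rng.integers(len(pool), size=ploidy)])
        li = private_locus[c]
        per_locus[li][0] = str(9000 + c)  # private allele, unique bank-wide
        private_slot.append((li, 0))
        carrier_calls.append(per_locus)
    for li, (name, ploidy) in enumerate(locus_shapes):
        open_slots = [
            (c, s)
            for c in range(k)
            for s in range(ploidy)
            if (li, s) != private_slot[c]
        ]
        for label in shared_labels[li]:
            counts: dict[str, int] = {}
            for c, s in open_slots:
                counts[carrier_calls[c][li][s]] = counts.get(carrier_calls[c][li][s], 0) + 1
            if label in counts:
                continue
            # overwrite only a slot whose label occurs elsewhere too, so a
            # repair never erases the sole copy of another shared allele
            safe = [(c, s) for c, s in open_slots if counts[carrier_calls[c][li][s]] > 1]
            if not safe:  # unreachable while pool size <= open slots; kept defensive
                safe = open_slots
            c, s = safe[int(rng.integers(len(safe)))]
            carrier_calls[c][li][s] = label

    width = max(2, len(str(n_samples)))
    carrier_iter = iter(range(k))
    carrier_of_pos = {pos: next(carrier_iter) for pos in carrier_pos}
    samples = []
    for i in range(n_samples):
        calls: dict[str, tuple[Call, ...]] = {}
        if i in carrier_of_pos:
            c = carrier_of_pos[i]
            for li, (name, ploidy) in enumerate(locus_shapes):
                calls[name] = tuple(carrier_calls[c][li])
        else:
            for li, (name, ploidy) in enumerate(locus_shapes):
                pool = shared_labels[li]
                calls[name] = tuple(
                    pool[j] for j in rng.integers(len(pool), size=ploidy)
                )
        samples.append(SampleProfile(sample_id=_sample_id(i, width), calls=calls))

    locus_specs = tuple(
        LocusSpec(name=name, ploidy=ploidy, frequencies=(1.0,))
        for name, ploidy in locus_shapes
    )
    table = GenotypeTable(loci=_locus_defs(locus_specs), samples=tuple(samples))
    table.validate()
    return PlantedInstance(
        table=table,
        planted_k=k,
        carrier_ids=tuple(samples[pos].sample_id for pos in carrier_pos),
    )
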