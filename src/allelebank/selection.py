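"""Choosing the fewest samples that carry a target share of all alleles.

This is a minimum set cover over per-sample allele sets: the universe is
every (locus, allele) pair detected across the whole bank, each sample
contributes the set of pairs its genotype carries, and a selection is
feasible when its pooled pairs reach ``ceil(target% x nA)``.  Two solvers
are provided:

* :func:`select_greedy` — the classic approximation: repeatedly add the
  sample contributing the most not-yet-covered alleles (ties broken by
  input-row order).
* :func:`select_exact` — depth-first branch-and-bound that proves minimum
  cardinality, seeded with the greedy solution as incumbent and pruned by
  a per-step gain bound and suffix-reachability.  Among equal-size optima
  it returns the lexicographically-first by input order.

Allele sets are packed into integer bitmasks internally; set cover is
NP-hard in general, but gamete banks are small (tens to a few hundred
samples) and low-diversity, so exact solutions are routinely affordable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

from ._rounding import round2
from .diversity import AlleleInventory, AllelePair, allele_inventory, sample_allele_set
from .genotype_io import GenotypeTable

__all__ = [
    "CoverageTarget",
    "SelectionResult",
    "InfeasibleSelectionError",
    "BudgetExhaustedWarning",
    "required_allele_count",
    "coverage_percent",
    "select_greedy",
    "select_exact",
    "select",
    "DEFAULT_EXACT_BUDGET",
    "AUTO_EXACT_MAX_N",
]

#: Node-expansion budget for the exact solver before it falls back to the
#: best incumbent with ``optimal=False``.
DEFAULT_EXACT_BUDGET = 2_000_000

#: ``mode="auto"`` uses the exact solver up to this many samples.
AUTO_EXACT_MAX_N = 40


class InfeasibleSelectionError(ValueError):
    """No selection can reach the requested coverage."""


class BudgetExhaustedWarning(UserWarning):
    """The exact solver hit its node budget; the result may be suboptimal."""


@dataclass(frozen=True)
class CoverageTarget:
    """Share of total allelic diversity the selection must carry, in (0, 100]."""

    percent: float = 100.0

    def __post_init__(self) -> None:
        if not 0 < self.percent <= 100:
            raise ValueError(
                f"coverage target must be in (0, 100], got {self.percent}"
            )


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a sample selection.

    ``selected_ids`` is in selection order for the greedy solver and in
    input order for the exact solver.  ``achieved_percent`` is
    100 x |covered| / nA, half-up rounded to 2 dp (100.00 when nA = 0:
    an empty target is vacuously covered).
    """

    selected_ids: tuple[str, ...]
    covered: frozenset[AllelePair]
    achieved_percent: float
    solver: str
    optimal: bool


def required_allele_count(total_nA: int, target: CoverageTarget) -> int:
    """Alleles needed to meet the target: ``ceil(percent/100 x nA)``."""
    return math.ceil(Fraction(repr(target.percent)) / 100 * total_nA)


def coverage_percent(
    covered: frozenset[AllelePair] | set[AllelePair], inventory: AlleleInventory
) -> float:
    """Share of the inventory the covered pairs represent, 2-dp half-up."""
    total = inventory.total_nA
    if total == 0:
        return 100.0
    return round2(Fraction(100 * len(covered), total))


# --------------------------------------------------------------------------
# Bitmask packing


def _pack(table: GenotypeTable) -> tuple[list[int], dict[AllelePair, int], int]:
    """Per-sample allele sets as bitmasks over a fixed pair -> bit mapping."""
    inventory = allele_inventory(table)
    bit_of: dict[AllelePair, int] = {}
    for locus in table.loci:
        for allele in sorted(inventory.per_locus[locus.name], key=int):
            bit_of[(locus.name, allele)] = len(bit_of)
    masks = []
    for profile in table.samples:
        pairs = sample_allele_set(profile, table.loci).alleles
        mask = 0
        for pair in pairs:
            mask |= 1 << bit_of[pair]
        masks.append(mask)
    return masks, bit_of, inventory.total_nA


def _unpack(mask: int, bit_of: dict[AllelePair, int]) -> frozenset[AllelePair]:
    return frozenset(pair for pair, bit in bit_of.items() if mask >> bit & 1)


def _result(
    table: GenotypeTable,
    chosen: list[int],
    covered_mask: int,
    bit_of: dict[AllelePair, int],
    total_nA: int,
    solver: str,
    optimal: bool,
    input_order: bool,
) -> SelectionResult:
    indices = sorted(chosen) if input_order else chosen
    covered = _unpack(covered_mask, bit_of)
    if total_nA == 0:
        achieved = 100.0
    else:
        achieved = round2(Fraction(100 * len(covered), total_nA))
    return SelectionResult(
        selected_ids=tuple(table.samples[i].sample_id for i in indices),
        covered=covered,
        achieved_percent=achieved,
        solver=solver,
        optimal=optimal,
    )


# --------------------------------------------------------------------------
# Greedy solver


def _greedy_indices(masks: list[int], required: int) -> tuple[list[int], int]:
    covered = 0
    chosen: list[int] = []
    available = set(range(len(masks)))
    while bin(covered).count("1") < required:
        best_i, best_gain = -1, 0
        for i in sorted(available):
            gain = bin(masks[i] & ~covered).count("1")
            if gain > best_gain:  # strict: earliest input row wins ties
                best_i, best_gain = i, gain
        if best_i < 0:
            raise InfeasibleSelectionError(
                f"no sample adds coverage: {bin(covered).count('1')} of "
                f"{required} required alleles reachable"
            )
        chosen.append(best_i)
        covered |= masks[best_i]
        available.remove(best_i)
    return chosen, covered


def select_greedy(
    table: GenotypeTable, target: CoverageTarget = CoverageTarget()
) -> SelectionResult:
    """Greedy cover: repeatedly take the sample adding the most new alleles.

    Deterministic for a fixed input file; ties go to the earliest input
    row.  Samples whose allele set is empty are never selected.
    """
    masks, bit_of, total_nA = _pack(table)
    required = required_allele_count(total_nA, target)
    chosen, covered = _greedy_indices(masks, required)
    return _result(
        table, chosen, covered, bit_of, total_nA,
        solver="greedy", optimal=False, input_order=False,
    )


# --------------------------------------------------------------------------
# Exact solver (branch and bound)


def _exact_indices(
    masks: list[int],
    required: int,
    max_samples: Optional[int],
    budget: int,
) -> tuple[list[int], bool]:
    """Minimum-cardinality cover over bitmask sets.

    Depth-first in input order, include-branch first, so the first solution
    found at the optimal size is the lexicographically-first optimum by
    input order.  Pruning: greedy incumbent, suffix-union reachability, and
    ``ceil(remaining needed / largest remaining set)`` lower bound.
    """
    n = len(masks)
    greedy_chosen, _ = _greedy_indices(masks, required)

    # Accept solutions strictly below this size.  Starting one above the
    # greedy size (not at it) means the lex-first solution of the optimal
    # size is always encountered and recorded, even when greedy is optimal.
    best_size = len(greedy_chosen) + 1
    if max_samples is not None:
        best_size = min(best_size, max_samples + 1)
    best: Optional[list[int]] = None

    sizes = [bin(m).count("1") for m in masks]
    suffix_union = [0] * (n + 1)
    suffix_max = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        suffix_union[i] = suffix_union[i + 1] | masks[i]
        suffix_max[i] = max(suffix_max[i + 1], sizes[i])

    expansions = 0
    exhausted = False

    def dfs(i: int, covered: int, chosen: list[int]) -> None:
        nonlocal best, best_size, expansions, exhausted
        if exhausted:
            return
        expansions += 1
        if expansions > budget:
            exhausted = True
            return
        missing = required - bin(covered).count("1")
        if missing <= 0:
            if len(chosen) < best_size:
                best, best_size = list(chosen), len(chosen)
            return
        if i >= n:
            return
        # reachability: can the remaining samples still cover what's needed?
        if bin((covered | suffix_union[i])).count("1") < required:
            return
        # each further sample adds at most suffix_max[i] new alleles
        lower = len(chosen) + math.ceil(missing / suffix_max[i])
        if lower >= best_size:
            return
        gain = masks[i] & ~covered
        if gain:  # include-first keeps lex order; zero-gain inclusion is useless
            chosen.append(i)
            dfs(i + 1, covered | masks[i], chosen)
            chosen.pop()
        dfs(i + 1, covered, chosen)

    dfs(0, 0, [])

    if best is None:
        # Only possible when the budget ran out before any solution was
        # recorded, or when max_samples cuts below the true minimum.
        if max_samples is not None and len(greedy_chosen) > max_samples:
            raise InfeasibleSelectionError(
                f"no selection of at most {max_samples} sample(s) reaches "
                f"the target"
                + (" within the search budget" if exhausted else "")
            )
        return sorted(greedy_chosen), False

    return best, not exhausted


def select_exact(
    table: GenotypeTable,
    target: CoverageTarget = CoverageTarget(),
    *,
    max_samples: Optional[int] = None,
    budget: int = DEFAULT_EXACT_BUDGET,
) -> SelectionResult:
    """Provably minimum-cardinality selection meeting the coverage target.

    Returns the lexicographically-first optimum by input order.  If the
    node-expansion ``budget`` runs out, the best selection found so far is
    returned with ``optimal=False`` and a :class:`BudgetExhaustedWarning`.
    ``max_samples`` optionally caps the allowed selection size; an
    :class:`InfeasibleSelectionError` is raised if no selection within the
    cap can reach the target.
    """
    masks, bit_of, total_nA = _pack(table)
    required = required_allele_count(total_nA, target)
    chosen, proven = _exact_indices(masks, required, max_samples, budget)
    if not proven:
        warnings.warn(
            f"exact search budget of {budget} node expansions exhausted; "
            f"returning best-known selection of {len(chosen)} sample(s)",
            BudgetExhaustedWarning,
            stacklevel=2,
        )
    covered = 0
    for i in chosen:
        covered |= masks[i]
    return _result(
        table, sorted(chosen), covered, bit_of, total_nA,
        solver="exact", optimal=proven, input_order=True,
    )


def select(
    table: GenotypeTable,
    target: CoverageTarget = CoverageTarget(),
    *,
    mode: str = "auto",
    max_samples: Optional[int] = None,
    budget: int = DEFAULT_EXACT_BUDGET,
) -> SelectionResult:
    """Dispatch to a solver: ``greedy``, ``exact``, or ``auto``.

    ``auto`` uses the exact solver up to ``AUTO_EXACT_MAX_N`` samples and
    the greedy approximation beyond that.
    """
    if mode not in ("greedy", "exact", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = "exact" if table.n_samples <= AUTO_EXACT_MAX_N else "greedy"
    if mode == "exact":
        return select_exact(table, target, max_samples=max_samples, budget=budget)
    return select_greedy(table, target)
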