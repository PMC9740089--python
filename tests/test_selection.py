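"""Greedy and exact sample selection over pooled (locus, allele) pairs."""

from __future__ import annotations

import io

import pytest

from allelebank import (
    BudgetExhaustedWarning,
    CoverageTarget,
    GenotypeTable,
    InfeasibleSelectionError,
    allele_inventory,
    coverage_percent,
    read_genotype_table,
    required_allele_count,
    sample_allele_set,
    select,
    select_exact,
    select_greedy,
)

from conftest import brute_force_min_cover, random_table


class TestRequiredAlleleCount:
    @pytest.mark.parametrize(
        "total,percent,expected",
        [(9, 100, 9), (9, 50, 5), (0, 100, 0), (10, 33, 4), (66, 100, 66)],
    )
    def test_ceiling_of_target_share(self, total, percent, expected):
        assert required_allele_count(total, CoverageTarget(percent)) == expected

    def test_target_bounds_enforced(self):
        for bad in (0, -5, 100.5):
            with pytest.raises(ValueError):
                CoverageTarget(bad)


class TestCoveragePercent:
    def test_toy_single_sample_covers_seven_ninths(self, toy_table):
        inv = allele_inventory(toy_table)
        s4 = sample_allele_set(toy_table.samples[3], toy_table.loci)
        assert coverage_percent(s4.alleles, inv) == 77.78

    def test_empty_selection_is_zero(self, toy_table):
        assert coverage_percent(frozenset(), allele_inventory(toy_table)) == 0.0

    def test_all_samples_cover_everything(self, toy_table):
        inv = allele_inventory(toy_table)
        assert coverage_percent(inv.pairs(), inv) == 100.0

    def test_vacuous_coverage_when_no_alleles(self):
        table = read_genotype_table(io.StringIO("ID,L1,L1\n"))
        assert coverage_percent(frozenset(), allele_inventory(table)) == 100.0


class TestGreedy:
    def test_toy_full_target_trace(self, toy_table):
        result = select_greedy(toy_table)
        assert result.selected_ids == ("S4", "S1")  # 7 pairs, then L1:1 + L1:2
        assert result.achieved_percent == 100.0
        assert result.solver == "greedy" and result.optimal is False

    def test_toy_half_target_stops_after_first_pick(self, toy_table):
        result = select_greedy(toy_table, CoverageTarget(50))
        assert result.selected_ids == ("S4",)
        assert result.achieved_percent == 77.78

    def test_single_carrier_of_everything(self):
        table = read_genotype_table(
            io.StringIO("ID,L1,L1\nS1,1,1\nS2,1,2\nS3,2,2\n")
        )
        assert select_greedy(table).selected_ids == ("S2",)

    def test_tie_broken_by_input_order(self):
        table = read_genotype_table(io.StringIO("ID,L1,L1\nS1,1,2\nS2,3,4\n"))
        result = select_greedy(table, CoverageTarget(50))
        assert result.selected_ids == ("S1",)

    @pytest.mark.parametrize("seed", range(10))
    def test_lowering_target_never_enlarges_selection(self, seed):
        table = random_table(seed)
        sizes = [
            len(select_greedy(table, CoverageTarget(pct)).selected_ids)
            for pct in (100, 75, 50, 25, 1)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_all_missing_samples_never_selected(self):
        table = read_genotype_table(
            io.StringIO("ID,L1,L1\nS1,0,0\nS2,1,2\nS3,0,\n")
        )
        for result in (select_greedy(table), select_exact(table)):
            assert result.selected_ids == ("S2",)


class TestExact:
    def test_toy_optimum_is_two_samples(self, toy_table):
        result = select_exact(toy_table)
        assert len(result.selected_ids) == 2  # no single sample holds 9 pairs
        assert result.achieved_percent == 100.0
        assert result.optimal is True and result.solver == "exact"

    def test_identical_samples_need_one(self):
        table = read_genotype_table(io.StringIO("ID,L1,L1\nS1,1,2\nS2,1,2\n"))
        assert select_exact(table).selected_ids == ("S1",)

    def test_result_ids_in_input_order_and_lex_first(self):
        # S1+S3 and S2+S3 both optimal; lexicographically-first wins
        table = read_genotype_table(
            io.StringIO("ID,L1,L1,L2,L2\nS1,1,2,5,5\nS2,1,2,5,5\nS3,3,4,6,6\n")
        )
        assert select_exact(table).selected_ids == ("S1", "S3")

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force_oracle(self, seed):
        table = random_table(seed)
        for pct in (100, 60):
            exact = select_exact(table, CoverageTarget(pct))
            assert exact.optimal
            assert len(exact.selected_ids) == brute_force_min_cover(table, pct)

    @pytest.mark.parametrize("seed", range(15))
    def test_never_larger_than_greedy_and_both_feasible(self, seed):
        table = random_table(seed)
        for pct in (100, 70):
            target = CoverageTarget(pct)
            exact = select_exact(table, target)
            greedy = select_greedy(table, target)
            assert len(exact.selected_ids) <= len(greedy.selected_ids)
            assert exact.achieved_percent >= pct
            assert greedy.achieved_percent >= pct

    @pytest.mark.parametrize("seed", range(10))
    def test_full_cover_solutions_are_irredundant(self, seed):
        table = random_table(seed)
        result = select_exact(table)
        total = allele_inventory(table).total_nA
        sets = {
            p.sample_id: sample_allele_set(p, table.loci).alleles
            for p in table.samples
        }
        for dropped in result.selected_ids:
            pooled = frozenset().union(
                *(sets[sid] for sid in result.selected_ids if sid != dropped),
                frozenset(),
            )
            assert len(pooled) < total

    def test_budget_exhaustion_returns_incumbent_with_flag(self, toy_table):
        with pytest.warns(BudgetExhaustedWarning):
            result = select_exact(toy_table, budget=2)
        assert result.optimal is False
        assert result.achieved_percent == 100.0

    def test_max_samples_below_optimum_is_infeasible(self, toy_table):
        with pytest.raises(InfeasibleSelectionError):
            select_exact(toy_table, max_samples=1)

    def test_empty_table_selects_nothing(self):
        table = read_genotype_table(io.StringIO("ID,L1,L1\n"))
        result = select_exact(table)
        assert result.selected_ids == ()
        assert result.achieved_percent == 100.0  # vacuous


class TestDispatchAndDeterminism:
    def test_auto_uses_exact_for_small_tables(self, toy_table):
        assert select(toy_table, mode="auto").solver == "exact"

    def test_unknown_mode_rejected(self, toy_table):
        with pytest.raises(ValueError):
            select(toy_table, mode="fastest")

    @pytest.mark.parametrize("seed", range(5))
    def test_identical_input_gives_identical_result(self, seed):
        table = random_table(seed)
        for solver in (select_greedy, select_exact):
            assert solver(table) == solver(table)
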