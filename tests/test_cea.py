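"""ICER arithmetic, dominance flags, efficiency frontier."""

import itertools
import math

import pytest

from ptsd_cea.cea import (EXTENDED, NO_DOMINANCE, STRICT, build_cea_table,
                          icer, load_reference_totals, render_table)


@pytest.fixture(scope="module")
def reference():
    return load_reference_totals()


class TestIcer:
    def test_short_term_frontier_worked_cell(self):
        assert icer(2226.3, 0.97, 2051.1, 0.96) == pytest.approx(17520.0)

    def test_long_term_frontier_worked_cell(self):
        assert icer(2269.8, 12.92, 2095.7, 12.86) == pytest.approx(2901.7, abs=0.05)

    def test_equal_qalys_undefined(self):
        assert math.isnan(icer(10.0, 1.0, 20.0, 1.0))

    def test_difference_quotient_symmetry(self):
        a, b = (120.0, 1.5), (80.0, 1.1)
        assert icer(*a, *b) == pytest.approx(icer(*b, *a))


class TestWorkedExampleTables:
    """The published per-arm totals reproduce the printed ICER cells."""

    def test_short_term_icers_and_dominance(self, reference):
        df = build_cea_table(reference["short_term_12m"]).set_index("strategy")
        assert df.loc["counselling", "icer_vs_comparator"] == \
            pytest.approx(34567, abs=0.5)
        assert df.loc["tfcbt", "icer_vs_comparator"] == pytest.approx(22790, abs=0.5)
        assert df.loc["tfcbt_ssri", "icer_vs_comparator"] == \
            pytest.approx(22263, abs=0.5)
        assert df.loc["tfcbt_ssri", "frontier_icer"] == pytest.approx(17520, abs=0.5)
        assert df.loc["counselling", "dominance"] == STRICT

    def test_long_term_icers_and_dominance(self, reference):
        df = build_cea_table(reference["long_term_31y"]).set_index("strategy")
        assert df.loc["counselling", "icer_vs_comparator"] == \
            pytest.approx(2081.57, abs=0.005)
        # increments derive from the printed totals (12.86 - 11.59 = 1.27)
        assert df.loc["tfcbt", "icer_vs_comparator"] == \
            pytest.approx(1650.16, abs=0.005)
        assert df.loc["tfcbt_ssri", "frontier_icer"] == \
            pytest.approx(2901.7, abs=0.05)
        assert df.loc["counselling", "dominance"] == STRICT

    def test_render_rounding_modes(self, reference):
        df = render_table(build_cea_table(reference["short_term_12m"]),
                          icer_decimals=0).set_index("strategy")
        assert df.loc["counselling", "icer_vs_comparator"] == 34567


class TestTableBuilder:
    ROWS = [
        {"strategy": "none", "cost": 0.0, "qaly": 10.0},
        {"strategy": "a", "cost": 900.0, "qaly": 11.0},
        {"strategy": "b", "cost": 1000.0, "qaly": 11.5},
        {"strategy": "c", "cost": 1050.0, "qaly": 12.0},
    ]

    def test_permutation_invariance(self):
        base = build_cea_table(self.ROWS, comparator="none")
        for perm in itertools.permutations(self.ROWS):
            df = build_cea_table(list(perm), comparator="none")
            assert df.reset_index(drop=True).equals(base.reset_index(drop=True))

    def test_removing_dominated_strategy_changes_nothing_else(self):
        rows = self.ROWS + [
            {"strategy": "dud", "cost": 2000.0, "qaly": 10.5}]
        full = build_cea_table(rows, comparator="none")
        assert full.set_index("strategy").loc["dud", "dominance"] == STRICT
        reduced = build_cea_table(self.ROWS, comparator="none")
        full_wo = full[full.strategy != "dud"].reset_index(drop=True)
        assert full_wo.equals(reduced.reset_index(drop=True))

    def test_extended_dominance_matches_chord_construction(self):
        # the middle point lies above the segment joining its neighbours
        rows = [{"strategy": "a", "cost": 0.0, "qaly": 0.0},
                {"strategy": "b", "cost": 80.0, "qaly": 1.0},
                {"strategy": "c", "cost": 100.0, "qaly": 2.0}]
        df = build_cea_table(rows, comparator="a").set_index("strategy")
        # oracle: blend of a and c with the same QALYs as b costs less
        t = (2.0 - 1.0) / (2.0 - 0.0)
        blended_cost = t * 0.0 + (1 - t) * 100.0
        assert blended_cost < 80.0
        assert df.loc["b", "dominance"] == EXTENDED
        # frontier chain keeps non-strictly-dominated rows: c vs b
        assert df.loc["c", "frontier_icer"] == pytest.approx(20.0)

    def test_exact_ties_do_not_dominate(self):
        rows = [{"strategy": "none", "cost": 0.0, "qaly": 1.0},
                {"strategy": "x", "cost": 50.0, "qaly": 2.0},
                {"strategy": "y", "cost": 50.0, "qaly": 2.0}]
        df = build_cea_table(rows, comparator="none")
        assert set(df[df.strategy.isin(["x", "y"])]["dominance"]) == \
            {NO_DOMINANCE}

    def test_frontier_icers_increase_on_a_convex_frontier(self):
        rows = [{"strategy": "none", "cost": 0.0, "qaly": 10.0},
                {"strategy": "a", "cost": 900.0, "qaly": 11.0},
                {"strategy": "b", "cost": 1400.0, "qaly": 11.5},
                {"strategy": "c", "cost": 2000.0, "qaly": 12.0}]
        df = build_cea_table(rows, comparator="none")
        assert set(df["dominance"]) == {NO_DOMINANCE}
        vals = list(df["frontier_icer"].dropna())
        assert vals == sorted(vals) == [900.0, 1000.0, 1200.0]

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_cea_table(self.ROWS + [self.ROWS[1]], comparator="none")

    def test_missing_comparator_rejected(self):
        with pytest.raises(ValueError, match="comparator"):
            build_cea_table(self.ROWS, comparator="ghost")
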