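"""Accumulated factor-level effects and smaller-the-better selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemoqc.effect_analysis import (
    ConditionResult,
    accumulate_effects,
    results_from_per_run,
    select_optimal_levels,
)
from hemoqc.errors import ConsistencyError, StructuralError
from hemoqc.experiment_design import build_l9


def _results_from_counts(plan, defective):
    return [
        ConditionResult(
            condition_id=i + 1,
            levels=plan.design.row(i + 1),
            defective=int(d),
            good=30 - int(d),
            sample=30,
        )
        for i, d in enumerate(defective)
    ]


class TestAccumulate:
    def test_reference_accumulated_counts(self, reference_effects):
        """Pooled defective counts per factor-level from the 270-run table."""
        expected = {
            "A": (23, 35, 28),
            "B": (28, 34, 24),
            "C": (28, 21, 37),
            "D": (28, 26, 32),
        }
        for factor, counts in expected.items():
            for level, count in enumerate(counts, start=1):
                assert reference_effects.defective(factor, level) == count
                assert reference_effects._cell(factor, level)["total"] == 90
        assert reference_effects.total_defective == 86
        assert reference_effects.total_sample == 270

    def test_reference_rates(self, reference_effects):
        assert reference_effects.rate("A", 1) == pytest.approx(23 / 90)
        assert round(reference_effects.rate("A", 1), 2) == 0.26
        expected_2dp = {
            "A": (0.26, 0.39, 0.31),
            "B": (0.31, 0.38, 0.27),
            "C": (0.31, 0.23, 0.41),
            "D": (0.31, 0.29, 0.36),
        }
        for factor, rates in expected_2dp.items():
            for level, rate in enumerate(rates, start=1):
                assert round(reference_effects.rate(factor, level), 2) == rate

    def test_all_zero_defective(self, plan):
        effects = accumulate_effects(plan, _results_from_counts(plan, [0] * 9))
        assert (effects.table["rate"] == 0.0).all()
        assert effects.overall_rate == 0.0

    def test_missing_condition_rejected(self, plan, reference_results):
        with pytest.raises(StructuralError):
            accumulate_effects(plan, reference_results[:-1])

    def test_duplicate_condition_rejected(self, plan, reference_results):
        with pytest.raises(StructuralError):
            accumulate_effects(plan, reference_results[:-1] + [reference_results[0]])

    def test_inconsistent_levels_rejected(self, plan, reference_results):
        bad = list(reference_results)
        r = bad[0]
        bad[0] = ConditionResult(r.condition_id, (2, 1, 1, 1), r.defective, r.good, r.sample)
        with pytest.raises(ConsistencyError):
            accumulate_effects(plan, bad)

    @given(defective=st.lists(st.integers(0, 30), min_size=9, max_size=9))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_per_run_tally(self, plan, defective):
        """Accumulation equals an independent per-run tally on random counts."""
        effects = accumulate_effects(plan, _results_from_counts(plan, defective))
        l9 = build_l9().cells
        for col, factor in enumerate("ABCD"):
            for level in (1, 2, 3):
                brute = sum(
                    d for row, d in zip(l9, defective) if row[col] == level
                )
                assert effects.defective(factor, level) == brute
            # conservation: the three level counts sum to the overall total
            assert sum(effects.defective(factor, l) for l in (1, 2, 3)) == sum(defective)

    @given(order=st.permutations(list(range(9))))
    @settings(max_examples=25, deadline=None)
    def test_permutation_invariance(self, plan, reference_results, order):
        shuffled = [reference_results[i] for i in order]
        effects = accumulate_effects(plan, shuffled)
        for factor in "ABCD":
            for level in (1, 2, 3):
                assert effects.defective(factor, level) == accumulate_effects(
                    plan, reference_results
                ).defective(factor, level)


class TestPerRunReduction:
    def test_per_run_rows_reduce_to_condition_counts(self, plan, reference_results):
        rows = []
        run_id = 1
        for r in reference_results:
            for outcome, count in (("defective", r.defective), ("good", r.good)):
                for _ in range(count):
                    rows.append(
                        {"run_id": run_id, "condition": r.condition_id,
                         **dict(zip("ABCD", r.levels)), "outcome": outcome}
                    )
                    run_id += 1
        reduced = results_from_per_run(pd.DataFrame(rows), plan)
        assert reduced == reference_results

    def test_level_mismatch_rejected(self, plan):
        df = pd.DataFrame(
            {"run_id": [1], "condition": [1], "A": [3], "B": [1], "C": [1],
             "D": [1], "outcome": ["good"]}
        )
        with pytest.raises(ConsistencyError):
            results_from_per_run(df, plan)


class TestSelection:
    def test_smaller_the_better_reference(self, reference_selection):
        assert reference_selection.label == "A1B3C2D2"
        assert reference_selection.choices == {"A": 1, "B": 3, "C": 2, "D": 2}

    def test_larger_the_better_reference(self, reference_effects):
        sel = select_optimal_levels(reference_effects, direction="larger")
        assert sel.label == "A2B2C3D3"

    def test_ties_break_to_lowest_level(self, plan):
        effects = accumulate_effects(plan, _results_from_counts(plan, [6] * 9))
        sel = select_optimal_levels(effects)
        assert sel.choices == {"A": 1, "B": 1, "C": 1, "D": 1}

    def test_empty_table_rejected(self, reference_effects):
        import dataclasses

        empty = dataclasses.replace(reference_effects, table=reference_effects.table.iloc[:0])
        with pytest.raises(StructuralError):
            select_optimal_levels(empty)


class TestParameterRecovery:
    def test_selection_recovers_generator_argmin_at_large_n(self, plan):
        """With many runs and monotone effects the true argmin is recovered."""
        from hemoqc.synthetic_data import OutcomeProfile, generate_runs
        from hemoqc.experiment_design import make_plan
        from hemoqc.synthetic_data import load_fixture

        # well-separated monotone level effects: p rises with every level index
        l9 = build_l9().cells
        probs = tuple(0.05 + 0.08 * (row.sum() - 4) for row in l9)
        big_plan = make_plan(load_fixture("table2"), runs_per_condition=400)
        runs = generate_runs(big_plan, OutcomeProfile(probs, 400), seed=7)
        effects = accumulate_effects(big_plan, results_from_per_run(runs, big_plan))
        assert select_optimal_levels(effects).label == "A1B1C1D1"
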