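"""Accumulated factor-level effects for binary (good/defective) outcomes.

With an attribute (count-value) quality characteristic, the effect of factor
F at level l is measured by pooling the defective counts of every condition
where F is set to l.  In the L9 plan each level appears in three conditions,
so each factor-level pools 3 x runs_per_condition dialyzers (90 in the
reference study).  The "smaller the better" selection then picks, per
factor, the level with the lowest accumulated defect rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .errors import ConsistencyError, StructuralError
from .experiment_design import N_LEVELS, ExperimentPlan

__all__ = [
    "ConditionResult",
    "EffectTable",
    "LevelSelection",
    "results_from_per_run",
    "results_from_condition_csv",
    "accumulate_effects",
    "select_optimal_levels",
]


@dataclass(frozen=True)
class ConditionResult:
    """Defective/good counts for one condition (one orthogonal-array row)."""

    condition_id: int
    levels: tuple[int, ...]
    defective: int
    good: int
    sample: int

    def __post_init__(self) -> None:
        if min(self.defective, self.good, self.sample) < 0:
            raise StructuralError("counts must be non-negative")
        if self.defective + self.good != self.sample:
            raise StructuralError(
                f"condition {self.condition_id}: defective ({self.defective}) + "
                f"good ({self.good}) != sample ({self.sample})"
            )

    @property
    def defect_rate(self) -> float:
        return self.defective / self.sample if self.sample else 0.0


@dataclass(frozen=True)
class EffectTable:
    """Per factor-level accumulated defective counts and defect rates.

    ``table`` has one row per (factor, level) with columns
    ``factor, level, defective, total, rate``; rates are stored at full
    precision (printed-precision rounding is applied only where a
    reproduction convention requires it, see :mod:`hemoqc.omega`).
    """

    table: pd.DataFrame
    total_defective: int
    total_sample: int

    @property
    def overall_rate(self) -> float:
        """The grand defect rate T-bar = total defective / total sample."""
        return self.total_defective / self.total_sample

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(self.table["factor"].unique())

    def defective(self, factor: str, level: int) -> int:
        return int(self._cell(factor, level)["defective"])

    def rate(self, factor: str, level: int) -> float:
        return float(self._cell(factor, level)["rate"])

    def _cell(self, factor: str, level: int) -> pd.Series:
        rows = self.table[(self.table["factor"] == factor) & (self.table["level"] == level)]
        if len(rows) != 1:
            raise StructuralError(f"no unique effect row for {factor}{level}")
        return rows.iloc[0]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class LevelSelection:
    """The chosen level per factor and the combination label (e.g. A1B3C2D2)."""

    choices: dict[str, int]
    rates: dict[str, float]
    direction: str

    @property
    def label(self) -> str:
        return "".join(f"{f}{l}" for f, l in self.choices.items())


def results_from_per_run(runs: pd.DataFrame, plan: ExperimentPlan) -> list[ConditionResult]:
    """Reduce per-run binary records to per-condition counts.

    ``runs`` columns: ``run_id, condition, A, B, C, D, outcome`` with outcome
    in {"defective", "good"}.  Level columns are checked against the plan.
    """
    required = {"condition", "outcome"}
    if not required.issubset(runs.columns):
        raise StructuralError(f"per-run table needs columns {sorted(required)}")
    bad = set(runs["outcome"].unique()) - {"defective", "good"}
    if bad:
        raise StructuralError(f"unknown outcome values: {sorted(bad)}")
    results = []
    for cond, group in runs.groupby("condition", sort=True):
        cond = int(cond)
        levels = plan.design.row(cond)
        names = plan.factor_names
        if set(names).issubset(runs.columns):
            stated = group[list(names)].drop_duplicates()
            if len(stated) != 1 or tuple(int(v) for v in stated.iloc[0]) != levels:
                raise ConsistencyError(
                    f"condition {cond}: run level columns disagree with the design row {levels}"
                )
        defective = int((group["outcome"] == "defective").sum())
        results.append(
            ConditionResult(
                condition_id=cond,
                levels=levels,
                defective=defective,
                good=len(group) - defective,
                sample=len(group),
            )
        )
    return results


def results_from_condition_csv(path: str | Path, plan: ExperimentPlan) -> list[ConditionResult]:
    """Read per-condition counts (``condition,A,B,C,D,defective,good,sample``)."""
    df = pd.read_csv(path)
    results = []
    for _, row in df.iterrows():
        levels = tuple(int(row[n]) for n in plan.factor_names)
        results.append(
            ConditionResult(
                condition_id=int(row["condition"]),
                levels=levels,
                defective=int(row["defective"]),
                good=int(row["good"]),
                sample=int(row["sample"]),
            )
        )
    return results


def accumulate_effects(
    plan: ExperimentPlan, results: Sequence[ConditionResult]
) -> EffectTable:
    """Pool defective counts per factor-level over the design's conditions.

    Requires exactly one result per design row, with levels matching the row.
    Conservation holds by construction: for every factor the three
    accumulated defective counts sum to the overall defective total.
    """
    if not results:
        raise StructuralError("no condition results supplied")
    ids = [r.condition_id for r in results]
    expected_ids = set(range(1, plan.n_conditions + 1))
    if len(ids) != len(set(ids)):
        raise StructuralError("duplicate condition results")
    if set(ids) != expected_ids:
        missing = sorted(expected_ids - set(ids))
        raise StructuralError(f"missing condition results for conditions {missing}")
    by_id = {r.condition_id: r for r in results}
    for cond in sorted(by_id):
        if by_id[cond].levels != plan.design.row(cond):
            raise ConsistencyError(
                f"condition {cond}: result levels {by_id[cond].levels} do not "
                f"match design row {plan.design.row(cond)}"
            )

    rows = []
    for col, factor in sorted(plan.factor_binding.items()):
        for level in range(1, N_LEVELS + 1):
            members = [
                by_id[c]
                for c in sorted(by_id)
                if plan.design.row(c)[col - 1] == level
            ]
            defective = sum(r.defective for r in members)
            total = sum(r.sample for r in members)
            rows.append(
                {
                    "factor": factor.name,
                    "level": level,
                    "defective": defective,
                    "total": total,
                    "rate": defective / total if total else 0.0,
                }
            )
    return EffectTable(
        table=pd.DataFrame(rows),
        total_defective=sum(r.defective for r in results),
        total_sample=sum(r.sample for r in results),
    )


def select_optimal_levels(
    effects: EffectTable,
    direction: Literal["smaller", "larger"] = "smaller",
) -> LevelSelection:
    """Pick per factor the level minimizing (or maximizing) the defect rate.

    Ties break to the lowest level index, so the output is deterministic.
    """
    if direction not in ("smaller", "larger"):
        raise StructuralError(f"unknown direction {direction!r}")
    if effects.table.empty:
        raise StructuralError("empty effect table")
    choices: dict[str, int] = {}
    rates: dict[str, float] = {}
    sign = 1.0 if direction == "smaller" else -1.0
    for factor in effects.factor_names:
        sub = effects.table[effects.table["factor"] == factor].sort_values("level")
        best_level, best_rate = None, None
        for _, row in sub.iterrows():
            r = float(row["rate"])
            if best_rate is None or sign * r < sign * best_rate:
                best_level, best_rate = int(row["level"]), r
        choices[factor] = best_level
        rates[factor] = best_rate
    return LevelSelection(choices=choices, rates=rates, direction=direction)


def _iter_levels(effects: EffectTable, factor: str) -> Iterable[tuple[int, float]]:  # pragma: no cover
    sub = effects.table[effects.table["factor"] == factor].sort_values("level")
    for _, row in sub.iterrows():
        yield int(row["level"]), float(row["rate"])
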