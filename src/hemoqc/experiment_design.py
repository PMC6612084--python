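"""Factors, levels and the L9(3^4) orthogonal array.

The experiment studies four medical-care factors at three levels each:
heparin anticoagulation dose, blood-flow velocity, dehydration volume and
vascular access type.  Nine conditions of the standard Taguchi L9(3^4)
orthogonal array cover all four factors, each condition repeated a fixed
number of runs (30 in the reference study, 270 runs total).

Only the L9(3^4) array is provided: the design it supports has four
three-level factors and 8 degrees of freedom, which the L9 saturates.
General orthogonal-array construction is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StructuralError

__all__ = [
    "FactorLevel",
    "FactorSpec",
    "DesignMatrix",
    "ExperimentPlan",
    "OrthogonalityReport",
    "build_l9",
    "validate_orthogonality",
    "make_plan",
    "default_factors",
    "factors_from_config",
    "factors_to_config",
    "design_to_csv",
    "design_from_csv",
]

#: Canonical Taguchi L9(3^4) rows (1-based level indices), columns A..D.
L9_ROWS: tuple[tuple[int, int, int, int], ...] = (
    (1, 1, 1, 1),
    (1, 2, 2, 2),
    (1, 3, 3, 3),
    (2, 1, 2, 3),
    (2, 2, 3, 1),
    (2, 3, 1, 2),
    (3, 1, 3, 2),
    (3, 2, 1, 3),
    (3, 3, 2, 1),
)

N_LEVELS = 3


@dataclass(frozen=True)
class FactorLevel:
    """One setting of a factor: a value plus its unit (None for categorical)."""

    value: Any
    unit: str | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.value}" if self.unit is None else f"{self.value} {self.unit}"


@dataclass(frozen=True)
class FactorSpec:
    """A named experimental factor with exactly three ordered levels.

    Levels are addressed with 1-based indices throughout the package, matching
    the convention of orthogonal-array tables.
    """

    name: str
    label: str
    levels: tuple[FactorLevel, ...]

    def __post_init__(self) -> None:
        if len(self.levels) != N_LEVELS:
            raise ConfigurationError(
                f"factor {self.name!r} must have exactly {N_LEVELS} levels, "
                f"got {len(self.levels)}"
            )
        values = [lv.value for lv in self.levels]
        if len(set(map(str, values))) != N_LEVELS:
            raise ConfigurationError(
                f"factor {self.name!r} has duplicate level values: {values}"
            )

    def level(self, index: int) -> FactorLevel:
        """Return the level descriptor for a 1-based level index."""
        if not 1 <= index <= N_LEVELS:
            raise ConfigurationError(
                f"level index {index} out of range 1..{N_LEVELS} for factor {self.name!r}"
            )
        return self.levels[index - 1]

    @property
    def is_numeric(self) -> bool:
        return all(isinstance(lv.value, (int, float)) for lv in self.levels)


@dataclass(frozen=True)
class DesignMatrix:
    """A run x factor grid of 1-based level indices."""

    cells: np.ndarray

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=int)
        if cells.ndim != 2:
            raise StructuralError(f"design cells must be 2-D, got shape {cells.shape}")
        object.__setattr__(self, "cells", cells)

    @property
    def n_runs(self) -> int:
        return self.cells.shape[0]

    @property
    def n_factors(self) -> int:
        return self.cells.shape[1]

    def row(self, condition_id: int) -> tuple[int, ...]:
        """Level tuple of a condition (1-based condition id)."""
        if not 1 <= condition_id <= self.n_runs:
            raise StructuralError(
                f"condition {condition_id} out of range 1..{self.n_runs}"
            )
        return tuple(int(v) for v in self.cells[condition_id - 1])

    def to_frame(self, factor_names: Sequence[str] | None = None) -> pd.DataFrame:
        names = list(factor_names) if factor_names else list("ABCD")[: self.n_factors]
        df = pd.DataFrame(self.cells, columns=names)
        df.insert(0, "run", np.arange(1, self.n_runs + 1))
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DesignMatrix):
            return NotImplemented
        return self.cells.shape == other.cells.shape and bool(
            (self.cells == other.cells).all()
        )


@dataclass(frozen=True)
class OrthogonalityReport:
    """Result of the pairwise level-pair census over a design's columns."""

    passed: bool
    violations: tuple[tuple[int, int], ...] = ()

    def __bool__(self) -> bool:
        return self.passed


@dataclass(frozen=True)
class ExperimentPlan:
    """A design matrix with factors bound to its columns.

    ``factor_binding`` maps 1-based column index to a :class:`FactorSpec`;
    by default factor i is bound to column i (A -> 1 ... D -> 4).
    """

    design: DesignMatrix
    factors: tuple[FactorSpec, ...]
    runs_per_condition: int
    factor_binding: Mapping[int, FactorSpec] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.factor_binding is None:
            object.__setattr__(
                self,
                "factor_binding",
                {i + 1: f for i, f in enumerate(self.factors)},
            )
        if set(self.factor_binding) != set(range(1, self.design.n_factors + 1)):
            raise ConfigurationError(
                "factor binding must cover every design column exactly once"
            )

    @property
    def n_conditions(self) -> int:
        return self.design.n_runs

    @property
    def n_planned_runs(self) -> int:
        return self.n_conditions * self.runs_per_condition

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    @property
    def degrees_of_freedom(self) -> int:
        return self.design.n_factors * (N_LEVELS - 1)


def build_l9() -> DesignMatrix:
    """Return the canonical L9(3^4) orthogonal array.

    Every column contains each level three times, and every ordered pair of
    levels occurs exactly once in every pair of columns.
    """
    return DesignMatrix(cells=np.array(L9_ROWS, dtype=int))


def validate_orthogonality(design: DesignMatrix) -> OrthogonalityReport:
    """Census every column pair for the balanced level-pair property.

    A pair of columns passes when each of the 9 ordered level pairs occurs
    exactly ``n_runs / 9`` times.  Returns a report listing every violating
    column pair (1-based indices).
    """
    cells = design.cells
    n_runs, n_cols = cells.shape
    if n_runs % (N_LEVELS**2) != 0:
        raise StructuralError(
            f"{n_runs} runs cannot balance {N_LEVELS**2} ordered level pairs"
        )
    if not ((cells >= 1) & (cells <= N_LEVELS)).all():
        raise StructuralError("level indices must lie in 1..3")
    expected = n_runs // (N_LEVELS**2)
    violations: list[tuple[int, int]] = []
    for i in range(n_cols):
        for j in range(i + 1, n_cols):
            counts = np.zeros((N_LEVELS, N_LEVELS), dtype=int)
            np.add.at(counts, (cells[:, i] - 1, cells[:, j] - 1), 1)
            if not (counts == expected).all():
                violations.append((i + 1, j + 1))
    return OrthogonalityReport(passed=not violations, violations=tuple(violations))


def make_plan(
    factors: Sequence[FactorSpec], runs_per_condition: int = 30
) -> ExperimentPlan:
    """Bind four 3-level factors to the L9 columns positionally."""
    factors = tuple(factors)
    if len(factors) != 4:
        raise ConfigurationError(
            f"the L9(3^4) plan needs exactly 4 factors, got {len(factors)}"
        )
    if runs_per_condition < 1:
        raise ConfigurationError("runs_per_condition must be >= 1")
    return ExperimentPlan(
        design=build_l9(), factors=factors, runs_per_condition=runs_per_condition
    )


def default_factors() -> tuple[FactorSpec, ...]:
    """The four clinical factors of the dialyzer clotting experiment.

    A: heparin anticoagulation dose; B: blood-flow velocity; C: dehydration
    volume; D: vascular access type (categorical).
    """
    return (
        FactorSpec(
            "A",
            "Amount of anticoagulation",
            (FactorLevel(500, "units"), FactorLevel(1000, "units"), FactorLevel(1500, "units")),
        ),
        FactorSpec(
            "B",
            "Velocity of blood flow",
            (FactorLevel(200, "ml/min"), FactorLevel(250, "ml/min"), FactorLevel(300, "ml/min")),
        ),
        FactorSpec(
            "C",
            "Dehydration volume",
            (FactorLevel(1.5, "kg"), FactorLevel(2.5, "kg"), FactorLevel(3.5, "kg")),
        ),
        FactorSpec(
            "D",
            "Vascular access type",
            (
                FactorLevel("artificial blood vessel"),
                FactorLevel("autologous blood vessel"),
                FactorLevel("temporary duct"),
            ),
        ),
    )


def factors_from_config(config: Sequence[Mapping[str, Any]]) -> tuple[FactorSpec, ...]:
    """Build factors from a JSON/YAML-style list of mappings.

    Each entry: ``{"name": ..., "label": ..., "levels": [{"value": ..,
    "unit": ..}, ...]}`` (unit optional per level).
    """
    specs = []
    for entry in config:
        levels = tuple(
            FactorLevel(value=lv["value"], unit=lv.get("unit")) for lv in entry["levels"]
        )
        specs.append(FactorSpec(name=entry["name"], label=entry.get("label", entry["name"]), levels=levels))
    return tuple(specs)


def factors_to_config(factors: Sequence[FactorSpec]) -> list[dict[str, Any]]:
    return [
        {
            "name": f.name,
            "label": f.label,
            "levels": [{"value": lv.value, "unit": lv.unit} for lv in f.levels],
        }
        for f in factors
    ]


def design_to_csv(design: DesignMatrix, path: str | Path) -> None:
    """Write the design as CSV with header ``run,A,B,C,D``."""
    design.to_frame().to_csv(path, index=False)


def design_from_csv(path: str | Path) -> DesignMatrix:
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c != "run"]
    return DesignMatrix(cells=df[cols].to_numpy(dtype=int))
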