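"""Synthetic run outcomes and patient covariates; packaged reference tables.

The generator emulates the structure of the dialyzer clotting experiment:
for each of the 9 orthogonal-array conditions it draws independent
Bernoulli(p) defect outcomes (30 runs per condition by default, 270 rows),
with the default per-condition probabilities equal to the reference study's
empirical rates.  Patient covariates (health and physiological categories)
are sampled independently from the printed category weights; covariates are
generated independently of outcomes — the source study reports them
descriptively and never links them to clotting.

Randomness uses a single explicit seed and a fixed stream order (conditions
in index order, runs in index order within a condition; covariates column by
column), so outputs are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .effect_analysis import ConditionResult
from .errors import ConfigurationError, StructuralError
from .experiment_design import (
    DesignMatrix,
    ExperimentPlan,
    FactorSpec,
    factors_from_config,
)

__all__ = [
    "DEFAULT_DEFECTIVE_COUNTS",
    "ConfirmationResult",
    "OutcomeProfile",
    "CovariateProfile",
    "default_outcome_profile",
    "health_covariates",
    "physiological_covariates",
    "improved_physiological_covariates",
    "generate_runs",
    "generate_patients",
    "load_fixture",
]

#: Reference per-condition defective counts out of 30 runs.
DEFAULT_DEFECTIVE_COUNTS = (7, 6, 10, 10, 16, 9, 11, 12, 5)

#: "Improved" normal-band percentages after adopting the selected combination.
IMPROVED_NORMAL_PERCENT = {
    "bmi": 40.3,
    "serum_calcium": 59.0,
    "hematocrit": 32.2,
    "ferritin": 76.4,
    "transferrin_saturation": 79.0,
}


@dataclass(frozen=True)
class ConfirmationResult:
    """Counts of a confirmation experiment at a fixed combination."""

    combination: str
    defective: int
    good: int
    total: int

    def __post_init__(self) -> None:
        if self.defective + self.good != self.total:
            raise StructuralError("confirmation counts do not add up")

    @property
    def defect_rate(self) -> float:
        return self.defective / self.total


@dataclass(frozen=True)
class OutcomeProfile:
    """Per-condition defect probabilities for the run generator."""

    probabilities: tuple[float, ...]
    runs_per_condition: int = 30

    def __post_init__(self) -> None:
        if any(not 0.0 <= p <= 1.0 for p in self.probabilities):
            raise ConfigurationError(
                f"defect probabilities must lie in [0, 1], got {self.probabilities}"
            )
        if self.runs_per_condition < 1:
            raise ConfigurationError("runs_per_condition must be >= 1")


def default_outcome_profile(runs_per_condition: int = 30) -> OutcomeProfile:
    """Profile whose probabilities are the reference empirical rates."""
    return OutcomeProfile(
        probabilities=tuple(d / 30 for d in DEFAULT_DEFECTIVE_COUNTS),
        runs_per_condition=runs_per_condition,
    )


@dataclass(frozen=True)
class CovariateProfile:
    """Categorical weight tables, one per covariate.

    Weights may be counts (summing to the cohort size) or percentages
    (summing to ~100); only their ratios matter for sampling.
    """

    distributions: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for name, dist in self.distributions.items():
            if not dist:
                raise ConfigurationError(f"covariate {name!r} has no categories")
            if any(w < 0 for w in dist.values()) or sum(dist.values()) <= 0:
                raise ConfigurationError(f"covariate {name!r} has invalid weights")


def _profile_from_table(df: pd.DataFrame, column: str) -> CovariateProfile:
    dists: dict[str, dict[str, float]] = {}
    for name, group in df.groupby("characteristic", sort=False):
        dists[str(name)] = dict(zip(group["category"], group[column].astype(float)))
    return CovariateProfile(distributions=dists)


def health_covariates() -> CovariateProfile:
    """Health-status covariate weights (counts mode), from the packaged table."""
    return _profile_from_table(load_fixture("table5"), "count")


def physiological_covariates(
    mode: Literal["counts", "percent"] = "counts",
) -> CovariateProfile:
    """Physiological covariate weights.

    The printed percentages of the physiological table are inconsistent with
    its printed counts (they do not equal count/270 for several bands);
    counts mode treats the counts as authoritative, percent mode uses the
    printed percentages verbatim.
    """
    column = "count" if mode == "counts" else "percent"
    return _profile_from_table(load_fixture("table6"), column)


def improved_physiological_covariates() -> CovariateProfile:
    """Post-improvement physiological profile (percent mode).

    Only the "normal" band percentage is reported after improvement; the
    remaining mass is split across the other bands in proportion to the
    original printed percentages.
    """
    base = physiological_covariates(mode="percent").distributions
    dists: dict[str, dict[str, float]] = {}
    for name, dist in base.items():
        normal = IMPROVED_NORMAL_PERCENT[name]
        others = {c: w for c, w in dist.items() if c != "normal"}
        scale = (100.0 - normal) / sum(others.values())
        improved = {c: w * scale for c, w in others.items()}
        improved["normal"] = normal
        dists[name] = {c: improved[c] for c in dist}  # preserve category order
    return CovariateProfile(distributions=dists)


# ---------------------------------------------------------------------------
# generators


def generate_runs(
    plan: ExperimentPlan,
    profile: OutcomeProfile | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-run Bernoulli defect outcomes for every plan condition.

    Returns the per-run schema ``run_id, condition, A, B, C, D, outcome``
    consumed by :mod:`hemoqc.effect_analysis` and :mod:`hemoqc.bpn`.
    """
    profile = profile or default_outcome_profile()
    if len(profile.probabilities) != plan.n_conditions:
        raise ConfigurationError(
            f"profile covers {len(profile.probabilities)} conditions, "
            f"plan has {plan.n_conditions}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    run_id = 1
    for cond in range(1, plan.n_conditions + 1):
        levels = plan.design.row(cond)
        p = profile.probabilities[cond - 1]
        draws = rng.random(profile.runs_per_condition) < p
        for defective in draws:
            rows.append(
                {
                    "run_id": run_id,
                    "condition": cond,
                    **dict(zip(plan.factor_names, levels)),
                    "outcome": "defective" if defective else "good",
                }
            )
            run_id += 1
    return pd.DataFrame(rows)


def generate_patients(
    n: int,
    profile: CovariateProfile,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample n patients, each covariate independently from its categories."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {}
    for name, dist in profile.distributions.items():
        cats = np.array(list(dist), dtype=object)
        weights = np.array(list(dist.values()), dtype=float)
        data[name] = rng.choice(cats, size=n, p=weights / weights.sum())
    df = pd.DataFrame(data)
    df.insert(0, "patient_id", np.arange(1, n + 1))
    return df


# ---------------------------------------------------------------------------
# packaged reference tables


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("hemoqc").joinpath("fixtures", f"{name}.csv")))


def load_fixture(name: str):
    """Load a packaged reference table as its typed object.

    ======== ==================================================
    name     returns
    ======== ==================================================
    table2   tuple of :class:`FactorSpec` (factors and levels)
    table3   :class:`DesignMatrix` (the L9(3^4) array)
    table4   list of :class:`ConditionResult` (run outcomes)
    table5   DataFrame of health-status categories
    table6   DataFrame of physiological categories
    table10  :class:`ConfirmationResult` (confirmation counts)
    ======== ==================================================
    """
    known = {"table2", "table3", "table4", "table5", "table6", "table10"}
    if name not in known:
        raise LookupError(f"unknown fixture {name!r}; known: {sorted(known)}")
    df = pd.read_csv(_fixture_path(name))
    if name == "table2":
        config = []
        for factor, group in df.groupby("factor", sort=False):
            levels = []
            for _, row in group.sort_values("level").iterrows():
                raw = row["value"]
                unit = None if pd.isna(row["unit"]) else str(row["unit"])
                try:
                    value = float(raw)
                    value = int(value) if value == int(value) else value
                except ValueError:
                    value = str(raw)
                levels.append({"value": value, "unit": unit})
            label = group["label"].iloc[0]
            config.append({"name": str(factor), "label": label, "levels": levels})
        return factors_from_config(config)
    if name == "table3":
        return DesignMatrix(cells=df[["A", "B", "C", "D"]].to_numpy(dtype=int))
    if name == "table4":
        return [
            ConditionResult(
                condition_id=int(r["condition"]),
                levels=tuple(int(r[c]) for c in "ABCD"),
                defective=int(r["defective"]),
                good=int(r["good"]),
                sample=int(r["sample"]),
            )
            for _, r in df.iterrows()
        ]
    if name == "table10":
        row = df.iloc[0]
        return ConfirmationResult(
            combination=str(row["combination"]),
            defective=int(row["defective"]),
            good=int(row["good"]),
            total=int(row["total"]),
        )
    return df
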