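"""End-to-end orchestration: analyze -> select -> predict -> verify -> confirm.

Runs the whole workflow on per-condition counts or per-run records: effect
accumulation, smaller-the-better level selection, the omega (dB) defect-rate
prediction in both rounding conventions, an optional back-propagation
convergence check on the per-run records, and the confirmation-experiment
arithmetic when confirmation counts are supplied.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from . import bpn, effect_analysis, omega, synthetic_data
from .effect_analysis import ConditionResult, EffectTable, LevelSelection
from .errors import HemoqcError, PipelineStageError
from .experiment_design import ExperimentPlan, make_plan
from .synthetic_data import ConfirmationResult

__all__ = [
    "PipelineConfig",
    "ConfirmationSummary",
    "PipelineReport",
    "run_pipeline",
    "confirmation_percentage",
]

log = logging.getLogger("hemoqc.pipeline")


def confirmation_percentage(defective: int, total: int) -> float:
    """Confirmation defect percentage at 1 decimal, truncated toward zero.

    Truncation (not rounding) matches the printing convention of the source
    tables: 35 defective of 270 is 12.963%, reported as 12.9%.  The full
    precision rate is carried separately in the report.
    """
    if total <= 0 or defective < 0 or defective > total:
        raise PipelineStageError("confirmation", f"bad counts {defective}/{total}")
    return math.floor(defective / total * 1000.0) / 10.0


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    ``input_csv`` may point at a per-condition counts CSV
    (``condition,A,B,C,D,defective,good,sample``) or a per-run CSV
    (``run_id,condition,A,B,C,D,outcome``); when None the packaged reference
    experiment table is used.
    """

    input_csv: str | Path | None = None
    fixture: str = "table4"
    runs_per_condition: int = 30
    rounding_mode: Literal["paper", "full"] = "paper"
    encoding: Literal["proportion", "binary"] = "proportion"
    hidden_units: int = bpn.HIDDEN_UNIT_PRESETS["summation"]
    epochs: int = 500
    seed: int = 0
    run_bpn: bool = True
    confirmation_csv: str | Path | None = None
    confirmation_fixture: str | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ConfirmationSummary:
    defective: int
    total: int
    rate: float
    percent_1dp: float


@dataclass(frozen=True)
class PipelineReport:
    """Everything the workflow computed, JSON-serializable."""

    effects: EffectTable
    selection: LevelSelection
    prediction_paper: omega.OmegaPrediction
    prediction_full: omega.OmegaPrediction
    baseline_rate: float
    baseline_percent_0dp: int
    convergence: bpn.ConvergenceReport | None = None
    confirmation: ConfirmationSummary | None = None

    def to_dict(self) -> dict:
        out = {
            "baseline_rate": self.baseline_rate,
            "baseline_percent_0dp": self.baseline_percent_0dp,
            "selection": {
                "combination": self.selection.label,
                "choices": dict(self.selection.choices),
                "rates": dict(self.selection.rates),
            },
            "effects": self.effects.table.to_dict(orient="records"),
            "prediction_paper": self.prediction_paper.to_dict(),
            "prediction_full": self.prediction_full.to_dict(),
        }
        if self.convergence is not None:
            out["bpn"] = {
                "final_train_mse": self.convergence.final_train_mse,
                "converged": self.convergence.converged,
                "convergence_epoch": self.convergence.convergence_epoch,
                "epochs": self.convergence.epochs,
            }
        if self.confirmation is not None:
            out["confirmation"] = {
                "defective": self.confirmation.defective,
                "total": self.confirmation.total,
                "rate": self.confirmation.rate,
                "percent_1dp": self.confirmation.percent_1dp,
            }
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _load_results(
    config: PipelineConfig, plan: ExperimentPlan
) -> tuple[list[ConditionResult], pd.DataFrame | None]:
    """Return per-condition results plus per-run records when available."""
    if config.input_csv is None:
        results = synthetic_data.load_fixture(config.fixture)
        if not isinstance(results, list):
            raise PipelineStageError(
                "effect_analysis", f"fixture {config.fixture!r} is not an experiment table"
            )
        return results, None
    df = pd.read_csv(config.input_csv)
    if df.empty:
        raise PipelineStageError("effect_analysis", f"input {config.input_csv} is empty")
    if "outcome" in df.columns:
        return effect_analysis.results_from_per_run(df, plan), df
    return effect_analysis.results_from_condition_csv(config.input_csv, plan), None


def _reconstruct_runs(results: Sequence[ConditionResult], plan: ExperimentPlan) -> pd.DataFrame:
    """Expand per-condition counts into per-run rows (defective runs first)."""
    rows = []
    run_id = 1
    for r in sorted(results, key=lambda r: r.condition_id):
        for outcome, count in (("defective", r.defective), ("good", r.good)):
            for _ in range(count):
                rows.append(
                    {
                        "run_id": run_id,
                        "condition": r.condition_id,
                        **dict(zip(plan.factor_names, r.levels)),
                        "outcome": outcome,
                    }
                )
                run_id += 1
    return pd.DataFrame(rows)


def _stage(name: str):
    """Decorator-free stage guard: re-raise hemoqc errors with the stage name."""

    class _Guard:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, HemoqcError) and not isinstance(
                exc, PipelineStageError
            ):
                raise PipelineStageError(name, str(exc)) from exc
            return False

    return _Guard()


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full workflow and assemble a :class:`PipelineReport`.

    Back-propagation non-convergence is reported, not fatal: the workflow's
    feedback loop treats it as a signal to revisit the factor configuration,
    so the report simply carries ``converged=False``.
    """
    plan = make_plan(
        synthetic_data.load_fixture("table2"), runs_per_condition=config.runs_per_condition
    )

    with _stage("effect_analysis"):
        results, runs = _load_results(config, plan)
        effects = effect_analysis.accumulate_effects(plan, results)
    log.info(
        "effect_analysis: %d conditions, overall %d/%d defective",
        len(results), effects.total_defective, effects.total_sample,
    )

    with _stage("selection"):
        selection = effect_analysis.select_optimal_levels(effects, direction="smaller")
    log.info("selection: %s", selection.label)

    with _stage("omega_prediction"):
        pred_paper = omega.predict_combination(effects, selection, rounding_mode="paper")
        pred_full = omega.predict_combination(effects, selection, rounding_mode="full")
    log.info(
        "omega_prediction: %.2f dB -> %.2f%% (paper mode)",
        pred_paper.combined_db, pred_paper.predicted_percent,
    )

    convergence = None
    if config.run_bpn:
        with _stage("bpn"):
            if runs is None:
                runs = _reconstruct_runs(results, plan)
            records = bpn.encode_records(runs, plan, encoding=config.encoding)
            net_config = bpn.NetworkConfig(
                hidden_units=config.hidden_units, epochs=config.epochs, seed=config.seed
            )
            tr, va, te = bpn.split_data(records, net_config.split, seed=config.seed)
            _, convergence = bpn.train(net_config, tr, va, te)
        log.info(
            "bpn: %d records, final train MSE %.6f, converged=%s",
            len(records), convergence.final_train_mse, convergence.converged,
        )

    confirmation = None
    conf: ConfirmationResult | None = None
    if config.confirmation_fixture:
        conf = synthetic_data.load_fixture(config.confirmation_fixture)
    elif config.confirmation_csv:
        row = pd.read_csv(config.confirmation_csv).iloc[0]
        conf = ConfirmationResult(
            combination=str(row.get("combination", selection.label)),
            defective=int(row["defective"]),
            good=int(row["good"]),
            total=int(row["total"]),
        )
    if conf is not None:
        with _stage("confirmation"):
            confirmation = ConfirmationSummary(
                defective=conf.defective,
                total=conf.total,
                rate=conf.defect_rate,
                percent_1dp=confirmation_percentage(conf.defective, conf.total),
            )
        log.info("confirmation: %d/%d -> %.1f%%", conf.defective, conf.total, confirmation.percent_1dp)

    return PipelineReport(
        effects=effects,
        selection=selection,
        prediction_paper=pred_paper,
        prediction_full=pred_full,
        baseline_rate=effects.overall_rate,
        baseline_percent_0dp=round(effects.overall_rate * 100),
        convergence=convergence,
        confirmation=confirmation,
    )
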