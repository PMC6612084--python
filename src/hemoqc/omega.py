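"""Omega transformation: defect rates <-> decibels, and additive prediction.

The omega transform maps a defect proportion P to a decibel value

    Omega(P) = 10 * log10((1 - P) / P)

(a logit scaled to dB).  Level effects that are roughly multiplicative on
the odds scale become additive in dB, so the defect rate of a factor-level
combination is predicted by

    Omega(comb) = sum_i Omega(p_i)  -  (m - 1) * Omega(T)

over the m selected levels, with T the grand defect rate, and mapped back
through the inverse

    P = 1 / (1 + 10**(Omega / 10)).

Two rounding conventions are supported.  ``rounding_mode="full"`` evaluates
the chain at full precision and is the default for new analyses.
``rounding_mode="paper"`` reproduces printed-table arithmetic: each rate is
rounded to 2 decimals before the transform, each dB value to 2 decimals
before combining, and the combined dB to 2 decimals before back-transforming.
The two modes differ in the second decimal of the combined dB value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .effect_analysis import EffectTable, LevelSelection
from .errors import DomainError

__all__ = ["OmegaPrediction", "omega_db", "inverse_omega", "predict_combination"]

RoundingMode = Literal["paper", "full"]


def omega_db(p: float) -> float:
    """Decibel value of a defect proportion; strictly decreasing on (0, 1).

    Raises :class:`DomainError` for p outside the open interval (0, 1) —
    degenerate rates are never silently clamped.
    """
    if not (isinstance(p, (int, float)) and math.isfinite(p)) or not 0.0 < p < 1.0:
        raise DomainError(
            f"defect proportion must lie strictly between 0 and 1, got {p!r}; "
            "for degenerate rates consider the Haldane correction "
            "(continuity=True in predict_combination)"
        )
    return 10.0 * math.log10((1.0 - p) / p)


def inverse_omega(db: float) -> float:
    """Back-transform a dB value to a defect proportion in (0, 1)."""
    if not (isinstance(db, (int, float)) and math.isfinite(db)):
        raise DomainError(f"dB value must be finite, got {db!r}")
    return 1.0 / (1.0 + 10.0 ** (db / 10.0))


@dataclass(frozen=True)
class OmegaPrediction:
    """The full dB chain for a selected factor-level combination."""

    level_rates: dict[str, float]  # rates as fed to the transform
    level_db: dict[str, float]
    overall_rate: float
    overall_db: float
    combined_db: float
    predicted_rate: float
    rounding_mode: RoundingMode

    @property
    def predicted_percent(self) -> float:
        return 100.0 * self.predicted_rate

    def to_dict(self) -> dict:
        return {
            "rounding_mode": self.rounding_mode,
            "level_rates": dict(self.level_rates),
            "level_db": dict(self.level_db),
            "overall_rate": self.overall_rate,
            "overall_db": self.overall_db,
            "combined_db": self.combined_db,
            "predicted_rate": self.predicted_rate,
            "predicted_percent": self.predicted_percent,
        }

    def format_chain(self) -> str:
        """Human-readable dB chain mirroring the printed arithmetic."""
        lines = [
            f"{name}: P = {rate:.2f} -> Omega = {db:.2f} dB"
            for (name, rate), db in zip(self.level_rates.items(), self.level_db.values())
        ]
        lines.append(f"T:  P = {self.overall_rate:.2f} -> Omega = {self.overall_db:.2f} dB")
        m = len(self.level_db)
        chain = " + ".join(f"{db:.2f}" for db in self.level_db.values())
        lines.append(
            f"Omega(comb) = {chain} - {m - 1}*{self.overall_db:.2f} = {self.combined_db:.2f} dB"
        )
        lines.append(f"predicted defect rate = {self.predicted_percent:.2f}%")
        return "\n".join(lines)


def _haldane(defective: int, total: int) -> float:
    return (defective + 0.5) / (total + 1.0)


def predict_combination(
    effects: EffectTable,
    selection: LevelSelection,
    rounding_mode: RoundingMode = "paper",
    continuity: bool = False,
) -> OmegaPrediction:
    """Predict the combination's defect rate from the additive dB chain.

    With ``continuity=True`` every rate is replaced by the Haldane-corrected
    (x + 0.5) / (n + 1) before any rounding, allowing degenerate 0/1 rates;
    by default degenerate rates raise :class:`DomainError`.
    """
    if rounding_mode not in ("paper", "full"):
        raise DomainError(f"unknown rounding mode {rounding_mode!r}")
    missing = set(selection.choices) - set(effects.factor_names)
    if missing or set(effects.factor_names) - set(selection.choices):
        raise DomainError(
            "selection must cover exactly the factors of the effect table"
        )

    def prepare(defective: int, total: int) -> float:
        rate = _haldane(defective, total) if continuity else defective / total
        if rounding_mode == "paper":
            rate = round(rate, 2)
        if not 0.0 < rate < 1.0:
            raise DomainError(
                f"rate {rate} is degenerate after rounding; use rounding_mode='full' "
                "or continuity=True (Haldane correction)"
            )
        return rate

    level_rates: dict[str, float] = {}
    level_db: dict[str, float] = {}
    for factor, level in selection.choices.items():
        d = effects.defective(factor, level)
        n = int(effects._cell(factor, level)["total"])
        rate = prepare(d, n)
        db = omega_db(rate)
        if rounding_mode == "paper":
            db = round(db, 2)
        level_rates[f"{factor}{level}"] = rate
        level_db[f"{factor}{level}"] = db

    overall_rate = prepare(effects.total_defective, effects.total_sample)
    overall_db = omega_db(overall_rate)
    if rounding_mode == "paper":
        overall_db = round(overall_db, 2)

    m = len(selection.choices)
    combined = sum(level_db.values()) - (m - 1) * overall_db
    if rounding_mode == "paper":
        combined = round(combined, 2)
    predicted = inverse_omega(combined)
    return OmegaPrediction(
        level_rates=level_rates,
        level_db=level_db,
        overall_rate=overall_rate,
        overall_db=overall_db,
        combined_db=combined,
        predicted_rate=predicted,
        rounding_mode=rounding_mode,
    )
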