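"""Modified-Delphi factor selection arithmetic.

A panel of experts scores each candidate prioritisation factor on a 9-point
Likert scale along two dimensions: how important the factor is for triage,
and how feasibly it can be measured at referral.  Per factor and dimension
the panel median drives a three-band rule:

* both medians above 7            -> ``selected``
* any median below 4              -> ``eliminated``
* otherwise (4-7 on some axis)    -> ``advance`` to the next round

Rounds stop once every surviving factor shows panel agreement of at least
80%, agreement being the fraction of experts whose score falls in the same
Likert band (1-3 / 4-7 / 8-9) as the factor's median.  The median, not the
mean, is the decisive summary; means are carried along for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DIMENSIONS",
    "DelphiScores",
    "FactorDecision",
    "RoundResult",
    "likert_band",
    "summarize_scores",
    "classify_factor",
    "agreement_rate",
    "run_round",
]

DIMENSIONS = ("importance", "measurement_capability")

SELECT_ABOVE = 7.0     # strict: median must exceed this on both dimensions
ELIMINATE_BELOW = 4.0  # strict: any median under this eliminates
AGREEMENT_THRESHOLD = 0.80


@dataclass(frozen=True)
class DelphiScores:
    """One dimension's expert-by-factor Likert scores for one round."""

    dimension: str
    scores: pd.DataFrame = field(repr=False)  # index: expert_ids, columns: factor_ids

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"dimension must be one of {DIMENSIONS}, got {self.dimension!r}")
        df = self.scores
        if df.empty:
            raise ValueError("scores table is empty")
        if df.isna().any().any():
            cell = df.stack(future_stack=True).index[df.isna().stack(future_stack=True).argmax()]
            raise ValueError(f"missing score for (expert, factor) = {cell}")
        vals = df.to_numpy()
        if ((vals < 1) | (vals > 9)).any():
            raise ValueError("all Likert scores must lie in [1, 9]")
        if df.index.duplicated().any() or df.columns.duplicated().any():
            raise ValueError("expert and factor ids must be unique")

    @property
    def expert_ids(self) -> list:
        return list(self.scores.index)

    @property
    def factor_ids(self) -> list:
        return list(self.scores.columns)


@dataclass(frozen=True)
class FactorDecision:
    factor_id: str
    medians: Mapping[str, float]   # per dimension
    means: Mapping[str, float]     # logged, never decisive
    agreement: float               # min over dimensions, in [0, 1]
    decision: str                  # selected | advance | eliminated
    overridden: bool = False


@dataclass(frozen=True)
class RoundResult:
    round_number: int
    decisions: list[FactorDecision]
    terminated: bool

    def counts(self) -> dict[str, int]:
        out = {"selected": 0, "advance": 0, "eliminated": 0}
        for d in self.decisions:
            out[d.decision] += 1
        return out


def likert_band(score: float) -> str:
    """Band of a score or median: 'low' (<4), 'mid' (4-7), 'high' (>7)."""
    if score < ELIMINATE_BELOW:
        return "low"
    if score <= SELECT_ABOVE:
        return "mid"
    return "high"


def summarize_scores(s: DelphiScores) -> pd.Series:
    """Per-factor median over experts (midpoint convention for even panels)."""
    return s.scores.median(axis=0)


def classify_factor(median_per_dimension: Mapping[str, float]) -> str:
    """Apply the selection bands to a factor's per-dimension medians.

    Elimination is disjunctive (weak on either axis kills the factor);
    selection is conjunctive (strong on both).  Medians sitting exactly on
    a boundary (4 or 7) advance to another round rather than deciding.
    """
    medians = [median_per_dimension[d] for d in DIMENSIONS]
    for m in medians:
        if not 1.0 <= m <= 9.0:
            raise ValueError(f"median {m} outside the Likert range [1, 9]")
    if any(m < ELIMINATE_BELOW for m in medians):
        return "eliminated"
    if all(m > SELECT_ABOVE for m in medians):
        return "selected"
    return "advance"


def agreement_rate(s: DelphiScores, factor_id: str) -> float:
    """Fraction of experts scoring in the same Likert band as the median."""
    if factor_id not in s.scores.columns:
        raise KeyError(f"unknown factor id {factor_id!r}")
    col = s.scores[factor_id]
    band = likert_band(float(col.median()))
    in_band = col.map(lambda x: likert_band(float(x)) == band)
    return float(in_band.mean())


def run_round(
    scores_by_dimension: "Mapping[str, DelphiScores] | Iterable[DelphiScores]",
    round_number: int,
    override_selected: "set[str] | None" = None,
) -> RoundResult:
    """Classify every factor in a round and test the stopping rule.

    ``scores_by_dimension`` supplies one :class:`DelphiScores` per scored
    dimension (both dimensions required).  The round terminates the Delphi
    when every non-eliminated factor reaches agreement >= 0.80 on both
    dimensions.  ``override_selected`` marks factors retained by explicit
    researcher decision regardless of their bands; overrides are recorded,
    never silent.
    """
    if round_number < 1:
        raise ValueError("round_number must be >= 1")
    if not isinstance(scores_by_dimension, Mapping):
        scores_by_dimension = {s.dimension: s for s in scores_by_dimension}
    missing = set(DIMENSIONS) - set(scores_by_dimension)
    if missing:
        raise ValueError(f"scores missing for dimension(s): {sorted(missing)}")
    tables = {d: scores_by_dimension[d] for d in DIMENSIONS}
    factor_sets = {tuple(t.factor_ids) for t in tables.values()}
    if len(factor_sets) != 1:
        raise ValueError("both dimensions must score the same factors")
    factor_ids = factor_sets.pop()
    override_selected = override_selected or set()

    medians = {d: summarize_scores(t) for d, t in tables.items()}
    means = {d: t.scores.mean(axis=0) for d, t in tables.items()}

    decisions = []
    terminated = True
    for f in factor_ids:
        med = {d: float(medians[d][f]) for d in DIMENSIONS}
        decision = classify_factor(med)
        overridden = False
        if f in override_selected and decision != "selected":
            decision, overridden = "selected", True
        agree = min(agreement_rate(tables[d], f) for d in DIMENSIONS)
        decisions.append(
            FactorDecision(
                factor_id=f,
                medians=med,
                means={d: float(means[d][f]) for d in DIMENSIONS},
                agreement=agree,
                decision=decision,
                overridden=overridden,
            )
        )
        if decision != "eliminated" and agree < AGREEMENT_THRESHOLD:
            terminated = False
    return RoundResult(round_number=round_number, decisions=decisions, terminated=terminated)
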