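"""The 100-point priority scoring framework for angiography referrals.

Seven factors, each scored 0-10 by the referring physician, are combined as

    total = scale * sum_i(weight_i * score_i),    scale = 10,

so with weights summing to one the total lives on a 0-100 point scale and
each factor's maximum contribution is ``10 * 10 * weight`` points (22, 18,
15, 15, 12, 10 and 8 under the default weights).  Totals map to three
priority tiers with maximum-wait targets:

    tier 1: >= 80 points, see within 4 weeks
    tier 2: >= 50 points, see within 8 weeks
    tier 3: everyone else, see within 16 weeks

The waiting list is ordered by total points (descending), breaking ties by
the waiting-time factor score, then referral date, then patient id, so the
ranking is a pure function of the roster.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Factor",
    "Tier",
    "FrameworkConfig",
    "PatientRecord",
    "ScoredPatient",
    "RankedWaitlist",
    "DEFAULT_CONFIG_DICT",
    "default_framework",
    "load_framework",
    "compute_total",
    "assign_tier",
    "rank_waitlist",
]


@dataclass(frozen=True)
class Factor:
    factor_id: str
    name: str
    weight: float


@dataclass(frozen=True)
class Tier:
    tier: int
    min_points: float     # inclusive lower bound
    max_wait_weeks: int


#: Packaged default: the seven consensus factors with their panel weights,
#: and the three tiers with wait targets of one, two and up to four months.
DEFAULT_CONFIG_DICT: dict = {
    "factors": [
        {"factor_id": "pain_severity", "name": "Pain severity and clinical symptoms", "weight": 0.22},
        {"factor_id": "stress_test", "name": "Stress test result", "weight": 0.18},
        {"factor_id": "underlying_disease", "name": "Underlying diseases and risk factors", "weight": 0.15},
        {"factor_id": "mi_count", "name": "Number of myocardial infarctions (ejection fraction)", "weight": 0.15},
        {"factor_id": "economic_social", "name": "Decreased economic and social performance", "weight": 0.12},
        {"factor_id": "waiting_time", "name": "Duration of waiting time", "weight": 0.10},
        {"factor_id": "special_circumstances", "name": "Special circumstances", "weight": 0.08},
    ],
    "score_min": 0,
    "score_max": 10,
    "scale": 10,
    "waiting_time_factor": "waiting_time",
    "tiers": [
        {"tier": 1, "min_points": 80, "max_wait_weeks": 4},
        {"tier": 2, "min_points": 50, "max_wait_weeks": 8},
        {"tier": 3, "min_points": 0, "max_wait_weeks": 16},
    ],
}


@dataclass(frozen=True)
class FrameworkConfig:
    """Validated scoring framework: factors, score bounds, tiers."""

    factors: tuple[Factor, ...]
    score_min: int = 0
    score_max: int = 10
    scale: float = 10.0
    waiting_time_factor: "str | None" = "waiting_time"
    tiers: tuple[Tier, ...] = (Tier(1, 80, 4), Tier(2, 50, 8), Tier(3, 0, 16))

    def __post_init__(self) -> None:
        ids = [f.factor_id for f in self.factors]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate factor ids in config")
        total_w = sum(f.weight for f in self.factors)
        if abs(total_w - 1.0) > 1e-9:
            raise ValueError(f"factor weights must sum to 1, got {total_w:.12f}")
        if any(f.weight < 0 for f in self.factors):
            raise ValueError("factor weights must be nonnegative")
        if not self.score_min < self.score_max:
            raise ValueError("score_min must be below score_max")
        mins = [t.min_points for t in self.tiers]
        if any(a <= b for a, b in zip(mins, mins[1:])):
            raise ValueError("tier thresholds must be strictly decreasing")
        if mins[-1] != 0:
            raise ValueError("lowest tier must start at 0 points to cover all totals")
        if self.waiting_time_factor is not None and self.waiting_time_factor not in ids:
            raise ValueError(f"waiting_time_factor {self.waiting_time_factor!r} not among factors")

    @property
    def factor_ids(self) -> tuple[str, ...]:
        return tuple(f.factor_id for f in self.factors)

    @property
    def weights(self) -> np.ndarray:
        return np.array([f.weight for f in self.factors])

    @property
    def max_points(self) -> float:
        return self.scale * self.score_max  # weights sum to 1

    def max_contributions(self) -> dict[str, float]:
        """Per-factor point ceiling: weight * score_max * scale."""
        return {f.factor_id: f.weight * self.score_max * self.scale for f in self.factors}


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    referral_date: dt.date
    factor_scores: Mapping[str, int]


@dataclass(frozen=True)
class ScoredPatient:
    patient_id: str
    referral_date: dt.date
    factor_scores: Mapping[str, int]
    contributions: Mapping[str, float]
    total_points: float
    tier: int
    max_wait_weeks: int


@dataclass(frozen=True)
class RankedWaitlist:
    """Waiting list in service order; ``positions`` run 1..n without gaps."""

    patients: tuple[ScoredPatient, ...]
    positions: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.positions:
            object.__setattr__(self, "positions", tuple(range(1, len(self.patients) + 1)))

    def __iter__(self):
        return iter(self.patients)

    def __len__(self) -> int:
        return len(self.patients)


def default_framework() -> FrameworkConfig:
    """The packaged seven-factor framework."""
    return load_framework(DEFAULT_CONFIG_DICT)


def load_framework(source: "str | Path | Mapping") -> FrameworkConfig:
    """Load and validate a framework config from a JSON file or mapping."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            doc = json.load(fh)
    else:
        doc = dict(source)
    try:
        factors = tuple(
            Factor(str(f["factor_id"]), str(f.get("name", f["factor_id"])), float(f["weight"]))
            for f in doc["factors"]
        )
        tiers = tuple(
            Tier(int(t["tier"]), float(t["min_points"]), int(t["max_wait_weeks"]))
            for t in doc.get("tiers", [dict(tier=1, min_points=80, max_wait_weeks=4),
                                       dict(tier=2, min_points=50, max_wait_weeks=8),
                                       dict(tier=3, min_points=0, max_wait_weeks=16)])
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed framework config: {exc}") from exc
    return FrameworkConfig(
        factors=factors,
        score_min=int(doc.get("score_min", 0)),
        score_max=int(doc.get("score_max", 10)),
        scale=float(doc.get("scale", 10)),
        # fall back to no waiting-time tie-break when the config omits the
        # key and carries no factor of that id (e.g. toy two-factor configs)
        waiting_time_factor=doc["waiting_time_factor"]
        if "waiting_time_factor" in doc
        else ("waiting_time" if any(f.factor_id == "waiting_time" for f in factors) else None),
        tiers=tiers,
    )


def assign_tier(total_points: float, c: FrameworkConfig) -> tuple[int, int]:
    """Map a total to ``(tier, max_wait_weeks)``; lower bounds are inclusive."""
    if not 0 <= total_points <= c.max_points + 1e-9:
        raise ValueError(f"total {total_points} outside [0, {c.max_points}]")
    for t in c.tiers:  # thresholds strictly decreasing, last is 0
        if total_points >= t.min_points:
            return t.tier, t.max_wait_weeks
    raise AssertionError("unreachable: lowest tier covers 0")


def compute_total(p: PatientRecord, c: FrameworkConfig) -> ScoredPatient:
    """Score one patient: weighted factor scores on the 100-point scale."""
    contributions: dict[str, float] = {}
    for f in c.factors:
        if f.factor_id not in p.factor_scores:
            raise ValueError(f"patient {p.patient_id!r}: missing score for factor {f.factor_id!r}")
        s = p.factor_scores[f.factor_id]
        if not c.score_min <= s <= c.score_max:
            raise ValueError(
                f"patient {p.patient_id!r}: score {s} for {f.factor_id!r} "
                f"outside [{c.score_min}, {c.score_max}]"
            )
        contributions[f.factor_id] = float(s) * f.weight * c.scale
    total = float(sum(contributions.values()))
    tier, wait = assign_tier(total, c)
    return ScoredPatient(
        patient_id=p.patient_id,
        referral_date=p.referral_date,
        factor_scores=dict(p.factor_scores),
        contributions=contributions,
        total_points=total,
        tier=tier,
        max_wait_weeks=wait,
    )


def _rank_key(sp: ScoredPatient, c: FrameworkConfig):
    wait_score = sp.factor_scores.get(c.waiting_time_factor, 0) if c.waiting_time_factor else 0
    return (-sp.total_points, -wait_score, sp.referral_date, str(sp.patient_id))


def rank_waitlist(
    patients: "Iterable[PatientRecord] | Sequence[PatientRecord]",
    c: FrameworkConfig,
    as_of_date: "dt.date | None" = None,
) -> RankedWaitlist:
    """Score and order a roster into a deterministic service queue.

    Order: total points descending; ties broken by waiting-time factor
    score descending, then referral date ascending, then patient id.
    ``as_of_date`` is accepted for interface symmetry with rosters exported
    on a given day; scores are taken as given in the records.
    """
    patients = list(patients)
    ids = [p.patient_id for p in patients]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient ids: {dup}")
    scored = [compute_total(p, c) for p in patients]
    scored.sort(key=lambda sp: _rank_key(sp, c))
    return RankedWaitlist(patients=tuple(scored))
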