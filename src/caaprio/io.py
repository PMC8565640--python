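"""Readers and writers for the toolkit's CSV/JSON artifacts.

Conventions: comma-separated UTF-8 with a header row, ISO-8601 dates,
decimal point.  Every CLI run also emits a JSON manifest (tool version,
input digests, config snapshot, seed, timestamp) sufficient to reproduce
the run.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import __version__
from .ahp import ComparisonMatrix, ConsistencyReport, WeightVector, validate_matrix
from .delphi import DIMENSIONS, DelphiScores, FactorDecision
from .scoring import FrameworkConfig, PatientRecord, RankedWaitlist

__all__ = [
    "RunManifest",
    "read_comparison_csv",
    "write_comparison_csv",
    "write_weights",
    "read_delphi_csv",
    "write_delphi_csv",
    "write_decisions_csv",
    "read_roster_csv",
    "write_ranked_csv",
    "write_manifest",
]

_LONG_COLUMNS = {"expert_id", "factor_row", "factor_col", "value"}


@dataclass(frozen=True)
class RunManifest:
    command: str
    seed: "int | None"
    inputs: Mapping[str, str]          # path -> sha256 of contents
    config: Mapping
    version: str = __version__
    timestamp: str = field(default_factory=lambda: dt.datetime.now(dt.timezone.utc).isoformat())


def _sha256(path: "str | Path") -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    path: "str | Path",
    command: str,
    inputs: Iterable["str | Path"] = (),
    config: "Mapping | None" = None,
    seed: "int | None" = None,
) -> RunManifest:
    manifest = RunManifest(
        command=command,
        seed=seed,
        inputs={str(p): _sha256(p) for p in inputs},
        config=dict(config or {}),
    )
    Path(path).write_text(json.dumps(asdict(manifest), indent=2, default=str) + "\n", encoding="utf-8")
    return manifest


def read_comparison_csv(path: "str | Path") -> list[tuple[str, ComparisonMatrix]]:
    """Read pairwise-comparison matrices from CSV.

    Two layouts are accepted:

    * wide — header row = factor ids, one n-row block, a single expert;
    * long — columns ``expert_id, factor_row, factor_col, value`` holding
      the upper (or full) triangle per expert.

    Returns ``[(expert_id, matrix), ...]``; validation is delegated to
    :func:`caaprio.ahp.validate_matrix` and errors carry cell positions.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if _LONG_COLUMNS.issubset(df.columns):
        return _matrices_from_long(df, path)
    factor_ids = [str(c) for c in df.columns]
    if len(df) != len(factor_ids):
        raise ValueError(
            f"{path}: wide matrix must have {len(factor_ids)} rows to match "
            f"its {len(factor_ids)} factor columns, found {len(df)}"
        )
    if df.isna().any().any():
        r = int(df.isna().any(axis=1).idxmax())
        c = df.columns[df.isna().iloc[r].to_numpy().argmax()]
        raise ValueError(f"{path}: missing cell at data row {r + 1}, column {c!r}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    return [(path.stem, validate_matrix(values, factor_ids))]


def _matrices_from_long(df: pd.DataFrame, path: Path) -> list[tuple[str, ComparisonMatrix]]:
    out = []
    for expert, grp in df.groupby("expert_id", sort=True):
        # factor order = order of first appearance, so writers that emit the
        # upper triangle row by row round-trip their factor ordering
        seen: dict[str, None] = {}
        for _, row in grp.iterrows():
            seen.setdefault(str(row["factor_row"]))
            seen.setdefault(str(row["factor_col"]))
        factors = list(seen)
        idx = {f: i for i, f in enumerate(factors)}
        n = len(factors)
        values = [[None] * n for _ in range(n)]
        for i in range(n):
            values[i][i] = 1.0
        for _, row in grp.iterrows():
            i, j = idx[str(row["factor_row"])], idx[str(row["factor_col"])]
            v = float(row["value"])
            values[i][j] = v
            if values[j][i] is None:
                values[j][i] = 1.0 / v
        for i in range(n):
            for j in range(n):
                if values[i][j] is None:
                    raise ValueError(
                        f"{path}: expert {expert!r} missing judgment for "
                        f"({factors[i]!r}, {factors[j]!r})"
                    )
        out.append((str(expert), validate_matrix(values, factors)))
    return out


def write_comparison_csv(path: "str | Path", matrices: Sequence[tuple[str, ComparisonMatrix]]) -> None:
    """Write matrices in the long layout (wide when a single expert)."""
    if len(matrices) == 1:
        expert, m = matrices[0]
        pd.DataFrame(m.values, columns=list(m.factor_ids)).to_csv(path, index=False)
        return
    rows = []
    for expert, m in matrices:
        for i, fi in enumerate(m.factor_ids):
            for j, fj in enumerate(m.factor_ids):
                if j > i:
                    rows.append({"expert_id": expert, "factor_row": fi, "factor_col": fj,
                                 "value": m.values[i, j]})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_weights(
    path: "str | Path", w: WeightVector, report: "ConsistencyReport | None" = None
) -> None:
    """Weights as CSV (factor_id, weight); ``.json`` path writes JSON with the
    consistency report inlined."""
    path = Path(path)
    if path.suffix == ".json":
        doc: dict = {"weights": w.as_dict()}
        if report is not None:
            doc["consistency"] = asdict(report)
        path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
        return
    pd.DataFrame({"factor_id": list(w.factor_ids), "weight": w.weights}).to_csv(path, index=False)
    if report is not None:
        path.with_suffix(".consistency.json").write_text(
            json.dumps(asdict(report), indent=2) + "\n", encoding="utf-8"
        )


def read_delphi_csv(path: "str | Path", round_number: "int | None" = None) -> dict[str, DelphiScores]:
    """Read long-format Delphi scores: (round, expert_id, factor_id, dimension, score).

    Returns one :class:`DelphiScores` per dimension for the requested round
    (default: the highest round present).
    """
    df = pd.read_csv(path)
    required = {"round", "expert_id", "factor_id", "dimension", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    if round_number is None:
        round_number = int(df["round"].max())
    df = df[df["round"] == round_number]
    if df.empty:
        raise ValueError(f"{path}: no rows for round {round_number}")
    out = {}
    for dim, grp in df.groupby("dimension"):
        wide = grp.pivot_table(index="expert_id", columns="factor_id", values="score",
                               aggfunc="first")
        out[str(dim)] = DelphiScores(dimension=str(dim), scores=wide)
    return out


def write_delphi_csv(
    path: "str | Path", scores_by_dimension: Mapping[str, DelphiScores], round_number: int = 1
) -> None:
    rows = []
    for dim in DIMENSIONS:
        s = scores_by_dimension[dim]
        for e in s.expert_ids:
            for f in s.factor_ids:
                rows.append({"round": round_number, "expert_id": e, "factor_id": f,
                             "dimension": dim, "score": int(s.scores.at[e, f])})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_decisions_csv(path: "str | Path", decisions: Sequence[FactorDecision]) -> None:
    rows = [
        {
            "factor_id": d.factor_id,
            "median_importance": d.medians["importance"],
            "median_measurability": d.medians["measurement_capability"],
            "mean_importance": d.means["importance"],
            "mean_measurability": d.means["measurement_capability"],
            "agreement_rate": d.agreement,
            "decision": d.decision,
            "overridden": d.overridden,
        }
        for d in decisions
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_roster_csv(path: "str | Path", config: FrameworkConfig) -> list[PatientRecord]:
    """Read a patient roster: patient_id, referral_date, one column per factor."""
    df = pd.read_csv(path)
    missing = {"patient_id", "referral_date", *config.factor_ids} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                referral_date=dt.date.fromisoformat(str(row["referral_date"])),
                factor_scores={f: int(row[f]) for f in config.factor_ids},
            )
        )
    return records


def write_ranked_csv(path: "str | Path", ranked: RankedWaitlist, config: FrameworkConfig) -> None:
    """Ranked waitlist as CSV: per-factor points, total, tier, wait target, rank."""
    rows = []
    for pos, sp in zip(ranked.positions, ranked.patients):
        row: dict = {"rank": pos, "patient_id": sp.patient_id,
                     "referral_date": sp.referral_date.isoformat()}
        for f in config.factor_ids:
            row[f"{f}_score"] = sp.factor_scores[f]
            row[f"{f}_points"] = round(sp.contributions[f], 4)
        row["total_points"] = round(sp.total_points, 4)
        row["tier"] = sp.tier
        row["max_wait_weeks"] = sp.max_wait_weeks
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
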