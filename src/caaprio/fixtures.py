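"""Synthetic study-data generators for demos and tests.

The study deposited no raw expert data, so these generators emulate its
three input kinds: (1) reciprocal pairwise-comparison matrices jittered
around a common set of true weights with controllable judgment noise,
(2) two-dimension Delphi Likert tables with per-factor consensus locations,
and (3) patient rosters sharing a latent-severity structure (the same model
the simulator uses for its arrival stream).
"""

from __future__ import annotations

import datetime as dt
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ahp import ComparisonMatrix, WeightVector, validate_matrix
from .delphi import DIMENSIONS, DelphiScores
from .scoring import FrameworkConfig, PatientRecord, default_framework

__all__ = [
    "jittered_comparison_matrices",
    "delphi_panel_scores",
    "synthetic_roster",
]


def jittered_comparison_matrices(
    true_weights: WeightVector,
    n_experts: int = 10,
    sigma: float = 0.15,
    rng: Optional[np.random.Generator] = None,
) -> list[ComparisonMatrix]:
    """Expert matrices around the consistent matrix of ``true_weights``.

    Each upper-triangle judgment is the true ratio ``w_i/w_j`` perturbed by
    lognormal noise ``exp(N(0, sigma^2))``; the lower triangle mirrors the
    reciprocal, so every matrix is valid.  ``sigma`` = 0.15 keeps typical
    consistency ratios comfortably below the 0.10 acceptance bar, mimicking
    a screened expert panel.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    w = np.asarray(true_weights.weights)
    n = len(w)
    base = np.outer(w, 1.0 / w)
    out = []
    for _ in range(n_experts):
        noise = np.exp(rng.normal(0.0, sigma, size=(n, n)))
        a = np.ones((n, n))
        iu = np.triu_indices(n, 1)
        a[iu] = base[iu] * noise[iu]
        a[(iu[1], iu[0])] = 1.0 / a[iu]
        out.append(validate_matrix(a, true_weights.factor_ids))
    return out


def delphi_panel_scores(
    factor_locations: "dict[str, dict[str, float]]",
    n_experts: int = 15,
    spread: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, DelphiScores]:
    """Likert score tables around per-factor consensus locations.

    ``factor_locations`` maps factor id -> {dimension: true location in
    [1, 9]}.  Expert scores are the location plus Gaussian noise, rounded
    and clipped to the 9-point scale; ``spread`` ~ 1 gives the tight
    agreement (>80% in-band) typical of a converging panel.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    experts = [f"E{i + 1:02d}" for i in range(n_experts)]
    factors = list(factor_locations)
    out = {}
    for dim in DIMENSIONS:
        cols = {}
        for f in factors:
            loc = factor_locations[f][dim]
            cols[f] = np.clip(np.rint(rng.normal(loc, spread, size=n_experts)), 1, 9).astype(int)
        out[dim] = DelphiScores(dimension=dim, scores=pd.DataFrame(cols, index=experts))
    return out


def synthetic_roster(
    n_patients: int = 20,
    config: Optional[FrameworkConfig] = None,
    severity_a: float = 2.0,
    severity_b: float = 3.0,
    start_date: dt.date = dt.date(2021, 1, 4),
    rng: Optional[np.random.Generator] = None,
) -> list[PatientRecord]:
    """A referral roster with latent-severity-correlated factor scores.

    Clinical/social scores are Binomial(score_max, u) given each patient's
    latent severity u ~ Beta(a, b); the waiting-time factor score reflects
    days already waited, spread uniformly over the preceding 16 weeks.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if config is None:
        config = default_framework()
    wt = config.waiting_time_factor
    records = []
    for i in range(n_patients):
        u = rng.beta(severity_a, severity_b)
        scores = {
            f: int(rng.binomial(config.score_max, u)) for f in config.factor_ids if f != wt
        }
        weeks_back = int(rng.integers(0, 17))
        if wt is not None:
            scores[wt] = min(config.score_max, int(10 * weeks_back / 16))
        records.append(
            PatientRecord(
                patient_id=f"PT{i + 1:04d}",
                referral_date=start_date - dt.timedelta(weeks=weeks_back),
                factor_scores=scores,
            )
        )
    return records
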