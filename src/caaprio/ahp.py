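"""Analytic hierarchy process: weights from pairwise-comparison matrices.

Experts compare prioritisation factors two at a time on the Saaty 1-9 ratio
scale (1 = equally important, 9 = extremely more important, reciprocals for
the reverse direction).  The priority weight of each factor is the
L1-normalised principal right eigenvector of the resulting reciprocal
matrix, and the consistency ratio (CR) measures how far the judgments
deviate from perfect transitivity; CR < 0.10 is conventionally acceptable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ComparisonMatrix",
    "WeightVector",
    "ConsistencyReport",
    "MatrixValidationError",
    "ConvergenceError",
    "RANDOM_INDEX",
    "CR_THRESHOLD",
    "validate_matrix",
    "derive_weights",
    "consistency_ratio",
    "aggregate_experts",
    "consistent_matrix_from_weights",
]

#: Saaty's random index: mean consistency index of random reciprocal
#: matrices, by matrix order.  CR = CI / RI.
RANDOM_INDEX = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12,
    6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49,
}

#: Conventional acceptability threshold for the consistency ratio.
CR_THRESHOLD = 0.10

_RECIPROCITY_RTOL = 1e-9


class MatrixValidationError(ValueError):
    """A pairwise-comparison table violates a structural invariant."""


class ConvergenceError(RuntimeError):
    """Power iteration failed to converge within the iteration cap."""


@dataclass(frozen=True)
class ComparisonMatrix:
    """One expert's (or an aggregated panel's) reciprocal judgment matrix.

    ``values[i, j]`` is how many times factor ``i`` is preferred over
    factor ``j``; the matrix satisfies ``values[j, i] == 1/values[i, j]``
    and has a unit diagonal.  Construct via :func:`validate_matrix`.
    """

    factor_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.factor_ids)

    def permuted(self, order: "list[int] | np.ndarray") -> "ComparisonMatrix":
        """Reorder factors; judgments move with their factors."""
        order = np.asarray(order)
        ids = tuple(self.factor_ids[i] for i in order)
        return ComparisonMatrix(ids, self.values[np.ix_(order, order)])


@dataclass(frozen=True)
class WeightVector:
    """Normalised priority weights, aligned with ``factor_ids``."""

    factor_ids: tuple[str, ...]
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or len(w) != len(self.factor_ids):
            raise ValueError("weights must align one-to-one with factor_ids")
        if np.any(w < -1e-12):
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {w.sum():.12f}")
        object.__setattr__(self, "weights", w)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.factor_ids, self.weights.tolist()))


@dataclass(frozen=True)
class ConsistencyReport:
    """Saaty consistency diagnostics for one comparison matrix."""

    n: int
    lambda_max: float
    consistency_index: float
    random_index: float
    consistency_ratio: float
    acceptable: bool


def validate_matrix(raw, factor_ids) -> ComparisonMatrix:
    """Validate a square ratio table and wrap it as a :class:`ComparisonMatrix`.

    Checks squareness, positivity, unit diagonal and reciprocity
    (``a_ji == 1/a_ij`` to relative tolerance 1e-9).  Violations raise
    :class:`MatrixValidationError` naming the offending cell; nothing is
    silently repaired.
    """
    factor_ids = tuple(str(f) for f in factor_ids)
    n = len(factor_ids)
    if n < 2:
        raise MatrixValidationError("need at least 2 factors")
    if len(set(factor_ids)) != n:
        raise MatrixValidationError("factor_ids must be unique")
    a = np.asarray(raw, dtype=float)
    if a.ndim != 2 or a.shape != (n, n):
        raise MatrixValidationError(
            f"expected a {n}x{n} table matching factor_ids, got shape {a.shape}"
        )
    if not np.all(np.isfinite(a)):
        i, j = np.argwhere(~np.isfinite(a))[0]
        raise MatrixValidationError(f"non-finite entry at cell ({i}, {j})")
    if np.any(a <= 0):
        i, j = np.argwhere(a <= 0)[0]
        raise MatrixValidationError(
            f"non-positive entry {a[i, j]!r} at cell ({i}, {j}); "
            "ratio judgments must be > 0"
        )
    diag = np.diag(a)
    if not np.allclose(diag, 1.0, rtol=0, atol=1e-12):
        i = int(np.argmax(np.abs(diag - 1.0)))
        raise MatrixValidationError(f"diagonal entry at ({i}, {i}) is {diag[i]!r}, must be 1")
    recip_err = np.abs(a * a.T - 1.0)
    if np.any(recip_err > _RECIPROCITY_RTOL * 3):
        # report the lower-triangle cell, matching how judgments are entered
        i, j = max(map(tuple, np.argwhere(recip_err > _RECIPROCITY_RTOL * 3)))
        raise MatrixValidationError(
            f"reciprocity violated at cell ({i}, {j}): "
            f"{a[i, j]!r} is not the reciprocal of {a[j, i]!r}"
        )
    return ComparisonMatrix(factor_ids, a)


def _power_iterate(a: np.ndarray, tol: float = 1e-12, max_iter: int = 10_000):
    """Principal right eigenvector of a positive matrix, L1-normalised.

    By Perron-Frobenius the dominant eigenvalue of a positive matrix is
    real, simple, and has a positive eigenvector, so plain power iteration
    converges.  Returns ``(weights, lambda_max)``.
    """
    n = a.shape[0]
    w = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        aw = a @ w
        w_new = aw / aw.sum()
        if np.max(np.abs(w_new - w)) < tol:
            aw = a @ w_new
            return w_new, float(aw.sum())  # sum(A w) = lambda when sum(w) = 1
        w = w_new
    raise ConvergenceError(f"power iteration did not converge in {max_iter} iterations")


def _report(lambda_max: float, n: int) -> ConsistencyReport:
    if n <= 2:
        ci, cr = 0.0, 0.0
    else:
        ci = (lambda_max - n) / (n - 1)
        try:
            ri = RANDOM_INDEX[n]
        except KeyError:
            raise ValueError(f"no random-index value tabulated for order {n}") from None
        cr = ci / ri
    ri = RANDOM_INDEX.get(n, float("nan"))
    # clamp tiny negative round-off so reports honour CI, CR >= 0
    ci = max(ci, 0.0)
    cr = max(cr, 0.0)
    return ConsistencyReport(
        n=n,
        lambda_max=lambda_max,
        consistency_index=ci,
        random_index=ri,
        consistency_ratio=cr,
        acceptable=cr < CR_THRESHOLD,
    )


def derive_weights(
    m: ComparisonMatrix, tol: float = 1e-12, max_iter: int = 10_000
) -> tuple[WeightVector, ConsistencyReport]:
    """Derive priority weights and consistency diagnostics from a matrix.

    Weights are the L1-normalised principal eigenvector obtained by power
    iteration (normalising every step, stopping when successive vectors
    differ by less than ``tol`` in the max norm).
    """
    w, lam = _power_iterate(m.values, tol=tol, max_iter=max_iter)
    return WeightVector(m.factor_ids, w), _report(lam, m.n)


def consistency_ratio(m: ComparisonMatrix) -> ConsistencyReport:
    """Consistency diagnostics only: CI = (lambda_max - n)/(n - 1), CR = CI/RI."""
    _, report = derive_weights(m)
    return report


def aggregate_experts(matrices: "list[ComparisonMatrix]") -> ComparisonMatrix:
    """Aggregate individual judgments by element-wise geometric mean.

    The geometric mean is the only aggregation of reciprocal matrices that
    yields a reciprocal matrix, so the panel matrix is valid by
    construction.  All matrices must share the same factors in the same
    order.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    ids = matrices[0].factor_ids
    for k, m in enumerate(matrices[1:], start=2):
        if m.factor_ids != ids:
            raise ValueError(
                f"matrix {k} has factors {m.factor_ids}, expected {ids}"
            )
    logs = np.mean([np.log(m.values) for m in matrices], axis=0)
    gm = np.exp(logs)
    # rebuild from the upper triangle: exact unit diagonal and reciprocity
    # despite float log-exp round-off
    n = len(ids)
    agg = np.eye(n)
    iu = np.triu_indices(n, 1)
    agg[iu] = gm[iu]
    agg[(iu[1], iu[0])] = 1.0 / gm[iu]
    return validate_matrix(agg, ids)


def consistent_matrix_from_weights(w: WeightVector) -> ComparisonMatrix:
    """Build the perfectly consistent matrix a_ij = w_i / w_j.

    Round-tripping through :func:`derive_weights` recovers ``w`` (up to
    float tolerance) with a consistency ratio of zero.
    """
    weights = np.asarray(w.weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("all weights must be strictly positive")
    return validate_matrix(np.outer(weights, 1.0 / weights), w.factor_ids)
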