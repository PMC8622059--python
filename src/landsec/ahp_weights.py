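"""Hierarchical pairwise-comparison weighting.

Implements the classic priority-derivation chain: positive reciprocal
judgment matrices on the 1-9 scale, principal-eigenvector weight
extraction by power iteration, the consistency index/ratio test against
the standard random-index table, and two-level aggregation of local
(within-group) weights into a global weight vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .errors import (
    ConsistencyError,
    NumericError,
    SaatyScaleWarning,
    SchemaError,
    UnsupportedOrderError,
    ValidationError,
)

__all__ = [
    "RI_TABLE",
    "CR_THRESHOLD",
    "JudgmentMatrix",
    "WeightVector",
    "ConsistencyReport",
    "judgment_from_weights",
    "principal_eigen",
    "geometric_mean_weights",
    "consistency",
    "hierarchical_weights",
]

#: Random consistency index RI(n) for matrix orders 1..10 (Saaty's values).
RI_TABLE: dict[int, float] = {
    1: 0.0,
    2: 0.0,
    3: 0.58,
    4: 0.90,
    5: 1.12,
    6: 1.24,
    7: 1.32,
    8: 1.41,
    9: 1.45,
    10: 1.49,
}

#: Conventional acceptability bound for the consistency ratio.
CR_THRESHOLD = 0.1

_RECIPROCITY_TOL = 1e-9


@dataclass(frozen=True)
class JudgmentMatrix:
    """Positive reciprocal pairwise-comparison matrix.

    Invariants checked on construction: square shape matching ``labels``,
    strictly positive entries, unit diagonal, and reciprocity
    ``a[j, i] == 1 / a[i, j]`` within 1e-9.  Entries outside the 1/9..9
    elicitation scale raise a :class:`SaatyScaleWarning` (perturbed
    synthetic matrices may legitimately exceed the scale).
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        labels = tuple(self.labels)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)
        n = len(labels)
        if len(set(labels)) != n:
            raise SchemaError("judgment matrix labels must be unique")
        if values.shape != (n, n):
            raise SchemaError(
                f"judgment matrix shape {values.shape} does not match "
                f"{n} labels"
            )
        if n == 0:
            raise ValidationError("judgment matrix cannot be empty")
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise ValidationError("judgment matrix entries must be positive and finite")
        if np.any(np.diag(values) != 1.0):
            raise ValidationError("judgment matrix diagonal must be exactly 1")
        recip_err = np.max(np.abs(values * values.T - 1.0))
        if recip_err > _RECIPROCITY_TOL:
            raise ValidationError(
                f"judgment matrix is not reciprocal (max |a_ij*a_ji - 1| = {recip_err:.3e})"
            )
        if np.any(values < 1 / 9 - 1e-12) or np.any(values > 9 + 1e-12):
            warnings.warn(
                "judgment matrix entries fall outside the 1/9..9 scale",
                SaatyScaleWarning,
                stacklevel=2,
            )

    @property
    def order(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class WeightVector:
    """Non-negative weights over labelled criteria, summing to 1."""

    labels: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self):
        labels = tuple(self.labels)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "weights", weights)
        if weights.shape != (len(labels),):
            raise SchemaError("weight vector length does not match labels")
        if len(set(labels)) != len(labels):
            raise SchemaError("weight vector labels must be unique")
        if np.any(weights < 0):
            raise ValidationError("weights must be non-negative")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"weights must sum to 1 (got {weights.sum():.12f})"
            )

    def __getitem__(self, label: str) -> float:
        try:
            return float(self.weights[self.labels.index(label)])
        except ValueError:
            raise KeyError(label) from None

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, map(float, self.weights)))

    def subset(self, labels: list[str]) -> "WeightVector":
        """Renormalized restriction to ``labels`` (local weights of a group)."""
        idx = [self.labels.index(lbl) for lbl in labels]
        w = self.weights[idx]
        if w.sum() == 0:
            raise ValidationError("cannot renormalize an all-zero subset")
        return WeightVector(tuple(labels), w / w.sum())


@dataclass(frozen=True)
class ConsistencyReport:
    """Outcome of the CI/CR consistency test for one judgment matrix."""

    order: int
    lambda_max: float
    ci: float
    ri: float
    cr: float
    consistent: bool
    threshold: float = CR_THRESHOLD


def judgment_from_weights(
    weights: WeightVector,
    perturbation: float = 0.0,
    seed: int | None = None,
) -> JudgmentMatrix:
    """Build a reciprocal matrix of weight ratios, optionally perturbed.

    Entries are ``a_ij = (w_i / w_j) * exp(eps_ij)`` with ``eps_ij``
    antisymmetric Gaussian log-noise of scale ``perturbation`` (zero noise
    gives a perfectly consistent matrix with CR = 0).  Reciprocity is exact
    by construction.
    """
    if perturbation < 0:
        raise ValidationError("perturbation must be non-negative")
    w = weights.weights
    if np.any(w == 0):
        raise ValidationError("cannot form pairwise ratios from zero weights")
    n = len(w)
    ratios = np.outer(w, 1.0 / w)
    if perturbation > 0:
        rng = np.random.default_rng(seed)
        eps = rng.normal(0.0, perturbation, size=(n, n))
        eps = np.triu(eps, k=1)
        eps = eps - eps.T  # antisymmetric => exact reciprocity
        ratios = ratios * np.exp(eps)
    np.fill_diagonal(ratios, 1.0)
    # wash out round-off so a_ij * a_ji == 1 exactly
    iu = np.triu_indices(n, k=1)
    ratios[(iu[1], iu[0])] = 1.0 / ratios[iu]
    with warnings.catch_warnings():
        if perturbation > 0:
            warnings.simplefilter("ignore", SaatyScaleWarning)
        return JudgmentMatrix(weights.labels, ratios)


def principal_eigen(
    matrix: JudgmentMatrix,
    tol: float = 1e-12,
    max_iter: int = 10000,
) -> tuple[WeightVector, float]:
    """Principal eigenvector and eigenvalue by power iteration.

    The weight vector is the Perron eigenvector normalized to sum 1;
    ``lambda_max`` is the Rayleigh quotient at convergence.  Deterministic
    given ``tol`` and ``max_iter``.

    Raises
    ------
    NumericError
        If the infinity-norm residual ``||Av - lambda v||`` has not dropped
        below ``tol`` within ``max_iter`` iterations.
    """
    a = matrix.values
    n = matrix.order
    v = np.full(n, 1.0 / n)
    lam = float("nan")
    for _ in range(max_iter):
        av = a @ v
        lam = float(v @ av / (v @ v))
        residual = float(np.max(np.abs(av - lam * v)))
        v_next = av / av.sum()
        if residual <= tol:
            return WeightVector(matrix.labels, v_next), lam
        v = v_next
    residual = float(np.max(np.abs(a @ v - lam * v)))
    raise NumericError(
        f"power iteration did not converge in {max_iter} iterations "
        f"(residual {residual:.3e} > tol {tol:.3e})"
    )


def geometric_mean_weights(matrix: JudgmentMatrix) -> WeightVector:
    """Row-geometric-mean weight extraction (logarithmic least squares)."""
    g = np.exp(np.mean(np.log(matrix.values), axis=1))
    return WeightVector(matrix.labels, g / g.sum())


def consistency(
    matrix: JudgmentMatrix,
    ri_table: Mapping[int, float] | None = None,
) -> ConsistencyReport:
    """CI/CR consistency test.

    ``CI = (lambda_max - n) / (n - 1)`` for n >= 2 and 0 for n <= 1;
    ``CR = CI / RI(n)`` for n >= 3 and is defined as 0 for n <= 2 (orders
    1 and 2 are always consistent).  ``consistent`` is ``CR < 0.1``.
    """
    table = dict(RI_TABLE if ri_table is None else ri_table)
    n = matrix.order
    if n not in table:
        raise UnsupportedOrderError(
            f"no random index for order {n}; supply ri_table to extend"
        )
    _, lam = principal_eigen(matrix)
    if n <= 2:
        ci, cr = 0.0, 0.0
    else:
        ci = (lam - n) / (n - 1)
        cr = ci / table[n]
    return ConsistencyReport(
        order=n,
        lambda_max=lam,
        ci=ci,
        ri=table[n],
        cr=cr,
        consistent=(n <= 2) or (cr < CR_THRESHOLD),
    )


def hierarchical_weights(
    top: JudgmentMatrix,
    groups: Mapping[str, JudgmentMatrix],
    force: bool = False,
    extractor: Callable[[JudgmentMatrix], tuple[WeightVector, float]] | None = None,
) -> tuple[WeightVector, WeightVector]:
    """Aggregate a top-level and per-group matrices into global weights.

    The global weight of sub-criterion ``j`` in group ``g`` is
    ``mainWeight(g) * localWeight(j | g)``; the returned global vector
    therefore sums to 1 exactly when each level's weights do.

    Every matrix must pass the CR < 0.1 test unless ``force`` is set; a
    failing matrix raises :class:`ConsistencyError` carrying its
    :class:`ConsistencyReport`.
    """
    if set(groups) != set(top.labels):
        raise SchemaError(
            f"group matrices {sorted(groups)} do not match top labels {sorted(top.labels)}"
        )
    extract = extractor or principal_eigen
    for name, m in [("top", top)] + [(g, groups[g]) for g in top.labels]:
        report = consistency(m)
        if not report.consistent and not force:
            raise ConsistencyError(
                f"judgment matrix {name!r} fails the consistency test "
                f"(CR = {report.cr:.4f} >= {report.threshold})",
                report=report,
            )
    main, _ = extract(top)
    labels: list[str] = []
    global_w: list[float] = []
    for g, mg in zip(top.labels, main.weights):
        local, _ = extract(groups[g])
        labels.extend(local.labels)
        global_w.extend(mg * local.weights)
    w = np.asarray(global_w)
    return main, WeightVector(tuple(labels), w / w.sum())
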