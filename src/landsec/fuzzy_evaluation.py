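"""Fuzzy comprehensive evaluation primitives.

Normalized indicator values are mapped to degrees of membership across an
ordered assessment set using triangular membership functions; the
per-indicator membership rows form a row-stochastic single-factor matrix
that is synthesized with a weight vector through the ordinary
weighted-average (matrix product) operator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ahp_weights import WeightVector
from .errors import SchemaError, ValidationError
from .indicator_model import AssessmentSet

__all__ = [
    "MembershipMatrix",
    "FuzzyResult",
    "triangular_membership",
    "build_membership_matrix",
    "membership_from_votes",
    "synthesize",
    "classify",
]

_ROW_TOL = 1e-9


@dataclass(frozen=True)
class MembershipMatrix:
    """Row-stochastic factors-by-levels membership matrix."""

    labels: tuple[str, ...]
    level_labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "level_labels", tuple(self.level_labels))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.labels), len(self.level_labels)):
            raise SchemaError(
                f"membership matrix shape {values.shape} does not match "
                f"{len(self.labels)} factors x {len(self.level_labels)} levels"
            )
        if np.any(values < 0):
            raise ValidationError("membership degrees must be non-negative")
        row_sums = values.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > _ROW_TOL):
            bad = self.labels[int(np.argmax(np.abs(row_sums - 1.0)))]
            raise ValidationError(f"membership row {bad!r} does not sum to 1")


@dataclass(frozen=True)
class FuzzyResult:
    membership: np.ndarray
    scalar_score: float
    level: str


def triangular_membership(x: float, anchors: AssessmentSet) -> np.ndarray:
    """Membership degrees of a normalized value across all levels.

    Each level's membership rises linearly from the neighboring lower
    anchor to 1 at its own anchor and falls to 0 at the neighboring upper
    anchor; the two boundary levels are half-triangles clamped at the
    scale ends (membership stays 1 at and beyond the terminal anchor).
    The vector is renormalized to sum exactly 1 and is aligned with
    ``anchors.levels``.
    """
    x = float(x)
    if not 0.0 <= x <= 1.0:
        raise ValidationError(f"normalized value {x} outside [0, 1]")
    a = np.asarray(anchors.anchors, dtype=float)
    order = np.argsort(a)  # positions sorted by anchor, ascending
    sorted_a = a[order]
    m = len(sorted_a)
    memb_sorted = np.zeros(m)
    for k in range(m):
        lo = sorted_a[k - 1] if k > 0 else None
        mid = sorted_a[k]
        hi = sorted_a[k + 1] if k < m - 1 else None
        if lo is None:  # lowest level: clamped on the left
            if x <= mid:
                memb_sorted[k] = 1.0
            elif x < hi:
                memb_sorted[k] = (hi - x) / (hi - mid)
        elif hi is None:  # highest level: clamped on the right
            if x >= mid:
                memb_sorted[k] = 1.0
            elif x > lo:
                memb_sorted[k] = (x - lo) / (mid - lo)
        else:
            if lo < x <= mid:
                memb_sorted[k] = (x - lo) / (mid - lo)
            elif mid < x < hi:
                memb_sorted[k] = (hi - x) / (hi - mid)
    total = memb_sorted.sum()
    if total == 0:  # cannot happen with clamped boundaries; guard anyway
        raise ValidationError(f"value {x} has zero membership at every level")
    memb_sorted /= total
    out = np.zeros(m)
    out[order] = memb_sorted
    return out


def build_membership_matrix(
    values: Sequence[float],
    anchors: AssessmentSet,
    labels: Sequence[str] | None = None,
) -> MembershipMatrix:
    """Stack per-factor membership rows into a single-factor matrix."""
    values = list(values)
    if labels is None:
        labels = [f"F{i + 1}" for i in range(len(values))]
    if len(labels) != len(values):
        raise SchemaError("labels do not match the number of factors")
    rows = []
    for label, value in zip(labels, values):
        try:
            rows.append(triangular_membership(value, anchors))
        except ValidationError as exc:
            raise ValidationError(f"{label}: {exc}") from exc
    return MembershipMatrix(tuple(labels), anchors.levels, np.vstack(rows))


def membership_from_votes(
    votes: np.ndarray,
    level_labels: Sequence[str],
    labels: Sequence[str] | None = None,
) -> MembershipMatrix:
    """Expert-vote construction: each row is its vote counts' proportions."""
    votes = np.asarray(votes, dtype=float)
    if votes.ndim != 2:
        raise SchemaError("votes must be a 2-D factors-by-levels array")
    if np.any(votes < 0):
        raise ValidationError("vote counts must be non-negative")
    totals = votes.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValidationError("every factor needs at least one vote")
    if labels is None:
        labels = [f"F{i + 1}" for i in range(votes.shape[0])]
    return MembershipMatrix(tuple(labels), tuple(level_labels), votes / totals)


def synthesize(
    weights: WeightVector,
    matrix: MembershipMatrix,
    anchors: AssessmentSet,
    level_scores: Sequence[float] | None = None,
) -> FuzzyResult:
    """Weighted-average synthesis ``X = W @ R`` plus scalar scoring.

    ``level_scores`` default to the anchors, so the scalar score is the
    membership-weighted mean anchor; the level is assigned by
    :func:`classify` on the synthesized vector.
    """
    if weights.labels != matrix.labels:
        raise SchemaError(
            "weight labels do not match membership matrix rows: "
            f"{weights.labels} vs {matrix.labels}"
        )
    scores = np.asarray(
        anchors.anchors if level_scores is None else level_scores, dtype=float
    )
    if scores.shape != (len(anchors),):
        raise SchemaError("level_scores must provide one score per level")
    x = weights.weights @ matrix.values
    scalar = float(x @ scores)
    return FuzzyResult(membership=x, scalar_score=scalar, level=classify(x, anchors))


def classify(membership: np.ndarray, anchors: AssessmentSet) -> str:
    """Maximum-membership level; ties break toward the less safe level."""
    membership = np.asarray(membership, dtype=float)
    if membership.shape != (len(anchors),):
        raise SchemaError("membership length does not match the assessment set")
    if np.any(membership < 0):
        raise ValidationError("membership degrees must be non-negative")
    if np.all(membership == 0):
        raise ValidationError("cannot classify an all-zero membership vector")
    best = membership.max()
    tied = [i for i, v in enumerate(membership) if v == best]
    # less safe == smaller anchor under the default (descending) orientation
    idx = min(tied, key=lambda i: anchors.anchors[i])
    return anchors.levels[idx]
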