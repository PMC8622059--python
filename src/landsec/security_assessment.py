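"""Pipeline orchestration: per-year security values, levels and trends.

Two scoring modes are supported and both preserve additivity of the three
group values to the comprehensive value:

* ``scalar`` (default, matches the published per-year table): the group
  value is the weighted sum of its normalized indicators under the global
  weights, and the comprehensive value is the sum of the group values;
* ``fuzzy``: each group's membership vector is synthesized from its local
  weights, the group value is the group weight mass times the group's
  scalar score, and group memberships are mass-combined into the
  comprehensive membership.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .ahp_weights import WeightVector
from .errors import SchemaError, ValidationError
from .fuzzy_evaluation import build_membership_matrix, classify, synthesize
from .indicator_model import (
    AssessmentSet,
    EvaluationResult,
    IndicatorPanel,
    IndicatorRegistry,
    NormalizedPanel,
)
from .normalization import NormalizationConfig, percent_change

__all__ = [
    "PipelineConfig",
    "evaluate_year",
    "evaluate_panel",
    "land_use_change_report",
    "trend_report",
]

logger = logging.getLogger(__name__)

WEIGHT_SOURCES = ("fixture_table2", "ahp_from_matrices")
SCORE_MODES = ("scalar", "fuzzy")

#: Default scalar-mode level cutoffs (level -> minimum comprehensive value);
#: anything below the last cutoff falls to the final (least safe) level.
DEFAULT_SCALAR_THRESHOLDS = (("S", 0.75), ("RS", 0.60), ("RU", 0.45))


@dataclass(frozen=True)
class PipelineConfig:
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    assessment: AssessmentSet = field(default_factory=AssessmentSet)
    weights_source: str = "fixture_table2"
    score_mode: str = "scalar"
    scalar_thresholds: tuple[tuple[str, float], ...] = DEFAULT_SCALAR_THRESHOLDS
    level_scores: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.weights_source not in WEIGHT_SOURCES:
            raise ValidationError(
                f"weights_source must be one of {WEIGHT_SOURCES}, got {self.weights_source!r}"
            )
        if self.score_mode not in SCORE_MODES:
            raise ValidationError(
                f"score_mode must be one of {SCORE_MODES}, got {self.score_mode!r}"
            )
        cuts = [t for _, t in self.scalar_thresholds]
        if list(cuts) != sorted(cuts, reverse=True) or len(set(cuts)) != len(cuts):
            raise ValidationError("scalar thresholds must be strictly decreasing")
        known = set(self.assessment.levels)
        for label, _ in self.scalar_thresholds:
            if label not in known:
                raise ValidationError(f"threshold level {label!r} not in assessment set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        norm = NormalizationConfig(**data.get("normalization", {}))
        assess_raw = data.get("assessment", {})
        assessment = AssessmentSet(
            levels=tuple(assess_raw.get("levels", AssessmentSet().levels)),
            anchors=tuple(assess_raw.get("anchors", AssessmentSet().anchors)),
        )
        thresholds = tuple(
            (str(label), float(cut))
            for label, cut in data.get("scalar_thresholds", DEFAULT_SCALAR_THRESHOLDS)
        )
        scores = data.get("level_scores")
        cfg = cls(
            normalization=norm,
            assessment=assessment,
            weights_source=data.get("weights_source", "fixture_table2"),
            score_mode=data.get("score_mode", "scalar"),
            scalar_thresholds=thresholds,
            level_scores=tuple(scores) if scores else None,
        )
        logger.info("pipeline config loaded from %s: %s", path, cfg)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "normalization": {
                "positive_mode": self.normalization.positive_mode,
                "negative_mode": self.normalization.negative_mode,
            },
            "assessment": {
                "levels": list(self.assessment.levels),
                "anchors": list(self.assessment.anchors),
            },
            "weights_source": self.weights_source,
            "score_mode": self.score_mode,
            "scalar_thresholds": [[label, cut] for label, cut in self.scalar_thresholds],
        }
        if self.level_scores is not None:
            data["level_scores"] = list(self.level_scores)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


def _classify_scalar(score: float, config: PipelineConfig) -> str:
    for label, cut in config.scalar_thresholds:
        if score >= cut:
            return label
    # fall through to the least safe level of the assessment set
    anchors = config.assessment.anchors
    return config.assessment.levels[int(np.argmin(anchors))]


def evaluate_year(
    normalized_row: pd.Series,
    global_weights: WeightVector,
    registry: IndicatorRegistry,
    config: PipelineConfig | None = None,
    year: int | None = None,
) -> EvaluationResult:
    """Evaluate one year's normalized indicator row.

    Group values are ``sum_i w_i x_i`` over the group's indicators (scalar
    mode) or the group weight mass times the group's synthesized scalar
    score (fuzzy mode); the comprehensive value is their sum in either
    mode.  Membership vectors are computed for both modes.
    """
    config = config or PipelineConfig()
    if list(normalized_row.index) != list(global_weights.labels):
        raise SchemaError("normalized row labels do not match the weight labels")
    if list(global_weights.labels) != registry.ids:
        raise SchemaError("weight labels do not match the registry")
    if year is None:
        year = int(normalized_row.name) if normalized_row.name is not None else 0

    anchors = config.assessment
    scores = np.asarray(
        anchors.anchors if config.level_scores is None else config.level_scores,
        dtype=float,
    )
    x = normalized_row.to_numpy(dtype=float)
    w = global_weights.weights

    group_values: dict[str, float] = {}
    membership: dict[str, np.ndarray] = {}
    comp_membership = np.zeros(len(anchors))
    for group in registry.groups:
        ids = registry.group_ids(group)
        idx = [registry.ids.index(i) for i in ids]
        w_g, x_g = w[idx], x[idx]
        mass = float(w_g.sum())
        local = WeightVector(tuple(ids), w_g / mass)
        r_g = build_membership_matrix(x_g, anchors, labels=ids)
        fuzzy_g = synthesize(local, r_g, anchors, scores)
        membership[group] = fuzzy_g.membership
        comp_membership += mass * fuzzy_g.membership
        if config.score_mode == "scalar":
            group_values[group] = float(w_g @ x_g)
        else:
            group_values[group] = mass * fuzzy_g.scalar_score
    membership["comprehensive"] = comp_membership / comp_membership.sum()
    comprehensive = float(sum(group_values.values()))

    if config.score_mode == "scalar":
        level = _classify_scalar(comprehensive, config)
    else:
        level = classify(membership["comprehensive"], anchors)
    return EvaluationResult(
        year=year,
        group_values=group_values,
        comprehensive_value=comprehensive,
        level=level,
        membership=membership,
    )


def evaluate_panel(
    panel: NormalizedPanel,
    weights: WeightVector,
    registry: IndicatorRegistry,
    config: PipelineConfig | None = None,
) -> list[EvaluationResult]:
    """Evaluate every year of a normalized panel, ordered by year."""
    config = config or PipelineConfig()
    if list(panel.values.columns) != list(weights.labels):
        raise SchemaError("panel columns do not match the weight labels")
    return [
        evaluate_year(panel.values.loc[year], weights, registry, config, year=year)
        for year in panel.years
    ]


def land_use_change_report(
    panel: IndicatorPanel | NormalizedPanel,
    categories: Sequence[str],
    year_a: int,
    year_b: int,
) -> pd.DataFrame:
    """Signed percent change per category between two years.

    Ratio normalization cancels in the change ratio, so raw and
    ratio-normalized panels give identical numbers.  Rows are sorted by
    absolute change, largest first.
    """
    rows = []
    for cat in categories:
        series = panel.series(cat)
        rows.append(
            {"indicator": cat, "percent_change": percent_change(series, year_a, year_b)}
        )
    df = pd.DataFrame(rows)
    return (
        df.reindex(df["percent_change"].abs().sort_values(ascending=False).index)
        .reset_index(drop=True)
    )


def _segments(years: list[int], values: np.ndarray) -> list[dict]:
    """Maximal monotone runs of a series as (start, end, direction)."""
    segs: list[dict] = []
    start = 0
    direction = 0
    for i in range(1, len(values)):
        step = int(np.sign(values[i] - values[i - 1]))
        if direction == 0:
            direction = step
        elif step != 0 and step != direction:
            segs.append(
                {
                    "start": years[start],
                    "end": years[i - 1],
                    "direction": "rising" if direction >= 0 else "falling",
                }
            )
            start, direction = i - 1, step
    segs.append(
        {
            "start": years[start],
            "end": years[-1],
            "direction": "rising" if direction >= 0 else "falling",
        }
    )
    return segs


def trend_report(results: Sequence[EvaluationResult]) -> dict:
    """Per-series trend summary over the evaluated years.

    For the comprehensive value and each group value: year-over-year
    deltas, the peak (argmax) year, a monotone-segment decomposition, and
    a ``declines_after_peak`` flag for series whose value falls after the
    peak year.
    """
    if len(results) < 2:
        raise ValidationError("trend report requires at least two years")
    results = sorted(results, key=lambda r: r.year)
    years = [r.year for r in results]
    series = {"comprehensive": np.array([r.comprehensive_value for r in results])}
    for group in results[0].group_values:
        series[group] = np.array([r.group_values[group] for r in results])
    report: dict = {"years": years, "series": {}}
    for name, values in series.items():
        deltas = {
            years[i]: float(values[i] - values[i - 1]) for i in range(1, len(years))
        }
        peak_idx = int(np.argmax(values))
        report["series"][name] = {
            "deltas": deltas,
            "peak_year": years[peak_idx],
            "peak_value": float(values[peak_idx]),
            "segments": _segments(years, values),
            "declines_after_peak": bool(
                peak_idx < len(years) - 1
                and values[peak_idx + 1 :].min() < values[peak_idx]
            ),
        }
    return report
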