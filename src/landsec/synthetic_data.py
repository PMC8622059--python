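"""Synthetic panels and judgment matrices with known ground truth.

Each indicator follows deterministic compound growth with optional
multiplicative log-normal noise: ``value(t) = initial * (1 + growth)^t *
exp(eps_t)`` with ``t`` counting years from the first (t = 0) and
``eps_t ~ Normal(0, sd^2)``.  Multiplicative noise keeps every value
strictly positive, so ratio normalization is always well defined.  All
randomness flows through one ``numpy`` generator seeded by a single
integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ahp_weights import (
    JudgmentMatrix,
    WeightVector,
    judgment_from_weights,
)
from .errors import ValidationError
from .indicator_model import (
    IndicatorPanel,
    IndicatorRegistry,
    default_registry,
    fixture_global_weights,
    fixture_main_weights,
)
from .security_assessment import PipelineConfig

__all__ = [
    "IndicatorTrend",
    "PanelSpec",
    "StudyBundle",
    "generate_panel",
    "generate_judgments",
    "generate_study_like_bundle",
    "default_trends",
]


@dataclass(frozen=True)
class IndicatorTrend:
    """Ground-truth generator parameters for one indicator column."""

    initial: float
    growth: float = 0.0  # signed annual fraction
    noise_sd: float = 0.0  # log-scale standard deviation

    def __post_init__(self):
        if self.initial <= 0:
            raise ValidationError("initial level must be strictly positive")
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be non-negative")
        if self.growth <= -1:
            raise ValidationError("growth must exceed -1 to keep values positive")


@dataclass(frozen=True)
class PanelSpec:
    years: Sequence[int]
    trends: Mapping[str, IndicatorTrend]
    seed: int = 0

    def __post_init__(self):
        years = list(self.years)
        object.__setattr__(self, "years", tuple(years))
        if len(years) < 2:
            raise ValidationError("a panel spec needs at least two years")
        if years != sorted(set(years)):
            raise ValidationError("years must be strictly increasing")


def generate_panel(spec: PanelSpec, registry: IndicatorRegistry) -> IndicatorPanel:
    """Simulate a raw panel; deterministic for a given seed."""
    missing = [i for i in registry.ids if i not in spec.trends]
    if missing:
        raise ValidationError(f"spec lacks trends for indicator(s): {', '.join(missing)}")
    rng = np.random.default_rng(spec.seed)
    t = np.arange(len(spec.years), dtype=float)
    data = {}
    for indicator_id in registry.ids:  # fixed iteration order => reproducible draws
        trend = spec.trends[indicator_id]
        values = trend.initial * (1.0 + trend.growth) ** t
        if trend.noise_sd > 0:
            values = values * np.exp(rng.normal(0.0, trend.noise_sd, size=len(t)))
        data[indicator_id] = values
    return IndicatorPanel(pd.DataFrame(data, index=list(spec.years)))


def generate_judgments(
    weights: WeightVector, perturbation: float = 0.0, seed: int | None = None
) -> JudgmentMatrix:
    """Reciprocal pairwise matrix of weight ratios with optional log-noise."""
    return judgment_from_weights(weights, perturbation=perturbation, seed=seed)


#: Annual growth fractions mirroring the study's qualitative directions:
#: construction/mining land and per-capita development indicators grow,
#: pastureland and other agricultural land shrink, territory area is fixed.
_DEFAULT_GROWTH = {
    "S11": -0.0005,
    "S12": 0.0075,
    "S13": 0.004,
    "S14": 0.002,
    "S15": -0.0138,
    "S16": -0.006,
    "S21": 0.0174,
    "S22": 0.0171,
    "S23": 0.042,
    "S24": 0.001,
    "S25": 0.13,
    "S26": 0.029,
    "S31": 0.0,
    "S32": 0.127,
    "S33": 0.026,
    "S34": 0.016,
    "S35": -0.007,
}

_DEFAULT_INITIAL = {
    "S11": 657_000.0,
    "S12": 130_000.0,
    "S13": 11_000.0,
    "S14": 235_000.0,
    "S15": 263_000.0,
    "S16": 25_000.0,
    "S21": 24_000.0,
    "S22": 17_000.0,
    "S23": 2_300.0,
    "S24": 3_600.0,
    "S25": 1_900.0,
    "S26": 480.0,
    "S31": 96_000.0,
    "S32": 12_000.0,
    "S33": 41.8,
    "S34": 370.0,
    "S35": 5.9,
}


def default_trends(
    registry: IndicatorRegistry | None = None, noise_sd: float = 0.01
) -> dict[str, IndicatorTrend]:
    registry = registry or default_registry()
    trends = {}
    for indicator_id in registry.ids:
        growth = _DEFAULT_GROWTH.get(indicator_id, 0.01)
        sd = 0.0 if growth == 0.0 else noise_sd  # keep the constant column exact
        trends[indicator_id] = IndicatorTrend(
            initial=_DEFAULT_INITIAL.get(indicator_id, 100.0),
            growth=growth,
            noise_sd=sd,
        )
    return trends


@dataclass(frozen=True)
class StudyBundle:
    panel: IndicatorPanel
    top_matrix: JudgmentMatrix
    group_matrices: dict[str, JudgmentMatrix]
    config: PipelineConfig
    registry: IndicatorRegistry = field(default_factory=default_registry)


def generate_study_like_bundle(
    seed: int = 0,
    years: Sequence[int] = tuple(range(2004, 2018)),
    noise_sd: float = 0.01,
) -> StudyBundle:
    """A full end-to-end input set shaped like the original 14-year study.

    The panel follows the default trends (growing non-agricultural land,
    declining pastureland, constant territory area) with multiplicative
    noise; the judgment matrices are perfectly consistent ratio matrices
    built from the published main and within-group weights.
    """
    registry = default_registry()
    spec = PanelSpec(years=years, trends=default_trends(registry, noise_sd), seed=seed)
    panel = generate_panel(spec, registry)
    main = fixture_main_weights()
    top = judgment_from_weights(main)
    global_w = fixture_global_weights()
    group_matrices = {
        group: judgment_from_weights(global_w.subset(registry.group_ids(group)))
        for group in registry.groups
    }
    return StudyBundle(
        panel=panel,
        top_matrix=top,
        group_matrices=group_matrices,
        config=PipelineConfig(),
        registry=registry,
    )
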