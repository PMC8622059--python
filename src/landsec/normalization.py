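"""Dimensionless normalization of indicator panels and change statistics.

Both orientations use ratio transforms, so every output lies in (0, 1]
and the result is invariant to rescaling a column by a positive constant:

* large-is-better indicators: ``x / max(x)`` (best year maps to 1);
* small-is-better indicators: either ``x / max(x)`` (default, preserves
  year ordering) or ``min(x) / x`` (flips orientation so the best —
  smallest — year maps to 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .indicator_model import (
    IndicatorPanel,
    IndicatorRegistry,
    NormalizedPanel,
    Polarity,
)

__all__ = [
    "POSITIVE_MODES",
    "NEGATIVE_MODES",
    "NormalizationConfig",
    "normalize_positive",
    "normalize_negative",
    "normalize_panel",
    "percent_change",
]

POSITIVE_MODES = ("ratio_to_max",)
NEGATIVE_MODES = ("ratio_to_max", "inverse_min_over_x")


@dataclass(frozen=True)
class NormalizationConfig:
    positive_mode: str = "ratio_to_max"
    negative_mode: str = "ratio_to_max"

    def __post_init__(self):
        if self.positive_mode not in POSITIVE_MODES:
            raise ValidationError(
                f"positive_mode must be one of {POSITIVE_MODES}, got {self.positive_mode!r}"
            )
        if self.negative_mode not in NEGATIVE_MODES:
            raise ValidationError(
                f"negative_mode must be one of {NEGATIVE_MODES}, got {self.negative_mode!r}"
            )


def _check_series(values: np.ndarray) -> None:
    if values.size == 0:
        raise ValidationError("cannot normalize an empty series")
    if not np.all(np.isfinite(values)) or np.any(values <= 0):
        raise ValidationError("series values must be strictly positive and finite")


def normalize_positive(series):
    """Scale a large-is-better series by its maximum: ``x / max(x)``."""
    values = np.asarray(series, dtype=float)
    _check_series(values)
    out = values / values.max()
    if isinstance(series, pd.Series):
        return pd.Series(out, index=series.index, name=series.name)
    return out


def normalize_negative(series, mode: str = "ratio_to_max"):
    """Normalize a small-is-better series.

    ``ratio_to_max`` applies ``x / max(x)`` (same transform as the
    positive branch, preserving year ordering); ``inverse_min_over_x``
    applies ``min(x) / x`` so that the smallest — best — value maps to 1.
    """
    if mode not in NEGATIVE_MODES:
        raise ValidationError(f"unknown negative mode {mode!r}")
    values = np.asarray(series, dtype=float)
    _check_series(values)
    if mode == "ratio_to_max":
        out = values / values.max()
    else:
        out = values.min() / values
    if isinstance(series, pd.Series):
        return pd.Series(out, index=series.index, name=series.name)
    return out


def normalize_panel(
    panel: IndicatorPanel,
    registry: IndicatorRegistry,
    config: NormalizationConfig | None = None,
) -> NormalizedPanel:
    """Column-wise normalization of a raw panel by indicator polarity."""
    config = config or NormalizationConfig()
    if list(panel.values.columns) != registry.ids:
        raise ValidationError("panel columns do not match the registry")
    out = {}
    for definition in registry.definitions:
        col = panel.values[definition.id]
        try:
            if definition.polarity is Polarity.POSITIVE:
                out[definition.id] = normalize_positive(col)
            else:
                out[definition.id] = normalize_negative(col, config.negative_mode)
        except ValidationError as exc:
            raise ValidationError(f"{definition.id}: {exc}") from exc
    return NormalizedPanel(pd.DataFrame(out, index=panel.values.index))


def percent_change(series: pd.Series, year_a: int, year_b: int) -> float:
    """Signed percent change ``(v_b / v_a - 1) * 100`` between two years.

    Invariant under any common positive rescaling of the series, so raw
    and ratio-normalized columns give identical results.
    """
    for year in (year_a, year_b):
        if year not in series.index:
            raise KeyError(f"year {year} not present in series")
    v_a = float(series.loc[year_a])
    v_b = float(series.loc[year_b])
    if v_a == 0:
        raise ValidationError("base-year value is zero; percent change undefined")
    return (v_b / v_a - 1.0) * 100.0
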