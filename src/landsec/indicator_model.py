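"""Domain types, the default indicator registry, and file readers/writers.

The registry describes 17 sub-indicators partitioned into three groups:
resource/environment sustainability (S1, 6 indicators), economic
sustainability (S2, 6) and social sustainability (S3, 5).  Panels hold
years-by-indicator magnitudes; fixtures ship the published normalized
panel, the published weight table and the published per-year results at
their printed 4-decimal precision.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .ahp_weights import JudgmentMatrix, WeightVector
from .errors import ConsistencyError, SchemaError, ValidationError

__all__ = [
    "Polarity",
    "Group",
    "IndicatorDefinition",
    "IndicatorRegistry",
    "IndicatorPanel",
    "NormalizedPanel",
    "AssessmentSet",
    "EvaluationResult",
    "default_registry",
    "default_assessment_set",
    "load_fixture",
    "fixture_global_weights",
    "fixture_main_weights",
    "read_panel",
    "write_panel",
    "read_registry",
    "write_registry",
    "read_judgment_matrix",
    "write_judgment_matrix",
    "read_results",
    "write_results",
]

RESULT_COLUMNS = ["year", "comprehensive_value", "S1", "S2", "S3", "level"]


class Polarity(str, enum.Enum):
    """Orientation of an indicator on the security scale.

    ``positive`` — larger raw values are better (large-value category);
    ``negative`` — smaller raw values are better (small-value category).
    """

    POSITIVE = "positive"
    NEGATIVE = "negative"


class Group(str, enum.Enum):
    S1 = "S1"  # resources & environment sustainability
    S2 = "S2"  # economic sustainability
    S3 = "S3"  # social sustainability


@dataclass(frozen=True)
class IndicatorDefinition:
    id: str
    name: str
    unit: str
    polarity: Polarity
    group: Group

    def __post_init__(self):
        object.__setattr__(self, "polarity", Polarity(self.polarity))
        object.__setattr__(self, "group", Group(self.group))
        if not self.id:
            raise ValidationError("indicator id cannot be empty")


@dataclass(frozen=True)
class IndicatorRegistry:
    """Ordered collection of indicator definitions with group labels."""

    definitions: tuple[IndicatorDefinition, ...]
    group_labels: Mapping[str, str] = field(
        default_factory=lambda: {g.value: g.value for g in Group}
    )

    def __post_init__(self):
        object.__setattr__(self, "definitions", tuple(self.definitions))
        ids = [d.id for d in self.definitions]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate indicator ids in registry")

    @property
    def ids(self) -> list[str]:
        return [d.id for d in self.definitions]

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for d in self.definitions:
            if d.group.value not in seen:
                seen.append(d.group.value)
        return seen

    def __len__(self) -> int:
        return len(self.definitions)

    def __getitem__(self, indicator_id: str) -> IndicatorDefinition:
        for d in self.definitions:
            if d.id == indicator_id:
                return d
        raise KeyError(indicator_id)

    def group_ids(self, group: str | Group) -> list[str]:
        g = Group(group)
        return [d.id for d in self.definitions if d.group is g]


def _fixture_path(name: str):
    return resources.files("landsec._fixtures").joinpath(name)


def _table2_frame() -> pd.DataFrame:
    with resources.as_file(_fixture_path("table2_weights.csv")) as p:
        return pd.read_csv(p)


def default_registry() -> IndicatorRegistry:
    """The 17-indicator registry shipped with the package (6+6+5)."""
    t2 = _table2_frame()
    defs = tuple(
        IndicatorDefinition(
            id=row.id,
            name=row.name_,
            unit=row.unit,
            polarity=Polarity(row.polarity),
            group=Group(row.group),
        )
        for row in t2.rename(columns={"name": "name_"}).itertuples(index=False)
    )
    labels = dict(zip(t2["group"], t2["group_name"]))
    return IndicatorRegistry(defs, labels)


@dataclass(frozen=True)
class IndicatorPanel:
    """Raw indicator magnitudes: rows are years, columns are indicator ids."""

    values: pd.DataFrame  # index = years (int), columns = indicator ids

    def __post_init__(self):
        df = self.values.copy()
        df.index = df.index.astype(int)
        object.__setattr__(self, "values", df)
        years = list(df.index)
        if len(years) == 0:
            raise ValidationError("panel must contain at least one year")
        if len(set(years)) != len(years):
            raise SchemaError("duplicate years in panel")
        if years != sorted(years):
            raise SchemaError("years must be strictly increasing")
        arr = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("panel contains missing or non-finite values")
        if np.any(arr <= 0):
            bad = df.columns[(arr <= 0).any(axis=0)][0]
            raise ValidationError(
                f"panel values must be strictly positive (offending column: {bad})"
            )

    @property
    def years(self) -> list[int]:
        return list(self.values.index)

    @property
    def indicator_ids(self) -> list[str]:
        return list(self.values.columns)

    def series(self, indicator_id: str) -> pd.Series:
        if indicator_id not in self.values.columns:
            raise KeyError(indicator_id)
        return self.values[indicator_id]


@dataclass(frozen=True)
class NormalizedPanel:
    """Dimensionless panel with every value in (0, 1]."""

    values: pd.DataFrame

    def __post_init__(self):
        df = self.values.copy()
        df.index = df.index.astype(int)
        object.__setattr__(self, "values", df)
        years = list(df.index)
        if len(set(years)) != len(years) or years != sorted(years):
            raise SchemaError("years must be strictly increasing and unique")
        arr = df.to_numpy(dtype=float)
        if np.any(arr <= 0) or np.any(arr > 1 + 1e-12):
            raise ValidationError("normalized values must lie in (0, 1]")

    @property
    def years(self) -> list[int]:
        return list(self.values.index)

    @property
    def indicator_ids(self) -> list[str]:
        return list(self.values.columns)

    def series(self, indicator_id: str) -> pd.Series:
        if indicator_id not in self.values.columns:
            raise KeyError(indicator_id)
        return self.values[indicator_id]

    def row(self, year: int) -> pd.Series:
        if year not in self.values.index:
            raise KeyError(year)
        return self.values.loc[year]


@dataclass(frozen=True)
class AssessmentSet:
    """Ordered assessment levels with one anchor value each.

    Levels run from safest to least safe; anchors sit on the normalized
    scale and must be strictly monotone.  The default four-level set is
    S > RS > RU > U with anchors 1.0, 0.75, 0.5, 0.25.
    """

    levels: tuple[str, ...] = ("S", "RS", "RU", "U")
    anchors: tuple[float, ...] = (1.0, 0.75, 0.5, 0.25)

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple(self.levels))
        object.__setattr__(self, "anchors", tuple(float(a) for a in self.anchors))
        if len(self.levels) != len(self.anchors):
            raise SchemaError("one anchor is required per level")
        if len(self.levels) < 2:
            raise ValidationError("at least two assessment levels are required")
        diffs = np.diff(self.anchors)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValidationError("anchors must be strictly monotone")

    def __len__(self) -> int:
        return len(self.levels)

    def safety_rank(self, level: str) -> int:
        """0 = safest.  Lower anchor means less safe under the default set."""
        return self.levels.index(level)


def default_assessment_set() -> AssessmentSet:
    return AssessmentSet()


@dataclass(frozen=True)
class EvaluationResult:
    """Per-year outcome: group values, comprehensive value, level.

    ``membership`` maps each group id plus ``"comprehensive"`` to a
    level-membership vector (aligned with the assessment set); it is
    ``None`` for results read back from disk, where only scalars survive.
    """

    year: int
    group_values: dict[str, float]
    comprehensive_value: float
    level: str
    membership: dict[str, np.ndarray] | None = None


# ---------------------------------------------------------------------------
# readers / writers


def read_panel(
    path: str | Path,
    registry: IndicatorRegistry,
    interpolate_missing: bool = False,
) -> IndicatorPanel:
    """Read a raw panel CSV (year column + one column per registry id).

    Columns are reordered to the registry order.  Unknown columns are
    rejected.  Missing cells are an error unless ``interpolate_missing``
    is set, in which case interior gaps are filled by linear interpolation
    between neighboring years.
    """
    df = pd.read_csv(path)
    if "year" not in df.columns:
        raise SchemaError("panel CSV must contain a 'year' column")
    missing = [i for i in registry.ids if i not in df.columns]
    if missing:
        raise SchemaError(f"panel CSV is missing indicator column(s): {', '.join(missing)}")
    unknown = [c for c in df.columns if c != "year" and c not in registry.ids]
    if unknown:
        raise SchemaError(f"panel CSV has unknown column(s): {', '.join(unknown)}")
    if df["year"].duplicated().any():
        dup = int(df.loc[df["year"].duplicated(), "year"].iloc[0])
        raise SchemaError(f"duplicate year in panel CSV: {dup}")
    df = df.sort_values("year").set_index("year")[registry.ids]
    for col in df.columns:
        series = pd.to_numeric(df[col], errors="coerce")
        bad = series.index[series.isna() & df[col].notna()]
        if len(bad):
            raise ValidationError(
                f"non-numeric value in column {col}, year {int(bad[0])}"
            )
        df[col] = series
    if df.isna().any().any():
        if interpolate_missing:
            df = df.interpolate(method="index", limit_area="inside")
        if df.isna().any().any():
            col = df.columns[df.isna().any()][0]
            year = int(df.index[df[col].isna()][0])
            raise ValidationError(f"missing value in column {col}, year {year}")
    nonpos = df.le(0)
    if nonpos.any().any():
        col = df.columns[nonpos.any()][0]
        year = int(df.index[df[col] <= 0][0])
        raise ValidationError(
            f"non-positive value in column {col}, year {year} (raw values must be > 0)"
        )
    return IndicatorPanel(df)


def write_panel(panel: IndicatorPanel | NormalizedPanel, path: str | Path) -> None:
    """Write a panel CSV with 4-decimal cells (round-trip stable)."""
    out = panel.values.copy()
    out.insert(0, "year", out.index)
    out.to_csv(path, index=False, float_format="%.4f")


def read_registry(path: str | Path) -> IndicatorRegistry:
    """Read a registry from JSON or YAML."""
    text = Path(path).read_text(encoding="utf-8")
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    defs = tuple(
        IndicatorDefinition(
            id=d["id"],
            name=d.get("name", d["id"]),
            unit=d.get("unit", ""),
            polarity=Polarity(d["polarity"]),
            group=Group(d["group"]),
        )
        for d in data["indicators"]
    )
    labels = data.get("group_labels") or {g.value: g.value for g in Group}
    return IndicatorRegistry(defs, labels)


def write_registry(registry: IndicatorRegistry, path: str | Path) -> None:
    data = {
        "group_labels": dict(registry.group_labels),
        "indicators": [
            {
                "id": d.id,
                "name": d.name,
                "unit": d.unit,
                "polarity": d.polarity.value,
                "group": d.group.value,
            }
            for d in registry.definitions
        ],
    }
    text = (
        json.dumps(data, indent=2)
        if str(path).endswith(".json")
        else yaml.safe_dump(data, sort_keys=False)
    )
    Path(path).write_text(text, encoding="utf-8")


def read_judgment_matrix(
    path: str | Path, auto_complete: bool = False
) -> JudgmentMatrix:
    """Read a judgment matrix from square CSV or JSON ``{labels, rows}``.

    With ``auto_complete`` the strict lower triangle may be left blank
    (NaN) and is filled with reciprocals of the upper triangle.
    """
    if str(path).endswith(".json"):
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        labels = tuple(data["labels"])
        values = np.asarray(data["rows"], dtype=float)
    else:
        df = pd.read_csv(path, index_col=0)
        labels = tuple(str(c) for c in df.columns)
        if tuple(str(i) for i in df.index) != labels:
            raise SchemaError("judgment matrix CSV row labels must match column labels")
        values = df.to_numpy(dtype=float)
    if auto_complete:
        n = len(labels)
        for i in range(n):
            for j in range(i):
                if np.isnan(values[i, j]):
                    values[i, j] = 1.0 / values[j, i]
        np.fill_diagonal(values, 1.0)
    if np.isnan(values).any():
        raise ValidationError("judgment matrix contains missing entries")
    return JudgmentMatrix(labels, values)


def write_judgment_matrix(matrix: JudgmentMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels)
    df.to_csv(path)


def write_results(results: Sequence[EvaluationResult], path: str | Path) -> None:
    """Write per-year results to CSV (published-table schema, 4 decimals)."""
    if not results:
        raise ValidationError("cannot write an empty result list")
    years = [r.year for r in results]
    if len(set(years)) != len(years):
        raise ConsistencyError("duplicate years in results")
    rows = []
    for r in sorted(results, key=lambda r: r.year):
        rows.append(
            {
                "year": r.year,
                "comprehensive_value": round(r.comprehensive_value, 4),
                **{g: round(v, 4) for g, v in r.group_values.items()},
                "level": r.level,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.4f")


def read_results(path: str | Path) -> list[EvaluationResult]:
    """Read a results CSV back into :class:`EvaluationResult` records.

    Additivity of the three group values to the comprehensive value is
    checked at rounded precision (2e-4), since the file stores 4-decimal
    values.
    """
    df = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"results CSV missing column(s): {', '.join(missing)}")
    results = []
    for row in df.itertuples(index=False):
        groups = {"S1": float(row.S1), "S2": float(row.S2), "S3": float(row.S3)}
        comp = float(row.comprehensive_value)
        if abs(sum(groups.values()) - comp) > 2e-4:
            raise ConsistencyError(
                f"year {int(row.year)}: group values sum to "
                f"{sum(groups.values()):.4f}, not the comprehensive value {comp:.4f}"
            )
        results.append(
            EvaluationResult(
                year=int(row.year),
                group_values=groups,
                comprehensive_value=comp,
                level=str(row.level),
            )
        )
    return results


# ---------------------------------------------------------------------------
# fixtures


def load_fixture(name: str):
    """Load a shipped fixture by name.

    ``table1_normalized`` — the published normalized panel (NormalizedPanel);
    ``table2_weights`` — the published weight table (DataFrame);
    ``table3_results`` — the published per-year results (list of
    EvaluationResult).
    """
    if name == "table1_normalized":
        with resources.as_file(_fixture_path("table1_normalized.csv")) as p:
            df = pd.read_csv(p).set_index("year")
        return NormalizedPanel(df)
    if name == "table2_weights":
        return _table2_frame()
    if name == "table3_results":
        with resources.as_file(_fixture_path("table3_results.csv")) as p:
            return read_results(p)
    raise KeyError(f"unknown fixture: {name!r}")


def fixture_global_weights() -> WeightVector:
    """The published 17 sub-indicator weights, renormalized to sum exactly 1.

    The printed values sum to 0.9999 (rounding); renormalization spreads
    the 1e-4 defect proportionally so the vector satisfies the sum-to-1
    invariant.
    """
    t2 = _table2_frame()
    w = t2["weight"].to_numpy(dtype=float)
    return WeightVector(tuple(t2["id"]), w / w.sum())


def fixture_main_weights() -> WeightVector:
    """The published three main-factor weights (sum to 1 exactly as printed)."""
    t2 = _table2_frame()
    sub = t2.drop_duplicates("group")
    w = sub["main_weight"].to_numpy(dtype=float)
    return WeightVector(tuple(sub["group"]), w / w.sum())
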