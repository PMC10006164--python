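"""Typed tabular datasets with a mixed-variable schema.

A dataset is an ordered collection of variables, each continuous,
categorical, boolean or date-valued.  Booleans are represented as
two-level categoricals so a single categorical code path serves both;
dates are carried as ``datetime64`` values and embedded as integer days
since 1970-01-01 wherever a numeric representation is needed, because a
monotone numeric embedding preserves distances between records.

Missing values are rejected outright: the generation method has no
defined behaviour for them and imputation is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariableSpec",
    "TabularDataset",
    "SchemaError",
    "DataValidationError",
    "read_dataset",
    "write_dataset",
    "validate_against",
    "infer_schema",
    "read_schema",
    "write_schema",
]

VTYPES = ("continuous", "categorical", "boolean", "date")

#: days-since-epoch origin used for the numeric embedding of dates
_EPOCH = np.datetime64("1970-01-01")


class SchemaError(ValueError):
    """A variable specification or schema is invalid."""


class DataValidationError(ValueError):
    """Data does not conform to its schema (missing/unparseable values, size)."""


@dataclass(frozen=True)
class VariableSpec:
    """Description of one column: name, type, categories and projection weight."""

    name: str
    vtype: str
    categories: tuple[str, ...] | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.vtype not in VTYPES:
            raise SchemaError(f"unknown vtype {self.vtype!r} for {self.name!r}")
        if self.weight <= 0:
            raise SchemaError(f"weight must be > 0 for {self.name!r}")
        if self.vtype == "categorical":
            if self.categories is None or len(self.categories) < 2:
                raise SchemaError(
                    f"categorical {self.name!r} needs >= 2 category labels"
                )
            if len(set(self.categories)) != len(self.categories):
                raise SchemaError(f"duplicate category labels in {self.name!r}")
            object.__setattr__(self, "categories", tuple(self.categories))
        elif self.vtype == "boolean":
            object.__setattr__(self, "categories", ("False", "True"))
        elif self.categories is not None:
            raise SchemaError(f"{self.name!r}: categories only valid for categoricals")

    @property
    def is_numeric(self) -> bool:
        return self.vtype in ("continuous", "date")


@dataclass
class TabularDataset:
    """An n x p table whose columns conform to an ordered schema.

    ``frame`` stores continuous columns as float64, dates as datetime64[ns]
    and categoricals/booleans as string-valued object columns.
    """

    schema: list[VariableSpec]
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        names = [v.name for v in self.schema]
        if list(self.frame.columns) != names:
            raise DataValidationError("frame columns do not match schema order")
        if len(self.frame) < 2:
            raise DataValidationError("a dataset needs at least 2 rows")
        self.frame = self.frame.reset_index(drop=True)
        self._coerce_and_check()

    def _coerce_and_check(self) -> None:
        for spec in self.schema:
            col = self.frame[spec.name]
            if col.isna().any():
                row = int(col.isna().idxmax())
                raise DataValidationError(
                    f"missing value at row {row}, column {spec.name!r}"
                )
            if spec.vtype == "continuous":
                try:
                    self.frame[spec.name] = pd.to_numeric(col).astype(np.float64)
                except (ValueError, TypeError) as exc:
                    raise DataValidationError(
                        f"column {spec.name!r} is not numeric: {exc}"
                    ) from None
            elif spec.vtype == "date":
                try:
                    self.frame[spec.name] = pd.to_datetime(col)
                except (ValueError, TypeError) as exc:
                    raise DataValidationError(
                        f"column {spec.name!r} is not date-valued: {exc}"
                    ) from None
            else:
                mapper = _canon_bool if spec.vtype == "boolean" else _canon_label
                values = col.map(mapper)
                bad = ~values.isin(spec.categories)
                if bad.any():
                    row = int(bad.idxmax())
                    raise DataValidationError(
                        f"value {values[row]!r} at row {row} not in categories "
                        f"of {spec.name!r}"
                    )
                self.frame[spec.name] = values

    # -- basic interface -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def p(self) -> int:
        return len(self.schema)

    def spec(self, name: str) -> VariableSpec:
        for v in self.schema:
            if v.name == name:
                return v
        raise KeyError(name)

    def numeric_view(self, name: str) -> np.ndarray:
        """Column as float64 (dates become days since 1970-01-01)."""
        spec = self.spec(name)
        col = self.frame[name]
        if spec.vtype == "date":
            return (
                (col.to_numpy().astype("datetime64[D]") - _EPOCH)
                .astype(np.int64)
                .astype(np.float64)
            )
        if spec.vtype == "continuous":
            return col.to_numpy(dtype=np.float64)
        raise TypeError(f"{name!r} is not numeric")

    def take(self, rows: Sequence[int] | np.ndarray) -> "TabularDataset":
        return TabularDataset(list(self.schema), self.frame.iloc[list(rows)])

    def with_weights(self, weights: dict[str, float]) -> "TabularDataset":
        schema = [
            replace(v, weight=weights.get(v.name, v.weight)) for v in self.schema
        ]
        return TabularDataset(schema, self.frame)

    def equals(self, other: "TabularDataset") -> bool:
        return self.schema == other.schema and self.frame.equals(other.frame)


def _canon_bool(x: object) -> str:
    """Canonical boolean label; accepts true/false (any case) and 0/1."""
    s = _canon_label(x)
    if s in ("True", "False"):
        return s
    try:
        v = float(s)
    except ValueError:
        return s
    if v == 0.0:
        return "False"
    if v == 1.0:
        return "True"
    return s


def _canon_label(x: object) -> str:
    """Canonical string form of a category/boolean label."""
    if isinstance(x, (bool, np.bool_)):
        return "True" if x else "False"
    s = str(x)
    if s.lower() in ("true", "false"):
        return s.lower().capitalize()
    return s


# -- schema inference ----------------------------------------------------

def infer_schema(frame: pd.DataFrame, categorical_cap: int = 10) -> list[VariableSpec]:
    """Infer a schema from a raw frame.

    Numeric columns become continuous unless they take only {0, 1};
    non-numeric columns with at most ``categorical_cap`` distinct values
    become categorical (more become an error: free text is unsupported);
    true/false-valued columns become boolean; ISO-8601 columns become dates.
    Deterministic for a fixed cap.
    """
    schema: list[VariableSpec] = []
    for name in frame.columns:
        col = frame[name]
        uniq = pd.unique(col.dropna())
        lowered = {str(u).lower() for u in uniq}
        if lowered <= {"true", "false"} and len(lowered) >= 1:
            schema.append(VariableSpec(name, "boolean"))
            continue
        numeric = pd.to_numeric(col, errors="coerce")
        if not numeric.isna().any():
            vals = set(np.unique(numeric.to_numpy()))
            if vals <= {0.0, 1.0}:
                schema.append(VariableSpec(name, "boolean"))
            else:
                schema.append(VariableSpec(name, "continuous"))
            continue
        as_date = pd.to_datetime(col, errors="coerce", format="ISO8601")
        if not as_date.isna().any():
            schema.append(VariableSpec(name, "date"))
            continue
        labels = sorted({_canon_label(u) for u in uniq})
        if len(labels) > categorical_cap:
            raise SchemaError(
                f"column {name!r} has {len(labels)} distinct non-numeric values "
                f"(cap {categorical_cap}); supply an explicit schema"
            )
        if len(labels) < 2:
            raise SchemaError(f"column {name!r} has a single value; cannot type it")
        schema.append(VariableSpec(name, "categorical", tuple(labels)))
    return schema


# -- I/O ------------------------------------------------------------------

def read_dataset(
    path: str | Path,
    schema: list[VariableSpec] | None = None,
    categorical_cap: int = 10,
) -> TabularDataset:
    """Read a CSV (header row, RFC-4180, UTF-8) into a typed dataset.

    When ``schema`` is omitted it is inferred with :func:`infer_schema`;
    boolean columns serialized as 0/1 or true/false are both accepted.
    """
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise DataValidationError(f"cannot parse {path}: {exc}") from None
    if frame.isna().any().any():
        col = frame.columns[frame.isna().any().to_numpy()][0]
        row = int(frame[col].isna().idxmax())
        raise DataValidationError(f"missing value at row {row}, column {col!r}")
    if schema is None:
        schema = infer_schema(frame, categorical_cap=categorical_cap)
    else:
        missing = [v.name for v in schema if v.name not in frame.columns]
        if missing:
            raise DataValidationError(f"columns absent from file: {missing}")
        frame = frame[[v.name for v in schema]]
    if len(frame) < 2:
        raise DataValidationError("a dataset needs at least 2 rows")
    return TabularDataset(list(schema), frame)


def write_dataset(data: TabularDataset, path: str | Path) -> None:
    """Write a dataset to CSV so that ``read_dataset`` round-trips it exactly.

    Continuous values use repr-precision floats, dates ISO-8601 days.
    """
    out = {}
    for spec in data.schema:
        col = data.frame[spec.name]
        if spec.vtype == "continuous":
            out[spec.name] = [np.format_float_positional(v, trim="0") for v in col]
        elif spec.vtype == "date":
            out[spec.name] = col.dt.strftime("%Y-%m-%d")
        else:
            out[spec.name] = col
    try:
        pd.DataFrame(out).to_csv(path, index=False)
    except OSError as exc:
        raise DataValidationError(f"cannot write {path}: {exc}") from None


def validate_against(
    data: TabularDataset, reference_schema: Iterable[VariableSpec]
) -> tuple[bool, list[str]]:
    """Structural-similarity check: same columns, order, types, category sets.

    Returns ``(ok, issues)``; never raises.
    """
    issues: list[str] = []
    ref = list(reference_schema)
    got = data.schema
    if [v.name for v in got] != [v.name for v in ref]:
        issues.append(
            f"column names/order differ: {[v.name for v in got]} vs "
            f"{[v.name for v in ref]}"
        )
    for g, r in zip(got, ref):
        if g.name != r.name:
            continue
        if g.vtype != r.vtype:
            issues.append(f"{g.name!r}: vtype {g.vtype} != {r.vtype}")
        elif g.vtype in ("categorical", "boolean"):
            extra = set(data.frame[g.name]) - set(r.categories)
            if extra:
                issues.append(f"{g.name!r}: values outside reference set: {sorted(extra)}")
    return (not issues, issues)


# -- schema files ---------------------------------------------------------

def read_schema(path: str | Path) -> list[VariableSpec]:
    """Load a YAML schema: a list of {name, vtype, categories?, weight?}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise SchemaError(f"{path}: expected a YAML list of variable mappings")
    out = []
    for item in raw:
        out.append(
            VariableSpec(
                name=item["name"],
                vtype=item["vtype"],
                categories=tuple(item["categories"]) if "categories" in item else None,
                weight=float(item.get("weight", 1.0)),
            )
        )
    return out


def write_schema(schema: Iterable[VariableSpec], path: str | Path) -> None:
    docs = []
    for v in schema:
        d: dict = {"name": v.name, "vtype": v.vtype}
        if v.vtype == "categorical":
            d["categories"] = list(v.categories)
        if v.weight != 1.0:
            d["weight"] = v.weight
        docs.append(d)
    with open(path, "w") as fh:
        yaml.safe_dump(docs, fh, sort_keys=False)
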