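"""Reading, writing and cleaning the clinical-table dialect.

The chronic kidney disease (CKD) table from the UCI repository — and the
synthetic cohorts this package generates in the same dialect — are
comma-separated text with a header row, ``?``/empty-string missing markers,
and sporadic whitespace/tab pollution of categorical tokens.  This module
declares column schemas, parses files into :class:`RawTable` (raw tokens,
missing cells flagged), corrects systematic typos, coerces mis-typed numeric
columns, and lowers a cleaned table into the numeric :class:`DataMatrix`
consumed by the preparation pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ColumnSpec",
    "AttributeSchema",
    "RawTable",
    "DataMatrix",
    "TypoMap",
    "SchemaError",
    "ParseError",
    "CoercionReport",
    "ckd_schema",
    "default_typo_map",
    "read_table",
    "write_table",
    "apply_typo_map",
    "coerce_numeric",
    "to_matrix",
    "parse_report",
]

KINDS = ("numeric", "categorical", "boolean")


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


class ParseError(ValueError):
    """A file cannot be parsed in the expected dialect."""


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    kind: str
    allowed_levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"unknown column kind {self.kind!r} for {self.name!r}")


@dataclass(frozen=True)
class AttributeSchema:
    """Column declarations for one table dialect.

    ``columns`` lists the *feature* columns in order; the id and class
    columns are declared separately and are not features.
    """

    columns: tuple[ColumnSpec, ...]
    class_column: str
    positive_label: str
    id_column: str | None = None
    missing_markers: frozenset[str] = frozenset({"?", ""})
    class_levels: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate feature column names")
        if self.class_column in names:
            raise SchemaError("class_column must not be listed as a feature")
        if self.id_column is not None and self.id_column in names:
            raise SchemaError("id_column must not be listed as a feature")

    @property
    def feature_names(self) -> list[str]:
        return [c.name for c in self.columns]

    @property
    def all_columns(self) -> list[str]:
        cols = [] if self.id_column is None else [self.id_column]
        return cols + self.feature_names + [self.class_column]

    def column(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise SchemaError(f"unknown column {name!r}")


@dataclass
class RawTable:
    """Parsed rows of raw cell tokens; ``None`` marks a missing cell."""

    schema: AttributeSchema
    rows: list[list[str | None]]
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        width = len(self.schema.all_columns)
        for i, row in enumerate(self.rows):
            if len(row) != width:
                raise ParseError(f"row {i} has {len(row)} cells, expected {width}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column_index(self, name: str) -> int:
        try:
            return self.schema.all_columns.index(name)
        except ValueError:
            raise SchemaError(f"unknown column {name!r}") from None

    def column_values(self, name: str) -> list[str | None]:
        j = self.column_index(name)
        return [r[j] for r in self.rows]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.schema.all_columns, dtype=object)


@dataclass
class DataMatrix:
    """Numeric matrix view of a table: missing cells are NaN sentinels.

    Categorical/boolean levels are stored as small integer codes; the
    ``level_maps`` record code -> level so a one-hot encoder can be fitted
    later without re-touching raw tokens.  The label is 1 for the schema's
    positive class.
    """

    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray
    column_kinds: list[str]
    level_maps: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.y) != self.X.shape[0]:
            raise ValueError("y length must equal number of rows of X")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match X columns")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("y must be binary 0/1")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> tuple[int, int]:
        """(negative, positive) sample counts."""
        return int((self.y == 0).sum()), int((self.y == 1).sum())

    def take(self, idx: np.ndarray) -> "DataMatrix":
        return DataMatrix(
            feature_names=list(self.feature_names),
            X=self.X[idx],
            y=self.y[idx],
            column_kinds=list(self.column_kinds),
            level_maps={k: list(v) for k, v in self.level_maps.items()},
        )

    def select(self, mask: Sequence[int] | np.ndarray) -> "DataMatrix":
        """Column subset by a 0/1 mask over features."""
        bits = np.asarray(mask, dtype=bool)
        keep = np.flatnonzero(bits)
        return DataMatrix(
            feature_names=[self.feature_names[j] for j in keep],
            X=self.X[:, keep],
            y=self.y.copy(),
            column_kinds=[self.column_kinds[j] for j in keep],
            level_maps={
                n: list(v) for n, v in self.level_maps.items()
                if n in {self.feature_names[j] for j in keep}
            },
        )


@dataclass(frozen=True)
class TypoMap:
    """Systematic token corrections: strip whitespace, canonicalise levels.

    ``explicit`` maps raw token -> canonical token per column; the generic
    rules (whitespace stripping, lowercasing of non-numeric levels) run
    first.  Application is idempotent.
    """

    explicit: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    strip_whitespace: bool = True
    lowercase_levels: bool = True

    def correct(self, column: ColumnSpec | None, token: str) -> str:
        out = token
        if self.strip_whitespace:
            out = out.strip()
        if (
            self.lowercase_levels
            and column is not None
            and column.kind in ("categorical", "boolean")
        ):
            out = out.lower()
        name = column.name if column is not None else ""
        out = dict(self.explicit.get(name, {})).get(out, out)
        return out


# Column layout of the 26-column UCI CKD file: id + 24 features + class.
_CKD_NUMERIC = [
    "age", "bp", "sg", "al", "su", "bgr", "bu", "sc", "sod", "pot",
    "hemo", "pcv", "wc", "rc",
]
_CKD_LEVELS = {
    "rbc": ("normal", "abnormal"),
    "pc": ("normal", "abnormal"),
    "pcc": ("notpresent", "present"),
    "ba": ("notpresent", "present"),
    "htn": ("no", "yes"),
    "dm": ("no", "yes"),
    "cad": ("no", "yes"),
    "appet": ("good", "poor"),
    "pe": ("no", "yes"),
    "ane": ("no", "yes"),
}
_CKD_BOOLEAN = {"htn", "dm", "cad", "pe", "ane"}
_CKD_ORDER = [
    "age", "bp", "sg", "al", "su", "rbc", "pc", "pcc", "ba", "bgr",
    "bu", "sc", "sod", "pot", "hemo", "pcv", "wc", "rc", "htn", "dm",
    "cad", "appet", "pe", "ane",
]


def ckd_schema() -> AttributeSchema:
    """The bundled 26-column UCI CKD schema (id + 24 features + class)."""
    cols = []
    for name in _CKD_ORDER:
        if name in _CKD_LEVELS:
            kind = "boolean" if name in _CKD_BOOLEAN else "categorical"
            cols.append(ColumnSpec(name, kind, _CKD_LEVELS[name]))
        else:
            cols.append(ColumnSpec(name, "numeric"))
    return AttributeSchema(
        columns=tuple(cols),
        class_column="classification",
        positive_label="ckd",
        id_column="id",
        class_levels=("notckd", "ckd"),
    )


def default_typo_map() -> TypoMap:
    """Corrections for the pollution classes the UCI file exhibits.

    Tab/space-padded tokens are handled by the generic strip rule; the
    explicit entries cover level variants observed in the wild.
    """
    return TypoMap(
        explicit={
            "classification": {"ckd\t": "ckd", "notckd\t": "notckd"},
            "dm": {"\tyes": "yes", " yes": "yes", "\tno": "no"},
            "cad": {"\tno": "no"},
        }
    )


def _norm_missing(token: str, markers: Iterable[str]) -> str | None:
    return None if token.strip() in markers else token


def read_table(path: str | Path, schema: AttributeSchema) -> RawTable:
    """Parse a delimited-text table into raw tokens.

    Header names must map onto the schema's columns (order-insensitive);
    cells matching the schema's missing markers are flagged missing.  No
    type coercion happens here.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(
            path, dtype=str, keep_default_na=False, skipinitialspace=False
        )
    except pd.errors.ParserError as exc:  # ragged row etc.
        raise ParseError(f"{path}: {exc}") from exc
    got = list(df.columns)
    want = set(schema.all_columns)
    unknown = [c for c in got if c not in want]
    if unknown:
        raise SchemaError(f"unknown column(s) in {path}: {unknown}")
    missing_cols = [c for c in schema.all_columns if c not in got]
    if missing_cols:
        raise SchemaError(f"column(s) absent from {path}: {missing_cols}")
    df = df[schema.all_columns]
    markers = set(schema.missing_markers)
    rows = [
        [_norm_missing(tok, markers) for tok in rec]
        for rec in df.itertuples(index=False, name=None)
    ]
    return RawTable(schema=schema, rows=rows, provenance=str(path))


def write_table(table: RawTable, path: str | Path) -> None:
    """Write a RawTable in the same dialect (missing cells as '?')."""
    df = table.to_frame().map(lambda v: "?" if v is None else v)
    df.to_csv(path, index=False)


def apply_typo_map(table: RawTable, typo_map: TypoMap) -> tuple[RawTable, int]:
    """Canonicalise tokens; returns the corrected table and cell count changed."""
    for col in typo_map.explicit:
        if col not in table.schema.all_columns:
            raise SchemaError(f"typo map references unknown column {col!r}")
    feature_specs = {c.name: c for c in table.schema.columns}
    markers = set(table.schema.missing_markers)
    count = 0
    new_rows: list[list[str | None]] = []
    for row in table.rows:
        new_row: list[str | None] = []
        for name, tok in zip(table.schema.all_columns, row):
            if tok is None:
                new_row.append(None)
                continue
            spec = feature_specs.get(name)
            if name == table.schema.class_column:
                spec = ColumnSpec(name, "categorical")
            fixed = typo_map.correct(spec, tok)
            if fixed.strip() in markers:
                fixed_val: str | None = None
            else:
                fixed_val = fixed
            if fixed_val != tok:
                count += 1
            new_row.append(fixed_val)
        new_rows.append(new_row)
    return RawTable(table.schema, new_rows, table.provenance), count


@dataclass
class CoercionReport:
    """Cells that could not be parsed as numbers: (row, column, token)."""

    failures: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def coerce_numeric(
    table: RawTable,
    columns: Sequence[str],
    on_error: str = "report",
) -> tuple[RawTable, CoercionReport]:
    """Re-kind listed columns as numeric, parsing their tokens.

    Unparseable non-missing tokens are listed in the report; with
    ``on_error="missing"`` they are additionally blanked, with ``"raise"``
    the first failure aborts.  Missing cells pass through untouched.
    """
    report = CoercionReport()
    col_idx = {name: table.column_index(name) for name in columns}
    new_rows = [list(r) for r in table.rows]
    for name, j in col_idx.items():
        for i, row in enumerate(new_rows):
            tok = row[j]
            if tok is None:
                continue
            try:
                float(tok.strip())
                row[j] = tok.strip()
            except ValueError:
                report.failures.append((i, name, tok))
                if on_error == "raise":
                    raise ParseError(
                        f"cannot coerce {tok!r} at row {i}, column {name!r}"
                    ) from None
                if on_error == "missing":
                    row[j] = None
    new_cols = tuple(
        ColumnSpec(c.name, "numeric") if c.name in col_idx else c
        for c in table.schema.columns
    )
    schema = replace(table.schema, columns=new_cols)
    return RawTable(schema, new_rows, table.provenance), report


def to_matrix(table: RawTable) -> DataMatrix:
    """Lower a cleaned table to numbers: codes for levels, NaN for missing.

    Level codes follow the schema's ``allowed_levels`` order where declared
    (data-independent), else first appearance.  The id column is dropped and
    the class column becomes y with positive_label -> 1.
    """
    schema = table.schema
    class_vals = table.column_values(schema.class_column)
    observed = [v for v in class_vals if v is not None]
    if len(observed) < len(class_vals):
        raise SchemaError("class column has missing cells")
    levels = sorted(set(observed))
    if len(levels) != 2:
        raise SchemaError(f"class column must have exactly 2 levels, got {levels}")
    if schema.positive_label not in levels:
        raise SchemaError(
            f"positive label {schema.positive_label!r} absent from class levels"
        )
    y = np.array([1 if v == schema.positive_label else 0 for v in class_vals])

    names, kinds, cols = [], [], []
    level_maps: dict[str, list[str]] = {}
    for spec in schema.columns:
        vals = table.column_values(spec.name)
        if all(v is None for v in vals):
            raise SchemaError(f"column {spec.name!r} is entirely missing")
        if spec.kind == "numeric":
            col = np.array(
                [math.nan if v is None else float(v) for v in vals], dtype=float
            )
        else:
            if spec.allowed_levels:
                lvls = list(spec.allowed_levels)
                extra = sorted(
                    {v for v in vals if v is not None and v not in lvls}
                )
                lvls += extra
            else:
                lvls = list(dict.fromkeys(v for v in vals if v is not None))
            code = {lvl: float(i) for i, lvl in enumerate(lvls)}
            col = np.array(
                [math.nan if v is None else code[v] for v in vals], dtype=float
            )
            level_maps[spec.name] = lvls
        names.append(spec.name)
        kinds.append(spec.kind)
        cols.append(col)
    X = np.column_stack(cols) if cols else np.empty((len(y), 0))
    return DataMatrix(names, X, y, kinds, level_maps)


def parse_report(table: RawTable) -> dict:
    """Structured summary: rows, columns, missing cells per column, classes."""
    per_col = {
        name: sum(v is None for v in table.column_values(name))
        for name in table.schema.all_columns
    }
    class_vals = [v for v in table.column_values(table.schema.class_column) if v]
    counts = pd.Series(class_vals).value_counts().to_dict()
    return {
        "provenance": table.provenance,
        "rows": table.n_rows,
        "columns": len(table.schema.all_columns),
        "feature_columns": len(table.schema.columns),
        "missing_per_column": per_col,
        "missing_total": int(sum(per_col.values())),
        "class_counts": {str(k): int(v) for k, v in counts.items()},
    }
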