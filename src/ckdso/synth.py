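"""Synthetic CKD-like cohort generator with a complete injection log.

Cohorts are emitted in the exact delimited-text dialect the reader parses
(comma-separated, '?' missing markers), with planted class-informative
features and the artifact classes messy clinical tables exhibit: duplicate
rows, extreme outlier rows, whitespace/tab-polluted tokens, and
missing-at-random cells.  Every injection is logged with exact coordinates,
so preparation-stage reports can be checked against ground truth and the
dirty cohort can be replayed from the clean one byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .dataio import AttributeSchema, ColumnSpec, RawTable

__all__ = ["SyntheticSpec", "InjectionLog", "generate_cohort", "replay",
           "uci_shape_spec"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one generated cohort.

    Defaults mirror the clinical table the framework targets: 400 records,
    ~10% missing cells, a handful of whitespace typos, two dozen extreme
    rows in the outlier-screened columns, and a 37.5% minority class.  The
    planted signal is a 2-SD class-conditional mean shift on the
    informative features.
    """

    n: int = 400
    d_informative: int = 5
    d_noise: int = 15
    effect_size: float = 2.0
    n_categorical: int = 2
    minority_fraction: float = 0.375
    missing_rate: float = 0.10
    typo_rate: float = 0.01
    duplicate_count: int = 0
    outlier_count: int = 26
    outlier_magnitude: float = 8.0
    minority_label: str = "positive"  # which class is the minority
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 20:
            raise ValueError("n must be >= 20")
        if self.d_informative < 1:
            raise ValueError("d_informative must be >= 1")
        for name in ("minority_fraction", "missing_rate", "typo_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.n_categorical > self.d_informative:
            raise ValueError("n_categorical cannot exceed d_informative")
        if self.duplicate_count > self.n:
            raise ValueError("duplicate_count cannot exceed n")
        if self.outlier_count > self.n:
            raise ValueError("outlier_count cannot exceed n")
        if self.minority_label not in ("positive", "negative"):
            raise ValueError("minority_label must be 'positive' or 'negative'")


@dataclass
class InjectionLog:
    """Exact coordinates of every injected artifact.

    Cell edits are (row, column, old_token, new_token); duplicate entries
    are (appended_row_index, source_row_index).  Replaying the log on the
    clean cohort reproduces the dirty cohort exactly.
    """

    informative_features: list[str] = field(default_factory=list)
    lof_columns: list[str] = field(default_factory=list)
    duplicates: list[tuple[int, int]] = field(default_factory=list)
    outlier_rows: list[int] = field(default_factory=list)
    outlier_cells: list[tuple[int, str, str, str]] = field(default_factory=list)
    typos: list[tuple[int, str, str, str]] = field(default_factory=list)
    missing: list[tuple[int, str, str]] = field(default_factory=list)
    seed: int = 0

    def counts(self) -> dict[str, int]:
        return {
            "duplicates": len(self.duplicates),
            "outlier_rows": len(self.outlier_rows),
            "typos": len(self.typos),
            "missing_cells": len(self.missing),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "InjectionLog":
        raw = json.loads(Path(path).read_text())
        log = cls(seed=raw["seed"])
        log.informative_features = raw["informative_features"]
        log.lof_columns = raw["lof_columns"]
        log.duplicates = [tuple(e) for e in raw["duplicates"]]
        log.outlier_rows = list(raw["outlier_rows"])
        log.outlier_cells = [tuple(e) for e in raw["outlier_cells"]]
        log.typos = [tuple(e) for e in raw["typos"]]
        log.missing = [tuple(e) for e in raw["missing"]]
        return log


def _fmt(v: float) -> str:
    return format(float(v), ".6g")


def _schema(spec: SyntheticSpec) -> tuple[AttributeSchema, list[str], list[str]]:
    num_informative = spec.d_informative - spec.n_categorical
    informative, cols = [], []
    for i in range(num_informative):
        name = f"inf_num_{i:02d}"
        cols.append(ColumnSpec(name, "numeric"))
        informative.append(name)
    for i in range(spec.n_categorical):
        name = f"inf_cat_{i:02d}"
        cols.append(ColumnSpec(name, "boolean", ("no", "yes")))
        informative.append(name)
    for i in range(spec.d_noise):
        name = f"noise_{i:02d}"
        cols.append(ColumnSpec(name, "numeric"))
    schema = AttributeSchema(
        columns=tuple(cols),
        class_column="classification",
        positive_label="ckd",
        id_column="id",
        class_levels=("notckd", "ckd"),
    )
    numeric_names = [c.name for c in cols if c.kind == "numeric"]
    lof_cols = numeric_names[: min(5, len(numeric_names))]
    return schema, informative, lof_cols


def uci_shape_spec(seed: int = 0) -> SyntheticSpec:
    """A cohort with the documented UCI CKD shape: 400 rows, 24 features,
    250 positive / 150 negative records."""
    return SyntheticSpec(
        n=400, d_informative=5, d_noise=19, minority_fraction=0.375,
        minority_label="negative", seed=seed,
    )


def generate_cohort(spec: SyntheticSpec) -> tuple[RawTable, InjectionLog]:
    """Draw a clean cohort, then inject duplicates, outliers, typos and
    missing cells in that order, logging every edit."""
    rng = np.random.default_rng(spec.seed)
    schema, informative, lof_cols = _schema(spec)
    log = InjectionLog(
        informative_features=informative, lof_columns=lof_cols, seed=spec.seed
    )

    n_minority = round(spec.n * spec.minority_fraction)
    minority_code = 1 if spec.minority_label == "positive" else 0
    y = np.array(
        [minority_code] * n_minority
        + [1 - minority_code] * (spec.n - n_minority)
    )
    rng.shuffle(y)

    columns: dict[str, list[str]] = {}
    num_informative = spec.d_informative - spec.n_categorical
    for i in range(num_informative):
        shift = spec.effect_size * y  # class-conditional mean shift in SD units
        vals = rng.normal(0.0, 1.0, spec.n) + shift
        columns[f"inf_num_{i:02d}"] = [_fmt(v) for v in vals]
    for i in range(spec.n_categorical):
        p = np.where(y == 1, 0.8, 0.2)  # class-dependent Bernoulli
        draws = rng.random(spec.n) < p
        columns[f"inf_cat_{i:02d}"] = ["yes" if b else "no" for b in draws]
    for i in range(spec.d_noise):
        vals = rng.normal(0.0, 1.0, spec.n)
        columns[f"noise_{i:02d}"] = [_fmt(v) for v in vals]

    all_cols = schema.all_columns
    rows: list[list[str | None]] = []
    for r in range(spec.n):
        row: list[str | None] = [str(r)]
        for c in schema.feature_names:
            row.append(columns[c][r])
        row.append("ckd" if y[r] == 1 else "notckd")
        rows.append(row)

    # duplicates: overwrite randomly chosen victim rows with copies of
    # same-class sources so class counts stay exact
    if spec.duplicate_count:
        victims = rng.choice(spec.n, size=spec.duplicate_count, replace=False)
        for v in victims:
            same = [
                r for r in range(spec.n)
                if r not in victims and y[r] == y[v]
            ]
            src = int(rng.choice(same))
            rows[v] = [str(v)] + list(rows[src][1:])
            log.duplicates.append((int(v), src))

    # outliers: shift the screened numeric columns by +/- magnitude SDs
    if spec.outlier_count:
        taken = {v for v, _ in log.duplicates}
        candidates = [r for r in range(spec.n) if r not in taken]
        out_rows = sorted(
            int(r) for r in rng.choice(
                candidates, size=spec.outlier_count, replace=False
            )
        )
        log.outlier_rows = out_rows
        for r in out_rows:
            for c in lof_cols:
                j = all_cols.index(c)
                old = rows[r][j]
                sign = 1.0 if rng.random() < 0.5 else -1.0
                new = _fmt(float(old) + sign * spec.outlier_magnitude)
                rows[r][j] = new
                log.outlier_cells.append((r, c, old, new))

    clean_rows = [list(r) for r in rows]

    # typos: whitespace/tab pollution of categorical and class tokens
    token_cols = [
        c.name for c in schema.columns if c.kind in ("categorical", "boolean")
    ] + [schema.class_column]
    eligible = [(r, c) for c in token_cols for r in range(spec.n)]
    n_typos = round(spec.typo_rate * len(eligible))
    if n_typos:
        pick = rng.choice(len(eligible), size=n_typos, replace=False)
        pollution = ["\t{}", "{}\t", " {}", "{} "]
        for idx in sorted(int(i) for i in pick):
            r, c = eligible[idx]
            j = all_cols.index(c)
            old = rows[r][j]
            new = pollution[int(rng.integers(0, len(pollution)))].format(old)
            rows[r][j] = new
            log.typos.append((r, c, old, new))

    # missing cells: MCAR over feature cells not already edited
    edited = {(r, c) for r, c, _, _ in log.typos}
    eligible_mc = [
        (r, c)
        for c in schema.feature_names
        for r in range(spec.n)
        if (r, c) not in edited
    ]
    n_missing = round(spec.missing_rate * len(eligible_mc))
    if n_missing:
        pick = rng.choice(len(eligible_mc), size=n_missing, replace=False)
        for idx in sorted(int(i) for i in pick):
            r, c = eligible_mc[idx]
            j = all_cols.index(c)
            log.missing.append((r, c, rows[r][j]))
            rows[r][j] = None

    dirty = RawTable(schema=schema, rows=rows, provenance="synthetic")
    dirty.clean_rows = clean_rows  # type: ignore[attr-defined]
    return dirty, log


def clean_cohort(spec: SyntheticSpec) -> RawTable:
    """The pre-injection cohort (duplicates and outliers included, since
    they are row content, not token corruption)."""
    dirty, _ = generate_cohort(spec)
    return RawTable(
        schema=dirty.schema,
        rows=[list(r) for r in dirty.clean_rows],  # type: ignore[attr-defined]
        provenance="synthetic",
    )


def replay(clean: RawTable, log: InjectionLog) -> RawTable:
    """Re-apply the logged token corruptions to the clean cohort."""
    if clean.provenance != "synthetic":
        raise ValueError("replay expects a synthetic clean cohort")
    rows = [list(r) for r in clean.rows]
    all_cols = clean.schema.all_columns
    for r, c, old, new in log.typos:
        j = all_cols.index(c)
        if rows[r][j] != old:
            raise ValueError(f"log mismatch at ({r}, {c}): {rows[r][j]!r} != {old!r}")
        rows[r][j] = new
    for r, c, old in log.missing:
        j = all_cols.index(c)
        if rows[r][j] != old:
            raise ValueError(f"log mismatch at ({r}, {c}): {rows[r][j]!r} != {old!r}")
        rows[r][j] = None
    return RawTable(schema=clean.schema, rows=rows, provenance="synthetic")
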