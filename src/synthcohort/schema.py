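"""Cohort data model: typed column specifications, schema and table containers.

A clinical cohort is a flat table, one row per patient, whose columns are
numerical (bounded, possibly integer-valued), binary (two labelled levels)
or categorical (three or more labelled levels).  The schema is the single
source of truth for validation, encoding and decoding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

NUMERICAL = "numerical"
BINARY = "binary"
CATEGORICAL = "categorical"
_KINDS = (NUMERICAL, BINARY, CATEGORICAL)


class SchemaError(ValueError):
    """Raised when a schema or a table violates the cohort data model."""


@dataclass(frozen=True)
class ColumnSpec:
    """Description of a single clinical column.

    Parameters
    ----------
    name
        Column identifier, unique within a schema.
    kind
        One of ``"numerical"``, ``"binary"``, ``"categorical"``.
    levels
        Ordered category labels; exactly 2 for binary, >=3 for categorical.
    min, max
        Bounds for numerical columns.  ``min == max`` is tolerated but the
        column is flagged degenerate by the encoder.
    integer_valued
        Numerical columns that only take whole values (e.g. age in years);
        decoded values are rounded half away from zero.
    """

    name: str
    kind: str
    levels: tuple[str, ...] = ()
    min: float = float("nan")
    max: float = float("nan")
    integer_valued: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise SchemaError(f"column {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == BINARY and len(self.levels) != 2:
            raise SchemaError(f"column {self.name!r}: binary needs exactly 2 levels")
        if self.kind == CATEGORICAL and len(set(self.levels)) < 3:
            raise SchemaError(
                f"column {self.name!r}: categorical needs >=3 distinct levels"
            )
        if self.kind in (BINARY, CATEGORICAL) and len(set(self.levels)) != len(
            self.levels
        ):
            raise SchemaError(f"column {self.name!r}: duplicate levels")
        if self.kind == NUMERICAL:
            if not (np.isfinite(self.min) and np.isfinite(self.max)):
                raise SchemaError(f"column {self.name!r}: numerical needs min/max")
            if self.min > self.max:
                raise SchemaError(f"column {self.name!r}: min > max")

    @property
    def degenerate(self) -> bool:
        return self.kind == NUMERICAL and self.min == self.max

    @property
    def encoded_width(self) -> int:
        """Number of design-matrix columns this feature occupies."""
        if self.kind == CATEGORICAL:
            return len(self.levels)
        return 1  # numerical scales to one column, binary is a single 0/1 column

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "kind": self.kind}
        if self.kind == NUMERICAL:
            d.update(min=self.min, max=self.max, integer_valued=self.integer_valued)
        else:
            d["levels"] = list(self.levels)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ColumnSpec":
        return cls(
            name=d["name"],
            kind=d["kind"],
            levels=tuple(d.get("levels", ())),
            min=float(d.get("min", float("nan"))),
            max=float(d.get("max", float("nan"))),
            integer_valued=bool(d.get("integer_valued", False)),
        )


@dataclass(frozen=True)
class CohortSchema:
    """Ordered collection of :class:`ColumnSpec` describing one cohort."""

    columns: tuple[ColumnSpec, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate column names: {dupes}")

    @property
    def n_raw_features(self) -> int:
        return len(self.columns)

    @property
    def encoded_width(self) -> int:
        """Width of the numeric design matrix this schema encodes to."""
        return sum(c.encoded_width for c in self.columns)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.columns]

    def __getitem__(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    def numerical(self) -> list[ColumnSpec]:
        return [c for c in self.columns if c.kind == NUMERICAL]

    def discrete(self) -> list[ColumnSpec]:
        """Binary and categorical columns, audited together."""
        return [c for c in self.columns if c.kind != NUMERICAL]

    def to_json(self, path: str | Path) -> None:
        doc = {"columns": [c.to_dict() for c in self.columns]}
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSchema":
        doc = json.loads(Path(path).read_text())
        return cls(tuple(ColumnSpec.from_dict(d) for d in doc["columns"]))


@dataclass
class CoercionLog:
    """Per-column counts of cells coerced or imputed during validation."""

    coerced: dict[str, int] = field(default_factory=dict)
    imputed: dict[str, int] = field(default_factory=dict)

    def note_coerced(self, col: str, n: int = 1) -> None:
        if n:
            self.coerced[col] = self.coerced.get(col, 0) + n

    def note_imputed(self, col: str, n: int = 1) -> None:
        if n:
            self.imputed[col] = self.imputed.get(col, 0) + n


@dataclass
class CohortTable:
    """Patient-level records conforming to a :class:`CohortSchema`.

    ``data`` columns follow schema order; numerical columns are float64,
    discrete columns hold level labels as strings.
    """

    schema: CohortSchema
    data: pd.DataFrame
    coercions: CoercionLog = field(default_factory=CoercionLog)

    def __post_init__(self) -> None:
        missing = set(self.schema.names) - set(self.data.columns)
        if missing:
            raise SchemaError(f"table lacks columns: {sorted(missing)}")
        self.data = self.data[self.schema.names].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_patients(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, schema: CohortSchema, strict: bool = True
    ) -> "CohortTable":
        raw = pd.read_csv(path, dtype=str, keep_default_na=True)
        return validate_schema(schema, raw, strict=strict)


def validate_schema(
    schema: CohortSchema,
    table: pd.DataFrame | Mapping[str, Iterable],
    strict: bool = True,
) -> CohortTable:
    """Validate a raw table against a schema and return a conforming cohort.

    Numeric cells are parsed to float; missing numerics are imputed by the
    column median and missing discrete cells by the column mode, with counts
    recorded in the coercion log.  In strict mode an unknown category label
    or an unparsable numeric raises :class:`SchemaError` naming the row and
    column; in lax mode such cells are treated as missing.
    """
    raw = pd.DataFrame(table)
    unknown = set(raw.columns) - set(schema.names)
    if unknown:
        raise SchemaError(f"unknown column(s): {sorted(unknown)}")
    missing = set(schema.names) - set(raw.columns)
    if missing:
        raise SchemaError(f"missing column(s): {sorted(missing)}")

    log = CoercionLog()
    out: dict[str, pd.Series] = {}
    for spec in schema.columns:
        col = raw[spec.name]
        if spec.kind == NUMERICAL:
            vals = pd.to_numeric(col, errors="coerce").astype(float)
            bad = vals.isna() & col.notna() & (col.astype(str).str.strip() != "")
            if bad.any():
                if strict:
                    row = int(bad.idxmax())
                    raise SchemaError(
                        f"row {row}, column {spec.name!r}: "
                        f"unparsable numeric {col[bad].iloc[0]!r}"
                    )
                log.note_coerced(spec.name, int(bad.sum()))
            n_missing = int(vals.isna().sum())
            if n_missing:
                if n_missing == len(vals):
                    raise SchemaError(f"column {spec.name!r}: all values missing")
                vals = vals.fillna(float(vals.median()))
                log.note_imputed(spec.name, n_missing)
            oob = (vals < spec.min) | (vals > spec.max)
            if oob.any():
                if strict:
                    row = int(oob.idxmax())
                    raise SchemaError(
                        f"row {row}, column {spec.name!r}: value "
                        f"{vals[oob].iloc[0]} outside [{spec.min}, {spec.max}]"
                    )
                vals = vals.clip(spec.min, spec.max)
                log.note_coerced(spec.name, int(oob.sum()))
            out[spec.name] = vals
        else:
            vals = col.astype("string")
            known = vals.isin(list(spec.levels))
            bad = ~known & vals.notna()
            if bad.any():
                if strict:
                    row = int(bad.idxmax())
                    raise SchemaError(
                        f"row {row}, column {spec.name!r}: "
                        f"category {vals[bad].iloc[0]!r} not in levels {spec.levels}"
                    )
                vals = vals.where(known)
                log.note_coerced(spec.name, int(bad.sum()))
            n_missing = int(vals.isna().sum())
            if n_missing:
                if n_missing == len(vals):
                    raise SchemaError(f"column {spec.name!r}: all values missing")
                mode = vals.mode(dropna=True).iloc[0]
                vals = vals.fillna(mode)
                log.note_imputed(spec.name, n_missing)
            out[spec.name] = vals.astype(object)

    df = pd.DataFrame(out) if out else pd.DataFrame(columns=schema.names)
    if len(raw) == 0:
        df = pd.DataFrame({n: pd.Series(dtype=object) for n in schema.names})
    return CohortTable(schema=schema, data=df, coercions=log)
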