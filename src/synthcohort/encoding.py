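"""TabularDataProcessor: cohort table <-> numeric design matrix.

Forward encoding min-max scales numerical columns to [0, 1], maps binary
columns to a single 0/1 column by level order and expands categoricals to
one-hot blocks, so every encoded coordinate lives in [0, 1] — the range a
sigmoid decoder can produce.  The inverse transform undoes the scaling with
the stored per-column (min, max), clips to the schema bounds, rounds
integer-valued numerics half away from zero, thresholds binaries at 0.5 and
decodes one-hot blocks by argmax (ties break to the lowest-index level).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import (
    BINARY,
    CATEGORICAL,
    NUMERICAL,
    CohortSchema,
    CohortTable,
    SchemaError,
)


@dataclass(frozen=True)
class EncodedColumn:
    """Provenance of one design-matrix column."""

    source: str  # raw column name
    role: str  # "scaled-numeric" | "binary" | "one-hot"
    level: str | None = None  # for one-hot columns, the level it indicates


@dataclass
class EncodedMatrix:
    """Numeric design matrix with column provenance and scaler state.

    ``values`` is n_patients x encoded_width, every entry in [0, 1].
    ``scaler_state`` maps each numerical column to the (min, max) observed
    at fit time, used for inversion.  ``degenerate`` lists numerical columns
    whose observed min equals max (encoded as constant 0.0).
    """

    values: np.ndarray
    schema: CohortSchema
    column_map: tuple[EncodedColumn, ...]
    scaler_state: dict[str, tuple[float, float]]
    degenerate: tuple[str, ...] = ()

    @property
    def d(self) -> int:
        return len(self.column_map)

    def sidecar(self) -> dict:
        """JSON-serialisable description of column_map + scaler_state."""
        return {
            "columns": [c.to_dict() for c in self.schema.columns],
            "column_map": [
                {"source": c.source, "role": c.role, "level": c.level}
                for c in self.column_map
            ],
            "scaler_state": {k: list(v) for k, v in self.scaler_state.items()},
            "degenerate": list(self.degenerate),
        }

    def to_files(self, csv_path: str | Path, sidecar_path: str | Path) -> None:
        header = [
            c.source if c.level is None else f"{c.source}={c.level}"
            for c in self.column_map
        ]
        pd.DataFrame(self.values, columns=header).to_csv(csv_path, index=False)
        Path(sidecar_path).write_text(json.dumps(self.sidecar(), indent=1))


class TabularProcessor:
    """Fit on a cohort, then encode/decode matrices for that schema.

    The processor is the bridge between patient records and the VAE: it is
    fit once on the training cohort and its scaler state travels with the
    model checkpoint so generated latent decodings can be mapped back to
    valid patient records.
    """

    def __init__(self, schema: CohortSchema):
        self.schema = schema
        self.scaler_state: dict[str, tuple[float, float]] | None = None
        self._column_map: tuple[EncodedColumn, ...] | None = None
        self._degenerate: tuple[str, ...] = ()

    # -- fitting -----------------------------------------------------------
    def fit(self, table: CohortTable) -> "TabularProcessor":
        if len(table) == 0:
            raise SchemaError("cannot fit on an empty cohort")
        if table.schema.names != self.schema.names:
            raise SchemaError("table schema does not match processor schema")
        state: dict[str, tuple[float, float]] = {}
        degenerate: list[str] = []
        cmap: list[EncodedColumn] = []
        for spec in self.schema.columns:
            if spec.kind == NUMERICAL:
                col = table.data[spec.name].to_numpy(dtype=float)
                lo, hi = float(np.min(col)), float(np.max(col))
                if lo == hi:
                    degenerate.append(spec.name)
                state[spec.name] = (lo, hi)
                cmap.append(EncodedColumn(spec.name, "scaled-numeric"))
            elif spec.kind == BINARY:
                cmap.append(EncodedColumn(spec.name, "binary"))
            else:
                for lev in spec.levels:
                    cmap.append(EncodedColumn(spec.name, "one-hot", lev))
        self.scaler_state = state
        self._column_map = tuple(cmap)
        self._degenerate = tuple(degenerate)
        return self

    # -- encoding ----------------------------------------------------------
    def transform(self, table: CohortTable) -> EncodedMatrix:
        if self.scaler_state is None or self._column_map is None:
            raise SchemaError("processor not fitted")
        n = len(table)
        out = np.zeros((n, len(self._column_map)), dtype=float)
        j = 0
        for spec in self.schema.columns:
            if spec.kind == NUMERICAL:
                lo, hi = self.scaler_state[spec.name]
                col = table.data[spec.name].to_numpy(dtype=float)
                if lo == hi:
                    out[:, j] = 0.0  # degenerate: constant column
                else:
                    out[:, j] = np.clip((col - lo) / (hi - lo), 0.0, 1.0)
                j += 1
            elif spec.kind == BINARY:
                col = table.data[spec.name].to_numpy(dtype=object)
                out[:, j] = (col == spec.levels[1]).astype(float)
                j += 1
            else:
                col = table.data[spec.name].to_numpy(dtype=object)
                for lev in spec.levels:
                    out[:, j] = (col == lev).astype(float)
                    j += 1
        return EncodedMatrix(
            values=out,
            schema=self.schema,
            column_map=self._column_map,
            scaler_state=dict(self.scaler_state),
            degenerate=self._degenerate,
        )

    def fit_transform(self, table: CohortTable) -> EncodedMatrix:
        return self.fit(table).transform(table)

    # -- decoding ----------------------------------------------------------
    def inverse_transform(self, matrix: np.ndarray) -> CohortTable:
        """Decode an n x d real matrix into schema-valid patient records."""
        if self.scaler_state is None or self._column_map is None:
            raise SchemaError("processor not fitted")
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != len(self._column_map):
            raise SchemaError(
                f"matrix width {matrix.shape[-1] if matrix.ndim == 2 else '?'} "
                f"does not match encoded width {len(self._column_map)}"
            )
        cols: dict[str, np.ndarray] = {}
        j = 0
        for spec in self.schema.columns:
            if spec.kind == NUMERICAL:
                lo, hi = self.scaler_state[spec.name]
                vals = matrix[:, j] * (hi - lo) + lo
                vals = np.clip(vals, spec.min, spec.max)
                if spec.integer_valued:
                    # round half away from zero
                    vals = np.sign(vals) * np.floor(np.abs(vals) + 0.5)
                    vals = np.clip(vals, spec.min, spec.max)
                cols[spec.name] = vals
                j += 1
            elif spec.kind == BINARY:
                idx = (matrix[:, j] >= 0.5).astype(int)
                cols[spec.name] = np.array(spec.levels, dtype=object)[idx]
                j += 1
            else:
                block = matrix[:, j : j + len(spec.levels)]
                idx = np.argmax(block, axis=1)  # ties -> lowest-index level
                cols[spec.name] = np.array(spec.levels, dtype=object)[idx]
                j += len(spec.levels)
        df = pd.DataFrame(cols, columns=self.schema.names)
        return CohortTable(schema=self.schema, data=df)

    @classmethod
    def from_sidecar(cls, sidecar: dict) -> "TabularProcessor":
        """Rebuild a fitted processor from an :meth:`EncodedMatrix.sidecar`."""
        from .schema import ColumnSpec

        schema = CohortSchema(
            tuple(ColumnSpec.from_dict(d) for d in sidecar["columns"])
        )
        proc = cls(schema)
        proc.scaler_state = {
            k: (float(v[0]), float(v[1]))
            for k, v in sidecar["scaler_state"].items()
        }
        proc._column_map = tuple(
            EncodedColumn(c["source"], c["role"], c.get("level"))
            for c in sidecar["column_map"]
        )
        proc._degenerate = tuple(sidecar.get("degenerate", ()))
        return proc
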