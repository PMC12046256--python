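"""Schema validation and the encode/decode (TabularDataProcessor) contract."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from synthcohort import (
    ColumnSpec,
    CohortSchema,
    CohortTable,
    SchemaError,
    TabularProcessor,
    validate_schema,
)


class TestValidateSchema:
    def test_empty_table_with_valid_header(self, tiny_schema):
        raw = pd.DataFrame({n: [] for n in tiny_schema.names})
        table = validate_schema(tiny_schema, raw)
        assert len(table) == 0

    def test_unknown_category_strict_names_row_and_column(self, tiny_schema):
        raw = pd.DataFrame(
            {"age": ["30"], "score": ["0.5"], "sex": ["F"], "grade": ["Z"]}
        )
        with pytest.raises(SchemaError, match=r"row 0.*'grade'.*'Z'"):
            validate_schema(tiny_schema, raw)

    def test_unparsable_numeric_rejected(self, tiny_schema):
        raw = pd.DataFrame(
            {"age": ["abc"], "score": ["0.5"], "sex": ["F"], "grade": ["A"]}
        )
        with pytest.raises(SchemaError, match=r"'age'"):
            validate_schema(tiny_schema, raw)

    def test_unknown_column_rejected(self, tiny_schema):
        raw = pd.DataFrame({"bogus": [1]})
        with pytest.raises(SchemaError, match="bogus|missing"):
            validate_schema(tiny_schema, raw)

    def test_missing_values_imputed_and_logged(self, tiny_schema):
        raw = pd.DataFrame(
            {
                "age": ["30", None, "50"],
                "score": ["0.5", "0.6", "0.7"],
                "sex": ["F", "M", None],
                "grade": ["A", "B", "A"],
            }
        )
        table = validate_schema(tiny_schema, raw)
        assert table.coercions.imputed == {"age": 1, "sex": 1}
        assert table.data["age"].iloc[1] == 40.0  # median of 30, 50
        assert table.data["sex"].iloc[2] == "F"  # mode

    def test_csv_round_trip(self, tiny_schema, tiny_table, tmp_path):
        path = tmp_path / "cohort.csv"
        tiny_table.to_csv(path)
        back = CohortTable.from_csv(path, tiny_schema)
        pd.testing.assert_frame_equal(
            back.data.astype(str), tiny_table.data.astype(str)
        )


class TestEncoding:
    def test_minmax_endpoints(self):
        schema = CohortSchema((ColumnSpec("x", "numerical", min=0, max=100),))
        table = CohortTable(schema, pd.DataFrame({"x": [0.0, 50.0, 100.0]}))
        enc = TabularProcessor(schema).fit_transform(table)
        assert enc.values[:, 0].tolist() == [0.0, 0.5, 1.0]

    def test_one_hot_by_hand(self):
        schema = CohortSchema(
            (ColumnSpec("g", "categorical", levels=("A", "B", "C")),)
        )
        table = CohortTable(schema, pd.DataFrame({"g": ["A", "B", "A"]}))
        enc = TabularProcessor(schema).fit_transform(table)
        assert enc.values.tolist() == [[1, 0, 0], [0, 1, 0], [1, 0, 0]]

    def test_one_hot_rows_sum_to_one(self, small_cohort):
        enc = TabularProcessor(small_cohort.schema).fit_transform(small_cohort)
        for spec in small_cohort.schema.columns:
            if spec.kind != "categorical":
                continue
            cols = [
                i for i, c in enumerate(enc.column_map) if c.source == spec.name
            ]
            assert np.all(enc.values[:, cols].sum(axis=1) == 1.0)

    def test_degenerate_numeric_flagged_constant_zero(self):
        schema = CohortSchema((ColumnSpec("x", "numerical", min=0, max=100),))
        table = CohortTable(schema, pd.DataFrame({"x": [5.0, 5.0]}))
        enc = TabularProcessor(schema).fit_transform(table)
        assert enc.degenerate == ("x",)
        assert np.all(enc.values == 0.0)

    def test_empty_table_rejected(self, tiny_schema):
        empty = CohortTable(
            tiny_schema,
            pd.DataFrame({n: pd.Series(dtype=object) for n in tiny_schema.names}),
        )
        with pytest.raises(SchemaError):
            TabularProcessor(tiny_schema).fit(empty)


class TestInverseTransform:
    def test_argmax_decoding(self):
        schema = CohortSchema(
            (ColumnSpec("g", "categorical", levels=("A", "B", "C")),)
        )
        proc = TabularProcessor(schema)
        proc.fit(CohortTable(schema, pd.DataFrame({"g": ["A", "B", "C"]})))
        out = proc.inverse_transform(np.array([[0.2, 0.7, 0.1]]))
        assert out.data["g"].iloc[0] == "B"

    def test_argmax_tie_breaks_to_lowest_index(self):
        schema = CohortSchema(
            (ColumnSpec("g", "categorical", levels=("A", "B", "C")),)
        )
        proc = TabularProcessor(schema)
        proc.fit(CohortTable(schema, pd.DataFrame({"g": ["A", "B", "C"]})))
        out = proc.inverse_transform(np.array([[0.5, 0.5, 0.0]]))
        assert out.data["g"].iloc[0] == "A"

    def test_out_of_range_clipped(self):
        schema = CohortSchema((ColumnSpec("x", "numerical", min=0, max=100),))
        proc = TabularProcessor(schema)
        proc.fit(CohortTable(schema, pd.DataFrame({"x": [0.0, 100.0]})))
        out = proc.inverse_transform(np.array([[1.3]]))
        assert out.data["x"].iloc[0] == 100.0

    def test_dimension_mismatch_rejected(self, tiny_schema, tiny_table):
        proc = TabularProcessor(tiny_schema).fit(tiny_table)
        with pytest.raises(SchemaError, match="width"):
            proc.inverse_transform(np.zeros((2, 3)))

    def test_round_trip_identity(self, tiny_table):
        proc = TabularProcessor(tiny_table.schema)
        enc = proc.fit_transform(tiny_table)
        back = proc.inverse_transform(enc.values)
        for spec in tiny_table.schema.columns:
            a, b = tiny_table.data[spec.name], back.data[spec.name]
            if spec.kind == "numerical":
                assert np.allclose(a.astype(float), b.astype(float), atol=1e-9)
            else:
                assert (a == b).all()

    def test_sidecar_round_trip(self, tiny_table, tmp_path):
        proc = TabularProcessor(tiny_table.schema)
        enc = proc.fit_transform(tiny_table)
        enc.to_files(tmp_path / "m.csv", tmp_path / "m.json")
        import json

        proc2 = TabularProcessor.from_sidecar(
            json.loads((tmp_path / "m.json").read_text())
        )
        back = proc2.inverse_transform(enc.values)
        assert (back.data["grade"] == tiny_table.data["grade"]).all()


# --- property tests over random schemas -----------------------------------

@st.composite
def random_schema_and_table(draw):
    n_cols = draw(st.integers(1, 8))
    n_rows = draw(st.integers(1, 12))
    cols, data = [], {}
    rnd = np.random.default_rng(draw(st.integers(0, 2**32 - 1)))
    for i in range(n_cols):
        kind = draw(st.sampled_from(["numerical", "binary", "categorical"]))
        name = f"c{i}"
        if kind == "numerical":
            lo = draw(st.floats(-100, 100, allow_nan=False))
            hi = lo + draw(st.floats(0.5, 100, allow_nan=False))
            cols.append(ColumnSpec(name, kind, min=lo, max=hi))
            data[name] = np.round(rnd.uniform(lo, hi, n_rows), 3)
        elif kind == "binary":
            cols.append(ColumnSpec(name, kind, levels=("n", "y")))
            data[name] = rnd.choice(["n", "y"], n_rows).astype(object)
        else:
            k = draw(st.integers(3, 6))
            levels = tuple(f"L{j}" for j in range(k))
            cols.append(ColumnSpec(name, kind, levels=levels))
            data[name] = rnd.choice(levels, n_rows).astype(object)
    schema = CohortSchema(tuple(cols))
    return schema, CohortTable(schema, pd.DataFrame(data))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(random_schema_and_table())
def test_encoded_width_formula_and_round_trip(schema_table):
    """Encoded width = #num + #bin + sum(levels); decode(encode(x)) == x."""
    schema, table = schema_table
    expected = sum(
        len(c.levels) if c.kind == "categorical" else 1 for c in schema.columns
    )
    assert schema.encoded_width == expected
    proc = TabularProcessor(schema)
    enc = proc.fit_transform(table)
    assert enc.values.shape == (len(table), expected)
    assert enc.values.min() >= 0.0 and enc.values.max() <= 1.0
    back = proc.inverse_transform(enc.values)
    for spec in schema.columns:
        a, b = table.data[spec.name], back.data[spec.name]
        if spec.kind == "numerical":
            tol = 0.5 if spec.integer_valued else 1e-6 * (spec.max - spec.min)
            # degenerate (constant) columns decode to the stored min
            if proc.scaler_state[spec.name][0] == proc.scaler_state[spec.name][1]:
                continue
            assert np.allclose(a.astype(float), b.astype(float), atol=max(tol, 1e-9))
        else:
            assert (a == b).all()
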