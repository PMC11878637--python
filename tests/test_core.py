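import numpy as np
import pandas as pd
import pytest

from ewaskit.core import (
    MethylationMatrix,
    SampleSheet,
    align_samples,
    beta_m_convert,
    convert_variable_types,
    load_annotation,
    load_methylation_matrix,
    load_sample_sheet,
)


def _write_matrix(path, df):
    df.to_csv(path)


class TestMatrixIO:
    def test_load_small_beta_matrix(self, tmp_path):
        df = pd.DataFrame(
            [[0.1, 0.2], [0.5, 0.6], [0.9, 0.8]],
            index=["cg1", "cg2", "cg3"],
            columns=["A", "B"],
        )
        path = tmp_path / "m.csv"
        _write_matrix(path, df)
        mat = load_methylation_matrix(path, value_type="beta")
        assert mat.shape == (3, 2)
        assert mat.probe_ids == ["cg1", "cg2", "cg3"]

    def test_beta_out_of_bounds_names_probe(self, tmp_path):
        df = pd.DataFrame([[0.1], [1.2]], index=["cgA", "cgBAD"], columns=["S1"])
        path = tmp_path / "m.csv"
        _write_matrix(path, df)
        with pytest.raises(ValueError, match="cgBAD"):
            load_methylation_matrix(path, value_type="beta")

    def test_duplicate_probe_ids_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("probe,S1\ncg1,0.5\ncg1,0.6\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_methylation_matrix(path, value_type="beta")

    def test_write_read_round_trip_bit_identical(self, tmp_path, rng):
        vals = rng.random((100, 10))
        df = pd.DataFrame(vals, index=[f"cg{i}" for i in range(100)],
                          columns=[f"S{j}" for j in range(10)])
        mat = MethylationMatrix(df, value_type="beta")
        path = tmp_path / "round.parquet"
        mat.save(path)
        back = load_methylation_matrix(path, value_type="beta")
        assert np.array_equal(back.values.to_numpy(), vals)

    def test_non_numeric_entries_become_missing(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("probe,S1,S2\ncg1,0.5,oops\ncg2,0.2,0.3\n")
        mat = load_methylation_matrix(path, value_type="beta")
        assert np.isnan(mat.values.loc["cg1", "S2"])


class TestSampleSheet:
    def test_load_sheet_variables(self, tmp_path):
        rows = ["id,group,age,sex"] + [
            f"S{i},{'case' if i % 2 else 'control'},{30 + i},{'male' if i % 3 else 'female'}"
            for i in range(16)
        ]
        path = tmp_path / "sheet.csv"
        path.write_text("\n".join(rows) + "\n")
        sheet = load_sample_sheet(path)
        assert len(sheet) == 16
        assert sheet.variables == ["group", "age", "sex"]

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ValueError):
            load_sample_sheet(path)

    def test_round_trip_preserves_row_order(self, tmp_path):
        ids = ["S3", "S1", "S2"]
        sheet = SampleSheet(pd.DataFrame({"age": [3, 1, 2]}, index=pd.Index(ids, name="id")))
        path = tmp_path / "sheet.csv"
        sheet.save(path)
        assert load_sample_sheet(path).sample_ids == ids

    def test_duplicate_sample_ids_rejected(self, tmp_path):
        path = tmp_path / "sheet.csv"
        path.write_text("id,age\nS1,30\nS1,31\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_sample_sheet(path)


class TestVariableConversion:
    def test_factor_conversion_levels_and_reference(self):
        sheet = SampleSheet(
            pd.DataFrame({"sex": ["male", "female", "male", "female"]},
                         index=pd.Index(list("ABCD"), name="id"))
        )
        out = convert_variable_types(sheet, {"sex": "factor"})
        ft = out.factors["sex"]
        assert ft.levels == ["male", "female"]  # first-appearance order
        assert ft.reference == "male"
        out2 = convert_variable_types(sheet, {"sex": {"type": "factor", "reference": "female"}})
        assert out2.factors["sex"].reference == "female"

    def test_numeric_identity(self):
        sheet = SampleSheet(pd.DataFrame({"age": [1.0, 2.0]}, index=pd.Index(["A", "B"], name="id")))
        out = convert_variable_types(sheet, {"age": "numeric"})
        assert out.data["age"].tolist() == [1.0, 2.0]

    def test_unparseable_numeric_errors_with_values(self):
        sheet = SampleSheet(
            pd.DataFrame({"weight": ["1.5kg", "2.0"]}, index=pd.Index(["A", "B"], name="id"))
        )
        with pytest.raises(ValueError, match="1.5kg"):
            convert_variable_types(sheet, {"weight": "numeric"})


class TestAlignment:
    def _pair(self, matrix_ids, sheet_ids):
        mat = MethylationMatrix(
            pd.DataFrame(np.arange(2 * len(matrix_ids), dtype=float).reshape(2, -1),
                         index=["cg1", "cg2"], columns=matrix_ids),
            value_type="m",
        )
        sheet = SampleSheet(
            pd.DataFrame({"x": range(len(sheet_ids))}, index=pd.Index(sheet_ids, name="id"))
        )
        return mat, sheet

    def test_reorders_to_sheet_order(self):
        mat, sheet = self._pair(["B", "A", "C"], ["A", "B", "C"])
        m2, s2 = align_samples(mat, sheet)
        assert m2.sample_ids == ["A", "B", "C"] == s2.sample_ids

    def test_extra_sheet_sample_dropped(self, caplog):
        mat, sheet = self._pair(["A", "B"], ["A", "B", "Z"])
        m2, s2 = align_samples(mat, sheet)
        assert s2.sample_ids == ["A", "B"]

    def test_disjoint_errors(self):
        mat, sheet = self._pair(["A", "B"], ["C", "D"])
        with pytest.raises(ValueError, match="no common"):
            align_samples(mat, sheet)

    def test_idempotent(self):
        mat, sheet = self._pair(["B", "A"], ["A", "B"])
        m1, s1 = align_samples(mat, sheet)
        m2, s2 = align_samples(m1, s1)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(s1.data, s2.data)


class TestBetaMConversion:
    @pytest.mark.parametrize(
        "beta,m",
        [(0.5, 0.0), (0.8, 2.0), (2.0 / 3.0, 1.0)],
    )
    def test_analytic_values(self, beta, m):
        assert beta_m_convert(beta, "beta_to_m") == pytest.approx(m, abs=1e-12)
        assert beta_m_convert(m, "m_to_beta") == pytest.approx(beta, abs=1e-12)

    def test_round_trip_identity(self):
        beta = np.linspace(0.01, 0.99, 200)
        back = beta_m_convert(beta_m_convert(beta, "beta_to_m"), "m_to_beta")
        assert np.max(np.abs(back - beta)) < 1e-12

    def test_boundary_values_clipped_not_infinite(self):
        out = beta_m_convert(np.array([0.0, 1.0]), "beta_to_m")
        assert np.all(np.isfinite(out))

    def test_shape_preserved(self, rng):
        x = rng.random((3, 4)) * 0.8 + 0.1
        assert beta_m_convert(x, "beta_to_m").shape == (3, 4)


class TestAnnotation:
    def test_toy_manifest_loads_all_probes(self, manifest_csv):
        ann = load_annotation(manifest_csv, "450K")
        assert len(ann) == 5
        assert ann.attrs["genome_build"] == "hg19"

    def test_known_island_probe_record(self, manifest_csv):
        ann = load_annotation(manifest_csv, "450K")
        rec = ann.loc["cg00394712"]
        assert rec["chrom"] == "1"
        assert rec["island_relation"] == "Island"
        assert rec["gene"] == "NUDT17"
        assert rec["location"] == "TSS200"

    def test_empty_gene_marked_unassigned(self, manifest_csv):
        ann = load_annotation(manifest_csv, "450K")
        assert ann.loc["cg04529486", "gene"] == "/"

    def test_unknown_platform_lists_supported(self, manifest_csv):
        with pytest.raises(ValueError, match="EPICv2"):
            load_annotation(manifest_csv, "850K")
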