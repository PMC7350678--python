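"""Dialect parsing, missing-value policy and structured-table export."""

import numpy as np
import pandas as pd
import pytest

from autoplot import (DIALECTS, DialectError, FixtureSpec, MissingPolicy,
                      ValidationError, classify_value, generate_fixture,
                      merge_duplicate_names, parse_input, serialise_input,
                      write_structured_tables)
from conftest import make_design, make_table


class TestClassifyValue:
    @pytest.mark.parametrize("token", ["", "NA", "NaN", "N/F", "N/A", "  N/F "])
    def test_missing_tokens(self, token):
        assert np.isnan(classify_value(token, MissingPolicy(), "other_list"))

    def test_zero_kept_by_default(self):
        assert classify_value(0, MissingPolicy(), "compounds_in_columns") == 0.0
        assert classify_value("0", MissingPolicy(), "other_list") == 0.0

    def test_zero_as_missing_only_for_compounds_in_columns(self):
        policy = MissingPolicy(zeros_as_missing=True)
        assert np.isnan(classify_value(0, policy, "compounds_in_columns"))
        assert classify_value(0, policy, "other_list") == 0.0

    def test_threshold_boundary_is_kept(self):
        """The threshold must be reached: >= passes, below is missing."""
        policy = MissingPolicy(threshold=1000)
        assert np.isnan(classify_value(850, policy, "compound_discoverer"))
        assert classify_value(1000, policy, "compound_discoverer") == 1000.0
        # threshold only applies to the matrix-style dialects
        assert classify_value(850, policy, "other_list") == 850.0

    def test_comma_decimal_separator(self):
        assert classify_value("12,5", MissingPolicy(), "other_list") == 12.5

    def test_non_numeric_text_is_an_error(self):
        with pytest.raises(ValidationError, match="garbage"):
            classify_value("garbage", MissingPolicy(), "other_list")


class TestParsing:
    def test_other_list_minimal(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "Metabolite,RT,Filename,Area\n"
            "Lactate,,s1,100\nLactate,,s2,200\nCitrate,,s1,50\n"
        )
        table = parse_input(path, "other_list")
        assert len(table.data) == 3
        assert table.compounds == ["Lactate", "Citrate"]
        assert table.samples == ["s1", "s2"]

    def test_header_only_input_gives_empty_table(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("Metabolite,RT,Filename,Area\n")
        table = parse_input(path, "other_list")
        assert len(table.data) == 0

    def test_missing_essential_column_names_column_and_dialect(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("Compound,Filename\nX,s1\n")
        with pytest.raises(DialectError, match="tracefinder.*'Area'"):
            parse_input(path, "tracefinder")

    def test_tracefinder_headers_case_insensitive(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("compound , FILENAME ,area\nX,s1.raw,5\n")
        table = parse_input(path, "tracefinder")
        assert table.samples == ["s1"]  # trailing .raw stripped

    def test_compound_discoverer_sample_pattern(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "Compound,RT [min],Area: ctrl_1.raw (F1),Norm. Area: treat_1.raw (F2)\n"
            "Glucose,4.2,1e6,2e6\n"
        )
        table = parse_input(path, "compound_discoverer")
        assert table.samples == ["ctrl_1", "treat_1"]
        assert len(table.data) == 2

    def test_compound_discoverer_needs_sample_columns(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("Compound,RT [min],ctrl\nX,1.0,5\n")
        with pytest.raises(DialectError, match="no sample columns"):
            parse_input(path, "compound_discoverer")

    def test_semicolon_delimiter_sniffed(self, tmp_path):
        path = tmp_path / "t.txt"
        path.write_text("Metabolite;RT;Filename;Area\nX;1,5;s1;10,5\n")
        table = parse_input(path, "other_list")
        assert table.data["intensity"].iloc[0] == 10.5
        assert table.data["rt"].iloc[0] == 1.5

    def test_melting_is_lossless(self, tmp_path):
        """Wide inputs melt to exactly n_compounds x n_samples records."""
        path = tmp_path / "t.csv"
        path.write_text(
            "Sample,Ala,Gly,Ser\ns1,1,2,\ns2,4,NA,6\n"
        )
        table = parse_input(path, "compounds_in_columns")
        assert len(table.data) == 6
        assert table.n_missing == 2

    def test_excel_first_sheet(self, tmp_path):
        frame = pd.DataFrame(
            {"Metabolite": ["X"], "RT": [1.0], "Filename": ["s1"], "Area": [7.0]}
        )
        path = tmp_path / "t.xlsx"
        frame.to_excel(path, index=False)
        table = parse_input(path, "other_list")
        assert table.data["intensity"].iloc[0] == 7.0


class TestDuplicateNames:
    def test_merge_appends_rt_to_two_decimals(self):
        table = make_table({"Leucine": {"s1": 1.0}})
        table.data = pd.DataFrame(
            {
                "compound": ["Leucine", "Leucine"],
                "rt": [7.31, 9.02],
                "sample_id": ["s1", "s1"],
                "intensity": [1.0, 2.0],
            }
        )
        merged = merge_duplicate_names(table)
        assert sorted(merged.compounds) == ["Leucine@7.31", "Leucine@9.02"]

    def test_unique_names_unchanged(self):
        table = make_table({"Ala": {"s1": 1.0}, "Gly": {"s1": 2.0}}, rt=3.0)
        assert merge_duplicate_names(table).compounds == ["Ala", "Gly"]

    def test_duplicate_without_rt_is_hard_error(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("Metabolite,RT,Filename,Area\nX,,s1,1\nX,,s1,2\n")
        with pytest.raises(DialectError, match="X"):
            parse_input(path, "other_list")

    def test_merged_names_are_unique(self, tmp_path):
        rows = ["Metabolite,RT,Filename,Area"]
        for name, rts in (("A", (1.0, 2.0)), ("B", (3.3, 4.4)), ("C", (5.0, 6.0))):
            for rt in rts:
                rows.append(f"{name},{rt},s1,10")
        path = tmp_path / "t.csv"
        path.write_text("\n".join(rows) + "\n")
        table = merge_duplicate_names(parse_input(path, "other_list"))
        names = table.compounds
        assert len(names) == len(set(names)) == 6


@pytest.mark.parametrize("dialect", DIALECTS)
def test_dialect_round_trip(dialect, tmp_path):
    """generate -> parse -> serialise -> parse yields an identical table."""
    spec = FixtureSpec(n_compounds=6, n_conditions=2,
                       n_experimental_replicates=3, missing_rate=0.1, seed=5)
    fix = generate_fixture(spec, dialect, tmp_path / "first")
    table1 = parse_input(fix.paths["input"], dialect)
    second = tmp_path / f"again.{ 'csv' }"
    serialise_input(table1, dialect, second)
    table2 = parse_input(second, dialect)
    merged1 = table1.wide().sort_index()
    merged2 = table2.wide().sort_index()
    pd.testing.assert_frame_equal(merged1, merged2)
    assert table1.n_missing == table2.n_missing


def test_missing_never_imputed(quant_fixture):
    """count(MISSING) after parsing equals the blank cells of the fixture."""
    table = parse_input(quant_fixture.paths["input"], "other_list")
    expected = int(quant_fixture.table.data["intensity"].isna().sum())
    assert table.n_missing == expected
    assert expected > 0


class TestStructuredTables:
    def test_summary_shape_and_missing_export(self, tmp_path):
        table = make_table(
            {
                "Ala": {"a1": 1.0, "a2": 3.0, "b1": 5.0, "b2": np.nan},
                "Gly": {"a1": 2.0, "a2": 2.0, "b1": 4.0, "b2": 8.0},
            }
        )
        design = make_design({"A": ["a1", "a2"], "B": ["b1", "b2"]})
        paths = write_structured_tables(table, design, tmp_path)
        summary = pd.read_csv(tmp_path / "Tables" / "summary_per_condition.csv")
        assert len(summary) == 4  # 2 compounds x 2 conditions
        assert summary.loc[
            (summary["compound"] == "Ala") & (summary["condition"] == "B"), "n"
        ].iloc[0] == 1
        # MISSING exported as empty cells, never 0
        matrix = (tmp_path / "Tables" / "data_matrix.csv").read_text()
        ala_line = next(l for l in matrix.splitlines() if l.startswith("Ala"))
        assert ala_line.endswith(",")  # b2 missing -> empty trailing cell
        assert ",0," not in ala_line and not ala_line.endswith(",0")
        assert (tmp_path / "Inputs" / "cleaned_input.csv").exists()
        assert all(p.exists() for p in paths)

    def test_wide_export_round_trip(self, tmp_path):
        table = make_table(
            {
                "Ala": {"s1": 1.5, "s2": np.nan},
                "Gly": {"s1": 2.0, "s2": 4.0},
            }
        )
        design = make_design({"A": ["s1"], "B": ["s2"]})
        write_structured_tables(table, design, tmp_path)
        back = parse_input(tmp_path / "Tables" / "data_matrix.csv", "other_matrix")
        pd.testing.assert_frame_equal(back.wide(), table.wide())
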