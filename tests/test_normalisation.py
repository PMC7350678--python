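"""External / internal / Total-Peak-Sum normalisation identities."""

import numpy as np
import pandas as pd
import pytest

from autoplot import (NormalisationConfig, ValidationError, external_correct,
                      internal_correct, total_peak_sum)
from conftest import make_design, make_table


class TestExternal:
    def test_absolute_divides(self):
        table = make_table({"Ala": {"s1": 1000.0}})
        design = make_design({"A": ["s1"]}, correction={"s1": 2.0})
        out = external_correct(table, design, "absolute")
        assert out.data["intensity"].iloc[0] == 500.0

    def test_relative_formula(self):
        """[100, 200] with c=[1, 3] -> [200, 133.33]: I/c times mean(c)=2."""
        table = make_table({"Ala": {"s1": 100.0, "s2": 200.0}})
        design = make_design({"A": ["s1"], "B": ["s2"]},
                             correction={"s1": 1.0, "s2": 3.0})
        out = external_correct(table, design, "relative")
        values = dict(zip(out.data["sample_id"], out.data["intensity"]))
        assert values["s1"] == pytest.approx(200.0)
        assert values["s2"] == pytest.approx(400.0 / 3.0)

    def test_relative_with_constant_correction_is_identity(self):
        table = make_table({"Ala": {"s1": 5.0, "s2": 9.0}})
        design = make_design({"A": ["s1", "s2"]},
                             correction={"s1": 4.2, "s2": 4.2})
        out = external_correct(table, design, "relative")
        np.testing.assert_allclose(out.data["intensity"], table.data["intensity"])

    def test_missing_correction_value_is_error(self):
        table = make_table({"Ala": {"s1": 1.0}})
        design = make_design({"A": ["s1"]})
        with pytest.raises(ValidationError, match="s1"):
            external_correct(table, design, "absolute")


class TestInternal:
    def test_standards_are_summed(self):
        table = make_table({"A": {"s1": 100.0}, "B": {"s1": 300.0},
                            "X": {"s1": 800.0}})
        out = internal_correct(table, ["A", "B"], "absolute")
        assert dict(zip(out.data["compound"],
                        out.data["intensity"]))["X"] == 2.0  # 800 / 400

    def test_constant_standard_relative_is_identity(self):
        table = make_table({"IS": {"s1": 50.0, "s2": 50.0},
                            "X": {"s1": 3.0, "s2": 7.0}})
        out = internal_correct(table, ["IS"], "relative")
        np.testing.assert_allclose(out.data["intensity"], table.data["intensity"])

    def test_doubling_standard_halves_absolute_result(self):
        base = make_table({"IS": {"s1": 10.0}, "X": {"s1": 40.0}})
        doubled = make_table({"IS": {"s1": 20.0}, "X": {"s1": 40.0}})
        a = internal_correct(base, ["IS"], "absolute")
        b = internal_correct(doubled, ["IS"], "absolute")
        xa = a.data.set_index("compound")["intensity"]["X"]
        xb = b.data.set_index("compound")["intensity"]["X"]
        assert xb == pytest.approx(xa / 2)

    def test_partially_missing_standard_warns_and_contributes_zero(self):
        table = make_table({"A": {"s1": 100.0, "s2": np.nan},
                            "B": {"s1": 100.0, "s2": 50.0},
                            "X": {"s1": 100.0, "s2": 100.0}})
        with pytest.warns(UserWarning, match="s2"):
            out = internal_correct(table, ["A", "B"], "absolute")
        values = out.data.set_index(["compound", "sample_id"])["intensity"]
        assert values[("X", "s1")] == pytest.approx(0.5)
        assert values[("X", "s2")] == pytest.approx(2.0)

    def test_all_standards_missing_in_a_sample_is_error(self):
        table = make_table({"A": {"s1": 1.0, "s2": np.nan},
                            "X": {"s1": 2.0, "s2": 3.0}})
        with pytest.warns(UserWarning), pytest.raises(ValidationError, match="s2"):
            internal_correct(table, ["A"], "absolute")

    def test_unknown_standard_is_error(self):
        table = make_table({"X": {"s1": 1.0}})
        with pytest.raises(ValidationError, match="IS"):
            internal_correct(table, ["IS"], "absolute")


class TestTotalPeakSum:
    def test_sum_skips_missing(self):
        table = make_table({"A": {"s1": 1.0}, "B": {"s1": 2.0},
                            "C": {"s1": 3.0}, "D": {"s1": np.nan}})
        out = total_peak_sum(table, "absolute")
        values = out.data.set_index("compound")["intensity"]
        assert values["C"] == pytest.approx(0.5)  # 3 / 6

    def test_relative_preserves_grand_mean_per_sample(self):
        """After relative TPS every sample's total equals the grand mean of
        the original per-sample totals."""
        table = make_table({
            "A": {"s1": 1.0, "s2": 10.0, "s3": 5.0},
            "B": {"s1": 3.0, "s2": 30.0, "s3": 5.0},
        })
        out = total_peak_sum(table, "relative")
        totals = out.data.groupby("sample_id")["intensity"].sum()
        grand_mean = table.data.groupby("sample_id")["intensity"].sum().mean()
        np.testing.assert_allclose(totals, grand_mean)

    def test_single_sample_relative_unchanged(self):
        table = make_table({"A": {"s1": 2.0}, "B": {"s1": 5.0}})
        out = total_peak_sum(table, "relative")
        np.testing.assert_allclose(out.data["intensity"], [2.0, 5.0])

    def test_all_missing_sample_is_error(self):
        table = make_table({"A": {"s1": 1.0, "s2": np.nan}})
        with pytest.raises(ValidationError, match="s2"):
            total_peak_sum(table, "absolute")


class TestInvariantsAndConfig:
    def test_relative_tps_preserves_grand_total_on_complete_data(self):
        """With c_s equal to the per-sample totals (Total Peak Sum), relative
        normalisation redistributes but conserves the grand total exactly."""
        rng = np.random.default_rng(42)
        samples = [f"s{i}" for i in range(6)]
        table = make_table({
            f"M{j}": {s: float(v) for s, v in zip(samples, rng.uniform(1, 100, 6))}
            for j in range(10)
        })
        out = total_peak_sum(table, "relative")
        assert out.data["intensity"].sum() == pytest.approx(
            table.data["intensity"].sum(), rel=1e-12)

    def test_missing_count_invariant_under_normalisation(self):
        table = make_table({"A": {"s1": 1.0, "s2": np.nan},
                            "B": {"s1": 2.0, "s2": 3.0}})
        design = make_design({"A": ["s1"], "B": ["s2"]},
                             correction={"s1": 2.0, "s2": 3.0})
        for out in (external_correct(table, design, "absolute"),
                    external_correct(table, design, "relative"),
                    total_peak_sum(table, "relative")):
            assert out.n_missing == table.n_missing == 1

    def test_order_of_operations_matters(self):
        """internal-before-external differs from external-before-internal
        when relative modes see unequal correction values."""
        table = make_table({"IS": {"s1": 10.0, "s2": 30.0},
                            "X": {"s1": 100.0, "s2": 100.0}})
        design = make_design({"A": ["s1"], "B": ["s2"]},
                             correction={"s1": 1.0, "s2": 2.0})
        before = internal_correct(
            external_correct(table, design, "relative"), ["IS"], "relative")
        after = external_correct(
            internal_correct(table, ["IS"], "relative"), design, "relative")
        xa = before.data.set_index(["compound", "sample_id"])["intensity"]
        xb = after.data.set_index(["compound", "sample_id"])["intensity"]
        assert not np.allclose(xa[("X", "s1")], xb[("X", "s1")])

    def test_config_mutual_exclusions(self):
        with pytest.raises(ValidationError):
            NormalisationConfig(internal_mode="absolute")  # no standards
        with pytest.raises(ValidationError):
            NormalisationConfig(internal_mode="absolute",
                                internal_standards=("IS",), total_peak_sum=True)
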