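"""Centile tables: generation, I/O, scoring, internal consistency."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lmsref import bccg, tables


ALL_TABLES = [f"{v}_{m}_{s}" for v in ("fmi", "ffmi")
              for m in ("sf", "mfbia", "dxa") for s in ("female", "male")]


class TestPackagedTables:
    @pytest.mark.parametrize("name", ALL_TABLES)
    def test_loads_with_valid_shape(self, name):
        t = tables.load_reference_table(name)
        assert t["age"].iloc[0] == 5.0 and t["age"].iloc[-1] == 18.0
        assert len(t) in (26, 27)        # published FFMI blocks omit 16.5 y
        assert set("LMS") <= set(t.columns)
        assert len([c for c in t.columns if c.startswith("P")]) == 11

    def test_fmi_tables_have_full_halfyear_grid(self):
        t = tables.load_reference_table("fmi_dxa_female")
        np.testing.assert_allclose(t["age"], np.arange(5.0, 18.01, 0.5))

    def test_rows_strictly_increasing_across_levels(self):
        for name in ALL_TABLES:
            t = tables.load_reference_table(name)
            cent = t[[c for c in t.columns if c.startswith("P")]]
            assert (cent.diff(axis=1).iloc[:, 1:] > 0).all().all(), name

    def test_p50_equals_m(self):
        for name in ALL_TABLES:
            t = tables.load_reference_table(name)
            np.testing.assert_array_equal(t["P50"], t["M"], err_msg=name)

    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError, match="available"):
            tables.load_reference_table("bmi_dxa_female")


class TestTableIO:
    def test_write_read_roundtrip(self, tmp_path):
        t = tables.load_reference_table("fmi_sf_male")
        path = tmp_path / "t.csv"
        tables.write_lms_table(t, path)
        back = tables.read_lms_table(path)
        pd.testing.assert_frame_equal(t, back)

    def test_missing_required_column_rejected(self):
        buf = io.StringIO("age,L,M\n5,1,10\n")
        with pytest.raises(ValueError, match="S"):
            tables.read_lms_table(buf)

    def test_nonmonotone_ages_rejected_with_row(self):
        buf = io.StringIO("age,L,M,S\n5,1,10,0.1\n5,1,10,0.1\n")
        with pytest.raises(ValueError, match="row 3"):
            tables.read_lms_table(buf)

    def test_unicode_minus_normalized(self):
        buf = io.StringIO("age,L,M,S\n5,−1.106,4.07,0.202\n")
        t = tables.read_lms_table(buf)
        assert t["L"].iloc[0] == -1.106


class TestMakeCentileTable:
    def test_constant_curve_normal_special_case(self, constant_lms_curve):
        t = tables.make_centile_table(constant_lms_curve, ages=[6.0, 10.0])
        # L=1, M=10, S=0.1 is exactly normal: P97 = 10*(1 + 0.1*1.880794)
        assert t["P97"].iloc[0] == pytest.approx(11.88, abs=0.005)
        assert (t["P50"] == t["M"]).all()

    def test_rows_monotone_and_quarter_year_step(self, constant_lms_curve):
        t = tables.make_centile_table(constant_lms_curve,
                                      ages=[5.0, 18.0], step=0.25)
        assert len(t) == 53
        cent = t[[c for c in t.columns if c.startswith("P")]]
        assert (cent.diff(axis=1).iloc[:, 1:] >= 0).all().all()

    def test_printed_age5_row_reproduced(self):
        """A curve interpolating the published female DXA FMI parameters
        regenerates the printed 97th centile at age 5."""
        from lmsref.simulate import TruthCurves

        class _Adapter:
            def __init__(self):
                self.tc = TruthCurves(
                    tables.load_reference_table("fmi_dxa_female"))
            def predict_params(self, ages):
                return self.tc.params(ages)

        t = tables.make_centile_table(_Adapter(), ages=[5.0])
        assert t["P97"].iloc[0] == pytest.approx(6.66, abs=0.01)

    def test_refuses_out_of_range_age(self, constant_lms_curve):
        with pytest.raises(ValueError):
            tables.make_centile_table(constant_lms_curve, ages=[3.0])


@pytest.fixture(scope="module")
def female_dxa_fmi():
    return tables.load_reference_table("fmi_dxa_female")


class TestScoring:

    def test_published_cell_scores_at_97th(self, female_dxa_fmi):
        res = tables.zscore_against_table(6.66, 5.0, female_dxa_fmi)
        assert res["z"] == pytest.approx(1.88, abs=0.01)
        assert res["centile"] == pytest.approx(97.0, abs=0.1)

    def test_median_scores_zero_at_tabulated_age(self, female_dxa_fmi):
        m = female_dxa_fmi.loc[female_dxa_fmi["age"] == 8.0, "M"].iloc[0]
        assert tables.zscore_against_table(m, 8.0, female_dxa_fmi)["z"] == \
            pytest.approx(0.0, abs=1e-12)

    def test_interpolated_median_scores_zero_between_rows(self, female_dxa_fmi):
        p = tables.interpolate_lms(female_dxa_fmi, 5.25)
        assert tables.zscore_against_table(p.M, 5.25, female_dxa_fmi)["z"] == \
            pytest.approx(0.0, abs=1e-12)

    def test_tabulated_age_returns_exact_parameters(self, female_dxa_fmi):
        p = tables.interpolate_lms(female_dxa_fmi, 5.0)
        assert (p.L, p.M, p.S) == (-1.106, 4.07, 0.202)

    def test_zscore_roundtrip_at_tabulated_age(self, female_dxa_fmi):
        p = tables.interpolate_lms(female_dxa_fmi, 12.0)
        for z in (-2.0, -0.5, 1.0, 2.5):
            y = bccg.value_from_z(z, p)
            got = tables.zscore_against_table(y, 12.0, female_dxa_fmi)["z"]
            assert got == pytest.approx(z, abs=1e-9)

    def test_refuses_out_of_range_with_hint(self, female_dxa_fmi):
        with pytest.raises(ValueError, match="nearest"):
            tables.zscore_against_table(5.0, 19.0, female_dxa_fmi)
        with pytest.raises(ValueError):
            tables.zscore_against_table(-1.0, 8.0, female_dxa_fmi)


class TestConsistencyChecker:
    def test_verified_female_rows_within_rounding(self):
        """Rows whose printed centiles agree with their printed L/M/S to
        2-decimal rounding."""
        checks = [("fmi_dxa_female", 5.0), ("fmi_dxa_female", 10.0),
                  ("fmi_sf_female", 5.0), ("fmi_sf_female", 10.0),
                  ("ffmi_sf_female", 5.0), ("ffmi_sf_female", 10.0)]
        for name, age in checks:
            t = tables.load_reference_table(name)
            rep = tables.check_table_consistency(t)
            row_max = rep["row_max"][t["age"] == age].iloc[0]
            assert row_max <= 0.02, (name, age, row_max)

    def test_whole_mfbia_female_fmi_table_consistent(self):
        t = tables.load_reference_table("fmi_mfbia_female")
        rep = tables.check_table_consistency(t)
        assert rep["max_abs"] <= 0.02

    def test_corrupted_cell_flagged_with_its_deviation(self):
        t = tables.load_reference_table("fmi_mfbia_female").copy()
        t.loc[4, "P75"] += 0.5
        rep = tables.check_table_consistency(t)
        assert rep["deviation"].loc[4, "P75"] == pytest.approx(0.5, abs=0.02)
        assert rep["row_max"].idxmax() == 4

    def test_reports_known_inconsistent_blocks(self):
        """Some printed male/FFMI blocks disagree with their own printed
        parameters far beyond rounding; the checker reports, never repairs."""
        rep = tables.check_table_consistency(
            tables.load_reference_table("fmi_dxa_male"))
        assert rep["max_abs"] > 0.5

    def test_requires_centile_columns(self):
        with pytest.raises(ValueError, match="centile"):
            tables.check_table_consistency(
                pd.DataFrame({"age": [5.0], "L": [1.0], "M": [10.0],
                              "S": [0.1]}))
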