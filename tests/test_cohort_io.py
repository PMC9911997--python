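"""Cohort CSV loading, validation, stratification and summaries."""

import numpy as np
import pandas as pd
import pytest

from colrpph import read_cohort_csv, stratify, summarize
from colrpph.cohort import SchemaError

from conftest import make_rows


def test_empty_file_with_header_yields_empty_cohort(toy_csv, header):
    table = read_cohort_csv(toy_csv(header))
    assert len(table) == 0
    assert table.validation.n_excluded == 0


def test_blank_outcome_row_is_excluded_and_counted(toy_csv, header):
    rows = (
        "400,vaginal,200,128,4.5,128,96,190,84\n"
        ",vaginal,210,130,4.2,120,90,180,80\n"
        "600,elective_cs,180,125,4.8,135,100,170,75\n"
    )
    table = read_cohort_csv(toy_csv(header + rows))
    assert len(table) == 2
    assert table.validation.n_excluded == 1
    assert table.validation.exclusions == {"missing_mbl": 1}


def test_unparseable_numeric_cell_excludes_row_not_crash(toy_csv, header):
    rows = (
        "400,vaginal,200,128,4.5,128,96,190,84\n"
        "500,vaginal,not_a_number,130,4.2,120,90,180,80\n"
    )
    table = read_cohort_csv(toy_csv(header + rows))
    assert len(table) == 1
    assert table.validation.exclusions == {"missing_platelets_pre": 1}


def test_three_modes_give_unit_stratum_counts(toy_csv, header):
    rows = (
        "400,vaginal,200,128,4.5,128,96,190,84\n"
        "500,elective_cs,210,130,4.2,120,90,180,80\n"
        "600,unplanned_cs,180,125,4.8,135,100,170,75\n"
    )
    table = read_cohort_csv(toy_csv(header + rows))
    counts = table.df["delivery_mode"].value_counts()
    assert tuple(counts[m] for m in ("vaginal", "elective_cs", "unplanned_cs")) == (1, 1, 1)


def test_missing_mapped_column_raises_named_schema_error(toy_csv):
    p = toy_csv("mbl,delivery_mode,platelets_pre\n400,vaginal,200\n")
    with pytest.raises(SchemaError, match="hemoglobin"):
        read_cohort_csv(p)


def test_column_map_renames_source_columns(toy_csv):
    text = (
        "MBL.ml,MODE,PLT,HB,FIB,FII,FXIII\n"
        "400,vaginal,200,128,4.5,128,96\n"
    )
    cmap = {
        "mbl": "MBL.ml", "delivery_mode": "MODE", "platelets_pre": "PLT",
        "hemoglobin_pre": "HB", "fibrinogen_pre": "FIB",
        "fii_pre": "FII", "fxiii_pre": "FXIII",
    }
    table = read_cohort_csv(toy_csv(text), column_map=cmap)
    assert len(table) == 1
    assert table.df.loc[0, "platelets_pre"] == 200


def test_nonpositive_optional_lab_becomes_missing(toy_csv, header):
    rows = "400,vaginal,200,128,4.5,128,96,-5,84\n"
    table = read_cohort_csv(toy_csv(header + rows))
    assert len(table) == 1
    assert np.isnan(table.df.loc[0, "platelets_post"])
    assert table.validation.n_optional_set_missing == 1


def test_stratify_identity_all_and_unknown(toy_csv, header):
    table = read_cohort_csv(toy_csv(header + make_rows(6, mode="vaginal")))
    assert len(stratify(table, "all")) == len(table)
    assert len(stratify(table, "vaginal")) == len(table)
    assert len(stratify(table, "elective_cs")) == 0
    with pytest.raises(ValueError, match="unknown delivery mode"):
        stratify(table, "forceps")


def test_stratify_partitions_cohort(default_cohort):
    sizes = [len(stratify(default_cohort, m))
             for m in ("vaginal", "elective_cs", "unplanned_cs")]
    assert sum(sizes) == len(default_cohort)
    # pooled cesarean = elective + unplanned
    assert len(stratify(default_cohort, "cesarean")) == sizes[1] + sizes[2]


def test_summarize_median_and_constant_column(toy_csv, header):
    rows = (
        "300,vaginal,200,128,4.5,128,96,190,84\n"
        "350,vaginal,210,130,4.2,120,96,180,80\n"
        "500,vaginal,180,125,4.8,135,96,170,75\n"
    )
    s = summarize(read_cohort_csv(toy_csv(header + rows)))
    mbl = s[(s.variable == "mbl") & (s.stratum == "vaginal")].iloc[0]
    assert mbl["median"] == 350
    fx = s[(s.variable == "fxiii_pre") & (s.stratum == "vaginal")].iloc[0]
    assert (fx["median"], fx["q1"], fx["q3"], fx["min"], fx["max"]) == (96,) * 5


def test_summarize_quartiles_linear_interpolation(toy_csv, header):
    # type-7 rule on (100, 200, 300, 400): q1 = 175, q3 = 325
    rows = "".join(
        f"{v},vaginal,200,128,4.5,128,96,190,84\n" for v in (100, 200, 300, 400)
    )
    s = summarize(read_cohort_csv(toy_csv(header + rows)))
    mbl = s[(s.variable == "mbl") & (s.stratum == "vaginal")].iloc[0]
    assert mbl["q1"] == pytest.approx(175.0)
    assert mbl["q3"] == pytest.approx(325.0)
    assert mbl["q1"] <= mbl["median"] <= mbl["q3"]


def test_summarize_empty_cohort_errors(toy_csv, header):
    table = read_cohort_csv(toy_csv(header))
    with pytest.raises(ValueError, match="empty"):
        summarize(table)


def test_summary_invariants_on_synthetic_cohort(default_cohort):
    s = summarize(default_cohort)
    num = s[s.variable != "n_subjects"].dropna(subset=["median"])
    assert (num["q1"] <= num["median"] + 1e-12).all()
    assert (num["median"] <= num["q3"] + 1e-12).all()
    assert (num["min"] <= num["q1"] + 1e-12).all()
    assert (num["q3"] <= num["max"] + 1e-12).all()


def test_csv_round_trip_preserves_retained_fields(tmp_path, default_cohort):
    out = tmp_path / "roundtrip.csv"
    default_cohort.to_csv(out)
    back = read_cohort_csv(out)
    assert len(back) == len(default_cohort)
    for col in ("mbl", "platelets_pre", "fxiii_post"):
        np.testing.assert_allclose(
            back.df[col].to_numpy(dtype=float),
            default_cohort.df[col].to_numpy(dtype=float),
            rtol=0, atol=0,
        )
    assert (back.df["delivery_mode"] == default_cohort.df["delivery_mode"]).all()
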