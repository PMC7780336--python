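"""Case classification and CMI computation."""

import numpy as np
import pandas as pd
import pytest

import casemix as cx
from casemix.cmi import ClassificationError, classify, monthly_cmi
from conftest import make_records


@pytest.mark.parametrize(
    "icd,cpt,los,expected",
    [
        ("A09", "", 1, ("medical", "short")),
        ("A09", "", 0, ("medical", "short")),
        ("A09", "", 2, ("medical", "medium")),
        ("J18.0", "", 15, ("medical", "medium")),
        ("J18.0", "", 16, ("medical", "long")),
        ("", "F9410L1", 2, ("surgical", None)),
        ("C50", "F9410L1", 3, ("mixed", "medium")),
    ],
)
def test_classification_boundaries(icd, cpt, los, expected):
    rec = {"record_id": "R0", "icd_code": icd, "cpt_codes": cpt, "length_of_stay": los}
    cls = classify(rec)
    assert (cls.case_type, cls.stay_class) == expected


def test_classification_requires_some_code():
    with pytest.raises(ClassificationError):
        classify({"record_id": "R0", "icd_code": "", "cpt_codes": "", "length_of_stay": 1})


def test_case_weight_components(toy_weights):
    surgical = {"record_id": "R1", "icd_code": "", "cpt_codes": "P1|P2", "length_of_stay": 2}
    assert cx.case_weight(surgical, toy_weights, "surgical") == pytest.approx(1.7)
    medical = {"record_id": "R2", "icd_code": "BBB", "cpt_codes": "", "length_of_stay": 5}
    assert cx.case_weight(medical, toy_weights, "medical") == pytest.approx(1.0)
    mixed = {"record_id": "R3", "icd_code": "CCC", "cpt_codes": "P1", "length_of_stay": 5}
    assert cx.case_weight(mixed, toy_weights, "all") == [pytest.approx(2.0), pytest.approx(1.2)]


def test_mixed_all_components_pools_both_contributions(toy_weights):
    # equal numbers of medical (CCC, w=2.0) and surgical (P1, w=1.2)
    # contributions pool to their plain average
    rec = make_records([{"icd": "CCC", "cpt": "P1", "los": 5} for _ in range(10)])
    series = monthly_cmi(rec, toy_weights, "mixed", component="all")
    point = series.dropna().iloc[0]
    assert point["cmi"] == pytest.approx((2.0 + 1.2) / 2)
    assert point["n_cases"] == 10
    med = monthly_cmi(rec, toy_weights, "mixed", component="medical").dropna().iloc[0]
    surg = monthly_cmi(rec, toy_weights, "mixed", component="surgical").dropna().iloc[0]
    assert med["cmi"] == pytest.approx(2.0)
    assert surg["cmi"] == pytest.approx(1.2)


def test_constant_weight_population_gives_constant_cmi(toy_weights):
    rows = [{"icd": "BBB", "month": f"2013-{m:02d}"} for m in range(1, 13) for _ in range(4)]
    series = monthly_cmi(make_records(rows), toy_weights, "medical")
    assert np.allclose(series["cmi"], 1.0)


def test_two_weight_month_averages(toy_weights):
    rec = make_records([{"icd": "AAA"}, {"icd": "CCC", "charge": 2e6}])
    series = monthly_cmi(rec, toy_weights, "medical").dropna()
    assert series["cmi"].iloc[0] == pytest.approx((0.5 + 2.0) / 2)


def test_monthly_cmi_equals_brute_force_oracle(records, weight_table):
    sub = records.head(4000)
    series = monthly_cmi(sub, weight_table, "medical", stay="medium")
    # independent brute force over raw rows
    totals, counts = {}, {}
    for _, r in sub.iterrows():
        if r["cpt_codes"] or not r["icd_code"]:
            continue
        if not (2 <= r["length_of_stay"] <= 15):
            continue
        if r["icd_code"] in ("Z51.1", "Z51.2"):
            continue
        m = pd.Period(r["discharge_date"], "M")
        w = weight_table.weight("medium", r["icd_code"])
        totals[m] = totals.get(m, 0.0) + w
        counts[m] = counts.get(m, 0) + 1
    for _, row in series.dropna().iterrows():
        m = row["month"]
        assert row["cmi"] == pytest.approx(totals[m] / counts[m], rel=1e-12)
        assert row["n_cases"] == counts[m]


def test_permutation_invariance(records, weight_table, medical_series):
    shuffled = records.sample(frac=1.0, random_state=0).reset_index(drop=True)
    again = monthly_cmi(shuffled, weight_table, "medical")
    pd.testing.assert_series_equal(medical_series["cmi"], again["cmi"])


def test_all_stay_cmi_is_case_weighted_stratum_combination(records, weight_table, medical_series):
    parts = {
        s: monthly_cmi(records, weight_table, "medical", stay=s)
        for s in ("short", "medium", "long")
    }
    num = sum((p["cmi"] * p["n_cases"]).fillna(0.0) for p in parts.values())
    den = sum(p["n_cases"] for p in parts.values())
    combined = num / den.replace(0, np.nan)
    valid = medical_series["cmi"].notna()
    assert np.allclose(medical_series.loc[valid, "cmi"], combined[valid], rtol=0, atol=1e-12)


def test_cmi_bounded_by_weight_range(records, weight_table, medical_series):
    med = weight_table.table[weight_table.table["stratum"].isin(["short", "medium", "long"])]
    lo, hi = med["weight"].min(), med["weight"].max()
    valid = medical_series["cmi"].dropna()
    assert (valid >= lo - 1e-12).all() and (valid <= hi + 1e-12).all()


def test_excluding_low_weight_code_raises_cmi(toy_weights):
    rows = [{"icd": "AAA"} for _ in range(30)] + [{"icd": "CCC"} for _ in range(30)]
    rec = make_records(rows)
    base = monthly_cmi(rec, toy_weights, "medical").dropna()["cmi"].iloc[0]
    # drop the w=0.5 code (below the mixture CMI of 1.25): CMI must rise
    without = monthly_cmi(rec[rec["icd_code"] != "AAA"], toy_weights, "medical").dropna()["cmi"].iloc[0]
    assert without > base
    # and excluding the high-weight code lowers it
    without_high = monthly_cmi(rec[rec["icd_code"] != "CCC"], toy_weights, "medical").dropna()["cmi"].iloc[0]
    assert without_high < base


def test_chemotherapy_cases_excluded_by_default(toy_weights):
    table = toy_weights.table.copy()
    table.loc[len(table)] = ["short", "Z51.1", 50, 2.5e5, 0.25, False]
    wt = cx.WeightTable(table=table, reference_cost_medical=1e6)
    rows = [{"icd": "Z51.1", "los": 1} for _ in range(20)] + [{"icd": "BBB"} for _ in range(10)]
    rec = make_records(rows)
    series = monthly_cmi(rec, wt, "medical").dropna()
    assert series["cmi"].iloc[0] == pytest.approx(1.0)
    assert series["n_cases"].iloc[0] == 10
    kept = monthly_cmi(rec, wt, "medical", exclude_chemo=False).dropna()
    assert kept["cmi"].iloc[0] == pytest.approx((20 * 0.25 + 10 * 1.0) / 30)
    assert kept["n_cases"].iloc[0] == 30


def test_zero_case_months_reported_missing(toy_weights):
    rec = make_records([{"icd": "BBB", "month": "2013-01"}, {"icd": "BBB", "month": "2013-04"}])
    series = monthly_cmi(rec, toy_weights, "medical")
    assert len(series) == 4
    feb = series[series["month"] == pd.Period("2013-02", "M")].iloc[0]
    assert np.isnan(feb["cmi"]) and feb["n_cases"] == 0


def test_series_round_trip(tmp_path, medical_series):
    path = tmp_path / "series.csv"
    cx.cmi.write_series(medical_series, path)
    back = cx.cmi.read_series(path)
    assert back.attrs["stratum"]["case_type"] == "medical"
    pd.testing.assert_frame_equal(
        back, medical_series.reset_index(drop=True), check_exact=False, rtol=1e-12
    )


def test_descriptive_table_composition(records):
    table = cx.descriptive_table(records)
    all_years = table[(table["ownership"] == "all") & (table["year"] == "all")]
    by_group = all_years.set_index("group")
    total = by_group.loc["total", "n_cases"]
    parts = by_group.loc[["medical_all", "surgical", "mixed"], "n_cases"].sum()
    assert parts == total
    # surgical cases carry ~1.1 procedures each in the study-like scenario
    assert 1.0 <= by_group.loc["surgical", "case_procedure_ratio"] <= 1.2
    assert 1.3 <= by_group.loc["mixed", "case_procedure_ratio"] <= 1.7
    # column percentages are of the scope total
    assert by_group.loc["total", "pct"] == 100.0
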