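"""Rates, differences, significance stars, cross-tabs and flow tables."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import moudflow as mf
from moudflow.disparity import stars_for
from moudflow.errors import ContractError, ValidationError
from moudflow.table import AdmissionTable

from conftest import make_tiny_config


def _table(rows):
    cb = mf.VariableCodebook([
        mf.VariableDef("SERVICES", "categorical", ("S1", "S2", "Unknown")),
        mf.VariableDef("LIVARAG", "categorical", ("GroupA", "GroupB", "Unknown")),
        mf.VariableDef("METHUSE", "categorical", ("No", "Yes", "Unknown")),
    ])
    df = pd.DataFrame(rows, columns=["SERVICES", "LIVARAG", "METHUSE"])
    return AdmissionTable(df, cb)


def test_rate_by_counted_fixture():
    rows = (
        [["S1", "GroupA", "Yes"]] * 3 + [["S1", "GroupA", "No"]] * 2  # A: 3/5
        + [["S1", "GroupB", "Yes"]] * 1 + [["S1", "GroupB", "No"]] * 4  # B: 1/5
    )
    rates = mf.rate_by(_table(rows), "LIVARAG").set_index("level")
    assert rates.loc["GroupA", "rate_percent"] == pytest.approx(60.0)
    assert rates.loc["GroupB", "rate_percent"] == pytest.approx(20.0)
    assert rates.loc["GroupA", "treated"] == 3 and rates.loc["GroupA", "total"] == 5


def test_rate_by_all_treated_and_unknown_level_included():
    rows = [["S1", "GroupA", "Yes"], ["S2", "Unknown", "Yes"]]
    rates = mf.rate_by(_table(rows), "LIVARAG")
    assert (rates["rate_percent"] == 100.0).all()
    assert "Unknown" in set(rates["level"])


def test_rate_by_excludes_unknown_outcomes():
    rows = [["S1", "GroupA", "Yes"], ["S1", "GroupA", "Unknown"],
            ["S1", "GroupA", "No"]]
    rates = mf.rate_by(_table(rows), "LIVARAG").set_index("level")
    assert rates.loc["GroupA", "total"] == 2


def test_percent_difference_printed_worked_examples():
    assert mf.percent_difference(28.56, 44.92) == pytest.approx(-36.42, abs=0.005)
    assert mf.percent_difference(34.54, 44.92) == pytest.approx(-23.11, abs=0.005)
    assert mf.percent_difference(51.32, 63.60) == pytest.approx(-19.31, abs=0.005)
    assert mf.percent_difference(7.5, 7.5) == 0.0
    with pytest.raises(ContractError):
        mf.percent_difference(10.0, 0.0)


def test_point_difference_printed_worked_examples():
    assert mf.point_difference(63.70, 47.19) == pytest.approx(16.51)
    assert mf.point_difference(63.70, 3.03) == pytest.approx(60.67)
    assert mf.point_difference(44.92, 28.56) == pytest.approx(16.36)
    assert mf.point_difference(5.0, 5.0) == 0.0
    # antisymmetry senses: point flips sign, percent flips base
    assert mf.point_difference(40.0, 30.0) == -mf.point_difference(30.0, 40.0)


def test_two_proportion_test_matches_closed_form_pooled_z():
    """Independent oracle: plain pooled-z arithmetic via the normal CDF."""
    k1, n1, k2, n2 = 30, 100, 20, 100
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    z = (p1 - p2) / np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    expected_p = 2 * (1 - norm.cdf(abs(z)))
    res = mf.two_proportion_test(k1, n1, k2, n2)
    assert res.p_value == pytest.approx(expected_p, abs=1e-10)
    assert res.point_difference == pytest.approx(10.0)
    assert res.percent_difference == pytest.approx(50.0)


def test_two_proportion_test_symmetry_and_extremes():
    a = mf.two_proportion_test(30, 100, 20, 100)
    b = mf.two_proportion_test(20, 100, 30, 100)
    assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
    extreme = mf.two_proportion_test(900, 1000, 100, 1000)
    assert extreme.p_value < 0.001 and extreme.stars == "****"
    same = mf.two_proportion_test(500, 1000, 500, 1000)
    assert same.p_value == pytest.approx(1.0)
    assert same.stars == ""
    with pytest.raises(ContractError):
        mf.two_proportion_test(1, 0, 1, 2)
    with pytest.raises(ContractError):
        mf.two_proportion_test(5, 2, 1, 2)


def test_star_thresholds():
    assert stars_for(0.0005) == "****"
    assert stars_for(0.005) == "***"
    assert stars_for(0.03) == "**"
    assert stars_for(0.07) == "*"
    assert stars_for(0.2) == ""


def test_crosstab_shares_and_rates():
    rows = (
        [["S1", "GroupA", "Yes"]] * 3 + [["S1", "GroupA", "No"]] * 4
        + [["S2", "GroupA", "Yes"]] * 2 + [["S2", "GroupA", "No"]] * 1
        + [["S1", "GroupB", "No"]] * 5 + [["S2", "GroupB", "Yes"]] * 5
    )
    ct = mf.crosstab(_table(rows))
    assert ct.column_shares[:, ct.column_index("GroupA")].sum() == pytest.approx(100.0)
    assert ct.column_shares[:, ct.column_index("GroupB")].sum() == pytest.approx(100.0)
    assert (ct.treated <= ct.total).all()
    i, j = ct.row_labels.index("S1"), ct.column_index("GroupA")
    assert ct.rate[i, j] == pytest.approx(100 * 3 / 7)
    assert ct.column_rates["GroupB"] == pytest.approx(50.0)


def test_overall_rate_composes_from_shares_and_rates(small_table):
    """Overall rate equals the share-weighted sum of per-level rates."""
    table, _ = mf.drop_unknown_outcome(small_table)
    overall = 100 * (table.df["METHUSE"] == "Yes").mean()
    for by in ("LIVARAG", "SERVICES"):
        rates = mf.rate_by(table, by)
        shares = rates["total"] / rates["total"].sum()
        composed = float((shares * rates["rate_percent"]).sum())
        assert composed == pytest.approx(overall, abs=1e-9)


def test_crosstab_with_tests_mirrors_reference_comparisons():
    rows = (
        [["S1", "GroupA", "Yes"]] * 30 + [["S1", "GroupA", "No"]] * 20
        + [["S1", "GroupB", "Yes"]] * 10 + [["S1", "GroupB", "No"]] * 40
    )
    out = mf.crosstab_with_tests(mf.crosstab(_table(rows)), "GroupA")
    assert len(out) == 1
    row = out.iloc[0]
    assert row["group"] == "GroupB"
    assert row["percent_difference"] == pytest.approx(
        mf.percent_difference(20.0, 60.0)
    )
    oracle = mf.two_proportion_test(10, 50, 30, 50)
    assert row["p_value"] == pytest.approx(oracle.p_value)
    assert row["stars"] == oracle.stars


def test_flow_table_shares_and_consistency():
    rows = (
        [["S1", "GroupA", "Yes"]] * 3 + [["S2", "GroupA", "Yes"]] * 5
        + [["S2", "GroupA", "No"]] * 2
    )
    flows = mf.flow_table(_table(rows), "GroupA").set_index("setting")
    assert flows["share_percent"].sum() == pytest.approx(100.0)
    assert flows.loc["S1", "share_percent"] == pytest.approx(30.0)
    assert flows.loc["S2", "share_percent"] == pytest.approx(70.0)
    assert flows.loc["S2", "rate_percent"] == pytest.approx(100 * 5 / 7)
    single = mf.flow_table(_table([["S1", "GroupB", "No"]]), "GroupB")
    assert len(single) == 1 and single["share_percent"].iloc[0] == 100.0
    with pytest.raises(ValidationError):
        mf.flow_table(_table(rows), "Unknown")


def test_flow_edges_balance():
    rows = [["S1", "GroupA", "Yes"]] * 3 + [["S1", "GroupA", "No"]] * 1
    flows = mf.flow_table(_table(rows), "GroupA")
    edges = mf.flow_edges(flows, "GroupA")
    into_s1 = edges[(edges["target"] == "S1")]["value"].sum()
    out_of_s1 = edges[(edges["source"] == "S1")]["value"].sum()
    assert into_s1 == pytest.approx(out_of_s1)


def test_flow_rates_match_rate_by_restriction(small_table):
    table, _ = mf.drop_unknown_outcome(small_table)
    group = "Homeless"
    flows = mf.flow_table(table, group).set_index("setting")
    sub = table.with_df(table.df[table.df["LIVARAG"] == group].reset_index(drop=True))
    rates = mf.rate_by(sub, "SERVICES").set_index("level")
    for setting in flows.index:
        assert flows.loc[setting, "rate_percent"] == pytest.approx(
            rates.loc[setting, "rate_percent"]
        )
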