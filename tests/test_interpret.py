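"""Shapley explanations: additivity, importance arithmetic, subgroups."""

import numpy as np
import pandas as pd
import pytest

import moudflow as mf
from moudflow.errors import ContractError
from moudflow.interpret import ShapMatrix
from moudflow.table import AdmissionTable

from conftest import make_matrix, make_tiny_config

RNG = np.random.default_rng(99)


def _fitted(n=500, p=4, rounds=40):
    X = RNG.normal(size=(n, p))
    y = (X[:, 0] + 0.5 * X[:, 1] + RNG.normal(scale=0.5, size=n) > 0).astype(int)
    enc = make_matrix(X)
    model = mf.fit(enc, y, mf.HyperParams(num_boost_round=rounds), seed=0)
    return model, enc


def test_additivity_base_plus_sum_equals_margin():
    model, enc = _fitted()
    shap = mf.explain(model, enc)
    margin = model.predict_margin(enc)
    resid = np.abs(shap.base_value + shap.values.sum(axis=1) - margin)
    assert resid.max() < 1e-4


def test_single_leaf_model_gives_zero_shap():
    """A model whose trees never split attributes nothing to any feature."""
    X = RNG.normal(size=(50, 3))
    enc = make_matrix(X)
    y = np.tile([0, 1], 25)
    # min_child_weight far above n forces every tree to stay a single leaf
    model = mf.fit(enc, y, mf.HyperParams(num_boost_round=5, min_child_weight=1e6),
                   seed=0)
    shap = mf.explain(model, enc)
    assert np.abs(shap.values).max() < 1e-8


def test_single_stump_matches_hand_computation():
    """Depth-1 single tree on one feature: phi = margin - cover-weighted mean."""
    X = np.array([[0.0], [1.0], [2.0], [3.0]])
    y = np.array([0, 0, 1, 1])
    enc = make_matrix(X)
    params = mf.HyperParams(max_depth=1, num_boost_round=1, learning_rate=1.0)
    model = mf.fit(enc, y, params, seed=0)
    shap = mf.explain(model, enc)
    margin = model.predict_margin(enc)
    # with one feature, the whole deviation from the expectation is its phi,
    # and the base value is the training-cover-weighted mean margin
    assert shap.base_value == pytest.approx(margin.mean(), abs=1e-6)
    np.testing.assert_allclose(shap.values[:, 0], margin - shap.base_value,
                               atol=1e-6)


def test_explain_feature_mismatch_raises():
    model, enc = _fitted(n=60)
    other = make_matrix(RNG.normal(size=(10, 4)))
    other.feature_names = ["A", "B", "C", "D"]
    with pytest.raises(ContractError):
        mf.explain(model, other)


# ---------------------------------------------------------------------------
# importance


def _shap_of(values):
    values = np.asarray(values, dtype=float)
    names = [f"F{j}" for j in range(values.shape[1])]
    return ShapMatrix(values, 0.0, names)


def test_importance_arithmetic_shares():
    # mean |phi| = (2, 1, 1) -> shares (50, 25, 25)
    shap = _shap_of([[2, 1, 1], [-2, -1, 1], [2, 1, -1], [-2, -1, -1]])
    imp = mf.importance(shap, category_map={})
    assert dict(zip(imp["feature"], imp["importance_share"])) == pytest.approx(
        {"F0": 50.0, "F1": 25.0, "F2": 25.0}
    )
    assert imp.loc[imp["feature"] == "F0", "rank"].iloc[0] == 1


def test_importance_equal_features_split_evenly_and_zero_feature():
    shap = _shap_of([[1, -1, 0], [-1, 1, 0]])
    imp = mf.importance(shap, category_map={}).set_index("feature")
    assert imp.loc["F0", "importance_share"] == pytest.approx(50.0)
    assert imp.loc["F1", "importance_share"] == pytest.approx(50.0)
    assert imp.loc["F2", "importance_share"] == 0.0


def test_importance_sums_to_100_and_permutation_equivariant():
    values = RNG.normal(size=(40, 6))
    shap = _shap_of(values)
    imp = mf.importance(shap, category_map={}).set_index("feature")
    assert imp["importance_share"].sum() == pytest.approx(100.0, abs=1e-6)
    perm = [3, 1, 5, 0, 2, 4]
    shuffled = ShapMatrix(values[:, perm], 0.0, [f"F{j}" for j in perm])
    imp2 = mf.importance(shuffled, category_map={}).set_index("feature")
    for j in range(6):
        assert imp2.loc[f"F{j}", "importance_share"] == pytest.approx(
            imp.loc[f"F{j}", "importance_share"]
        )


def test_all_zero_shap_warns_zero_shares():
    with pytest.warns(UserWarning, match="zero"):
        imp = mf.importance(_shap_of(np.zeros((5, 3))), category_map={})
    assert (imp["importance_share"] == 0).all()


def test_category_aggregation_conserves_total():
    shap = _shap_of(RNG.normal(size=(30, 4)))
    cmap = {"F0": "CatA", "F1": "CatA", "F2": "CatB"}  # F3 -> Other
    imp = mf.importance(shap, category_map=cmap)
    agg = mf.category_importance(imp)
    assert agg["importance_share"].sum() == pytest.approx(100.0, abs=1e-6)
    assert set(agg["category"]) == {"CatA", "CatB", "Other"}
    catA = imp.loc[imp["category"] == "CatA", "importance_share"].sum()
    assert agg.set_index("category").loc["CatA", "importance_share"] == pytest.approx(catA)


def test_single_informative_feature_ranks_first():
    """One covariate with >=1 log-odds spread dominates pure-noise covariates."""
    cfg = mf.GeneratorConfig(
        n_admissions=5000,
        living_status_probs={"OnlyGroup": 1.0},
        setting_shares={"OnlyGroup": (1.0,)},
        setting_rates={"OnlyGroup": (0.5,)},
        settings=("OnlySetting",),
        covariates=(
            mf.CovariateSpec("SIGNAL", "categorical", ("Low", "High"),
                             (0.5, 0.5), effects=(-0.75, 0.75)),
            mf.CovariateSpec("NOISE1", "categorical", ("A", "B", "C"),
                             (0.3, 0.4, 0.3)),
            mf.CovariateSpec("NOISE2", "ordinal", ("L1", "L2", "L3", "L4"),
                             (0.25, 0.25, 0.25, 0.25)),
        ),
        seed=6,
    )
    table = mf.generate_admissions(cfg)
    enc = mf.encode(table.with_df(table.df.drop(columns=["CASEID", "ADMYR"])))
    y = mf.outcome_labels(table)
    model = mf.fit(enc, y, mf.HyperParams(num_boost_round=80, max_depth=3), seed=0)
    imp = mf.importance(mf.explain(model, enc), category_map={})
    assert imp.iloc[0]["feature"] == "SIGNAL"
    top, runner_up = imp["importance_share"].iloc[0], imp["importance_share"].iloc[1]
    assert top > runner_up


# ---------------------------------------------------------------------------
# subgroup summaries


def test_subgroup_sign_recovery_for_living_status():
    """Within-setting rates favouring GroupA make its own Shapley positive."""
    cfg = make_tiny_config(
        n=6000,
        setting_shares={"GroupA": (0.4, 0.3, 0.3), "GroupB": (0.4, 0.3, 0.3)},
        setting_rates={"GroupA": (0.75, 0.65, 0.55), "GroupB": (0.35, 0.25, 0.15)},
        seed=13,
    )
    table = mf.generate_admissions(cfg)
    enc = mf.encode(table.with_df(table.df.drop(columns=["CASEID", "ADMYR"])))
    y = mf.outcome_labels(table)
    model = mf.fit(enc, y, mf.HyperParams(num_boost_round=60, max_depth=3), seed=0)
    shap = mf.explain(model, enc)
    trimmed = table.with_df(table.df.drop(columns=["CASEID", "ADMYR"]))
    summary = mf.subgroup_summary(shap, trimmed, "LIVARAG").set_index("level")
    assert summary.loc["GroupA", "median"] > 0
    assert summary.loc["GroupB", "median"] < 0
    assert (summary["q1"] <= summary["median"]).all()
    assert (summary["median"] <= summary["q3"]).all()
    assert summary["n"].sum() == table.n_rows


def test_subgroup_constant_column_and_single_level():
    values = np.zeros((8, 2))
    values[:, 1] = 0.5
    shap = ShapMatrix(values, 0.0, ["VAR", "OTHER"])
    cb = mf.VariableCodebook([
        mf.VariableDef("VAR", "categorical", ("OnlyLevel", "Unknown")),
        mf.VariableDef("OTHER", "categorical", ("X", "Unknown")),
        mf.VariableDef("METHUSE", "categorical", ("No", "Yes", "Unknown")),
    ])
    df = pd.DataFrame({"VAR": ["OnlyLevel"] * 8, "OTHER": ["X"] * 8,
                       "METHUSE": ["Yes", "No"] * 4})
    with pytest.warns(UserWarning, match="omitted"):
        summary = mf.subgroup_summary(shap, AdmissionTable(df, cb), "VAR")
    assert len(summary) == 1
    row = summary.iloc[0]
    assert row["n"] == 8
    assert row["q1"] == row["median"] == row["q3"] == 0.0


def test_subgroup_requires_model_feature(small_table):
    shap = ShapMatrix(np.zeros((small_table.n_rows, 1)), 0.0, ["AGE"])
    with pytest.raises(ContractError):
        mf.subgroup_summary(shap, small_table, "NOT_A_FEATURE")
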