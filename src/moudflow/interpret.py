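"""Shapley-value explanations, normalized importance, and subgroup summaries.

Per-admission, per-feature Shapley values are computed with the tree-exact
path-dependent algorithm built into the boosting library
(``pred_contribs``); they live on the log-odds (margin) scale and satisfy
local additivity: base value plus the row sum of attributions reproduces
the model margin for every admission.

Feature importance is the mean absolute Shapley value over the evaluation
set, normalized to sum to 100%.  Importance is computed on the held-out
test partition, matching the framing of interpreting predictions rather
than training fit.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xgboost as xgb
from dataclasses import dataclass

from .errors import ContractError
from .model import ModelHandle
from .preprocess import EncodedMatrix
from .table import AdmissionTable

#: additivity tolerance for base + sum(phi) vs the model margin
ADDITIVITY_TOL = 1e-4

#: variable -> thematic category, as assigned in the published ranking
DEFAULT_CATEGORY_MAP: dict[str, str] = {
    "SERVICES": "Coordination of care",
    "PSOURCE_DETCRIM": "Coordination of care",
    "DAYWAIT": "Coordination of care",
    "STFIPS": "Geographic",
    "REGION": "Geographic",
    "DIVISION": "Geographic",
    "CBSA2010": "Geographic",
    "NOPRIOR": "Medical history",
    "DSMCRIT": "Medical history",
    "FREQ_ATND_SELF_HELP": "Medical history",
    "PSYPROB": "Medical history",
    "FREQ1": "Substance use history",
    "SUB1": "Substance use history",
    "SUB2": "Substance use history",
    "HLTHINS": "Economic",
    "PRIMPAY": "Economic",
    "PRIMINC": "Economic",
    "EMPLOY_DETNLF": "Economic",
    "LIVARAG": "Economic",
    "AGE": "Demographic",
    "GENDER": "Demographic",
    "RACE": "Demographic",
    "ETHNIC": "Demographic",
    "MARSTAT": "Demographic",
    "ARRESTS": "Personal history",
    "EDUC": "Personal history",
}


@dataclass
class ShapMatrix:
    """Per-admission, per-feature attributions on the margin scale."""

    values: np.ndarray
    base_value: float
    feature_names: list[str]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


def explain(model: ModelHandle, data: EncodedMatrix) -> ShapMatrix:
    """Tree-exact Shapley values for every admission in ``data``.

    Raises :class:`ContractError` on feature mismatch or if the additivity
    identity fails beyond :data:`ADDITIVITY_TOL`.
    """
    if data.feature_names != model.feature_names:
        raise ContractError("feature order differs from training order")
    dmat = xgb.DMatrix(data.values, feature_names=model.feature_names, nthread=1)
    contribs = model.booster.predict(dmat, pred_contribs=True).astype(np.float64)
    values, base = contribs[:, :-1], contribs[:, -1]
    margin = model.predict_margin(data)
    resid = np.max(np.abs(base + values.sum(axis=1) - margin)) if len(margin) else 0.0
    if resid > ADDITIVITY_TOL:
        raise ContractError(f"Shapley additivity violated: residual {resid:.2e}")
    return ShapMatrix(
        values=values, base_value=float(base[0]) if len(base) else 0.0,
        feature_names=list(data.feature_names),
    )


def importance(
    shap: ShapMatrix, category_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Normalized per-feature importance shares (percent, summing to 100).

    Share = mean |phi| over admissions divided by the total over features.
    Rank is dense by descending share.  Features absent from the category
    map fall into ``"Other"``.
    """
    cmap = DEFAULT_CATEGORY_MAP if category_map is None else category_map
    mean_abs = np.abs(shap.values).mean(axis=0)
    total = mean_abs.sum()
    if total == 0.0:
        warnings.warn("all Shapley values are zero; importance shares set to 0")
        shares = np.zeros_like(mean_abs)
    else:
        shares = 100.0 * mean_abs / total
    df = pd.DataFrame(
        {
            "feature": shap.feature_names,
            "importance_share": shares,
            "category": [cmap.get(f, "Other") for f in shap.feature_names],
        }
    )
    df = df.sort_values("importance_share", ascending=False, kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def category_importance(importance_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate feature shares by category (conserves the 100% total)."""
    agg = (
        importance_table.groupby("category", as_index=False)["importance_share"]
        .sum()
        .sort_values("importance_share", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    agg["rank"] = np.arange(1, len(agg) + 1)
    return agg


def subgroup_summary(
    shap: ShapMatrix, table: AdmissionTable, variable: str
) -> pd.DataFrame:
    """Median and interquartile range of one feature's Shapley values per level.

    Rows of ``table`` must align one-to-one with rows of ``shap``.  Levels
    with no admissions are omitted with a warning.  Quartiles use linear
    interpolation.
    """
    if variable not in shap.feature_names:
        raise ContractError(f"{variable!r} is not a model feature")
    if table.n_rows != shap.n_rows:
        raise ContractError("table and Shapley matrix row counts differ")
    j = shap.feature_names.index(variable)
    col = shap.values[:, j]
    labels = table.df[variable].to_numpy()
    rows = []
    for level in table.codebook[variable].levels:
        mask = labels == level
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"{variable}={level!r}: no admissions; level omitted")
            continue
        q1, med, q3 = np.percentile(col[mask], [25, 50, 75])
        rows.append(
            {"level": level, "n": n, "q1": float(q1), "median": float(med), "q3": float(q3)}
        )
    return pd.DataFrame(rows)
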