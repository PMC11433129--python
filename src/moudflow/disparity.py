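"""Descriptive treatment rates, cross-tabs, significance stars and flows.

Rates are reported in percent.  Comparisons (percent and point
differences) are computed at full precision; rounding happens only at
presentation time, since published parenthetical differences are
irreproducible from rounded cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

from .errors import ContractError, ValidationError
from .table import TREATED, AdmissionTable

#: significance star thresholds, most stringent first
STAR_LEVELS = ((0.001, "****"), (0.01, "***"), (0.05, "**"), (0.1, "*"))


def stars_for(p_value: float) -> str:
    for thr, s in STAR_LEVELS:
        if p_value < thr:
            return s
    return ""


@dataclass(frozen=True)
class DiffResult:
    """A rate comparison: relative and absolute difference plus a p-value."""

    percent_difference: float
    point_difference: float
    p_value: float
    stars: str


def percent_difference(rate: float, reference_rate: float) -> float:
    """Signed relative difference in percent: 100*(rate - ref)/ref."""
    if reference_rate == 0:
        raise ContractError("percent difference undefined for zero reference rate")
    return 100.0 * (rate - reference_rate) / reference_rate


def point_difference(rate_a: float, rate_b: float) -> float:
    """Difference in percentage points: rate_a - rate_b."""
    return rate_a - rate_b


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> DiffResult:
    """Two-sided pooled-variance z-test comparing k1/n1 against k2/n2.

    Group 2 is the reference for the percent difference.  Returns the
    p-value and its significance stars.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ContractError("group sizes must be >= 1")
        if not 0 <= k <= n:
            raise ContractError("successes must lie in [0, n]")
    r1, r2 = 100.0 * k1 / n1, 100.0 * k2 / n2
    if k1 == k2 and n1 == n2:
        p = 1.0
    else:
        _, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
        p = float(p)
        if np.isnan(p):  # identical pooled proportion of 0 or 1
            p = 1.0
    pct = percent_difference(r1, r2) if r2 > 0 else float("nan")
    return DiffResult(
        percent_difference=pct,
        point_difference=point_difference(r1, r2),
        p_value=p,
        stars=stars_for(p),
    )


@dataclass
class RateCrossTab:
    """Treated/total counts by (setting row, group column), plus margins."""

    row_labels: list[str]
    col_labels: list[str]
    treated: np.ndarray  # (rows, cols) int
    total: np.ndarray  # (rows, cols) int

    def __post_init__(self) -> None:
        if (self.treated > self.total).any():
            raise ContractError("treated counts exceed totals")

    @property
    def rate(self) -> np.ndarray:
        """Percent treated per cell; NaN where a cell is empty."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, 100.0 * self.treated / self.total, np.nan)

    @property
    def column_shares(self) -> np.ndarray:
        """Percent of each group's admissions per setting (columns sum to 100)."""
        colsum = self.total.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(colsum > 0, 100.0 * self.total / colsum, np.nan)

    @property
    def column_rates(self) -> dict[str, float]:
        """Marginal treated percent per group."""
        out = {}
        for j, g in enumerate(self.col_labels):
            tot = self.total[:, j].sum()
            out[g] = float(100.0 * self.treated[:, j].sum() / tot) if tot else float("nan")
        return out

    def column_index(self, group: str) -> int:
        try:
            return self.col_labels.index(group)
        except ValueError:
            raise ContractError(f"group {group!r} not in cross-tab") from None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        rate = self.rate
        share = self.column_shares
        for i, s in enumerate(self.row_labels):
            for j, g in enumerate(self.col_labels):
                rows.append(
                    {
                        "setting": s,
                        "group": g,
                        "treated": int(self.treated[i, j]),
                        "total": int(self.total[i, j]),
                        "rate_percent": rate[i, j],
                        "share_of_group_percent": share[i, j],
                    }
                )
        return pd.DataFrame(rows)


def crosstab(
    table: AdmissionTable, row_var: str = "SERVICES", col_var: str = "LIVARAG"
) -> RateCrossTab:
    """Build the setting-by-group treated/total cross-tab from a table."""
    for v in (row_var, col_var, table.outcome_column):
        if v not in table.df.columns:
            raise ContractError(f"column {v!r} missing")
    unknown_out = table.codebook[table.outcome_column].unknown_label
    df = table.df[table.df[table.outcome_column] != unknown_out]
    row_levels = [l for l in table.codebook[row_var].levels if (df[row_var] == l).any()]
    col_levels = [l for l in table.codebook[col_var].levels if (df[col_var] == l).any()]
    treated = np.zeros((len(row_levels), len(col_levels)), dtype=np.int64)
    total = np.zeros_like(treated)
    grp = df.groupby([row_var, col_var], observed=True)[table.outcome_column]
    counts = grp.agg(total="size", treated=lambda s: int((s == TREATED).sum()))
    for (r, c), rec in counts.iterrows():
        i, j = row_levels.index(r), col_levels.index(c)
        total[i, j] = rec["total"]
        treated[i, j] = rec["treated"]
    return RateCrossTab(row_levels, col_levels, treated, total)


def rate_by(table: AdmissionTable, by: str) -> pd.DataFrame:
    """Treated count, total and percent rate per level of ``by``.

    Unknown levels of ``by`` are ordinary rows; unknown *outcomes* are
    excluded from both numerator and denominator.
    """
    if by not in table.df.columns:
        raise ContractError(f"column {by!r} missing")
    unknown_out = table.codebook[table.outcome_column].unknown_label
    df = table.df[table.df[table.outcome_column] != unknown_out]
    rows = []
    for level in table.codebook[by].levels:
        sub = df[df[by] == level]
        if len(sub) == 0:
            continue
        k = int((sub[table.outcome_column] == TREATED).sum())
        rows.append(
            {"level": level, "treated": k, "total": len(sub), "rate_percent": 100.0 * k / len(sub)}
        )
    return pd.DataFrame(rows)


def crosstab_with_tests(ct: RateCrossTab, reference: str) -> pd.DataFrame:
    """Per-cell comparison of every group against ``reference``.

    Mirrors the published table: the rate, the percent difference from the
    reference group within the same setting, and significance stars from a
    two-proportion z-test.
    """
    jref = ct.column_index(reference)
    rows = []
    for i, setting in enumerate(ct.row_labels):
        for j, group in enumerate(ct.col_labels):
            if j == jref:
                continue
            if ct.total[i, j] == 0 or ct.total[i, jref] == 0:
                continue
            res = two_proportion_test(
                int(ct.treated[i, j]), int(ct.total[i, j]),
                int(ct.treated[i, jref]), int(ct.total[i, jref]),
            )
            rows.append(
                {
                    "setting": setting,
                    "group": group,
                    "rate_percent": ct.rate[i, j],
                    "reference_rate_percent": ct.rate[i, jref],
                    "percent_difference": res.percent_difference,
                    "p_value": res.p_value,
                    "stars": res.stars,
                }
            )
    return pd.DataFrame(rows)


def flow_table(
    table: AdmissionTable,
    group: str,
    group_var: str = "LIVARAG",
    setting_var: str = "SERVICES",
) -> pd.DataFrame:
    """Per-setting share of a group's admissions and the setting's treated rate.

    Shares sum to 100 over settings; this is the numeric content of a
    two-stage flow (Sankey) diagram for the group.
    """
    unknown_out = table.codebook[table.outcome_column].unknown_label
    df = table.df[table.df[table.outcome_column] != unknown_out]
    sub = df[df[group_var] == group]
    if len(sub) == 0:
        raise ValidationError(f"no admissions with {group_var}={group!r}")
    rows = []
    for setting in table.codebook[setting_var].levels:
        cell = sub[sub[setting_var] == setting]
        if len(cell) == 0:
            continue
        k = int((cell[table.outcome_column] == TREATED).sum())
        rows.append(
            {
                "setting": setting,
                "share_percent": 100.0 * len(cell) / len(sub),
                "rate_percent": 100.0 * k / len(cell),
                "n": len(cell),
            }
        )
    return pd.DataFrame(rows)


def flow_edges(flows: pd.DataFrame, group: str) -> pd.DataFrame:
    """(source, target, value) edge list for any Sankey renderer.

    Stage 1: group -> setting, weighted by the share of admissions.
    Stage 2: setting -> treated/not-treated, splitting that share by rate.
    """
    edges = []
    for _, r in flows.iterrows():
        edges.append({"source": group, "target": r["setting"], "value": r["share_percent"]})
        treated_val = r["share_percent"] * r["rate_percent"] / 100.0
        edges.append({"source": r["setting"], "target": "MOUD", "value": treated_val})
        edges.append(
            {"source": r["setting"], "target": "No MOUD", "value": r["share_percent"] - treated_val}
        )
    return pd.DataFrame(edges)
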