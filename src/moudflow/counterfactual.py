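"""Counterfactual service-setting reallocation (direct standardization).

The what-if question: if the target group (say, unhoused admissions)
entered each service setting at the reference group's frequency, but kept
its own within-setting treatment rates, what would its overall treatment
rate be, and how much of the observed disparity would disappear?

The standardized rate is ``R_cf = sum_s w_ref(s) * r_target(s)``; the
observed disparity is ``D_obs = R_ref - R_target`` (positive means the
target group is disadvantaged), the counterfactual disparity is
``D_cf = R_ref - R_cf``, and the elimination share is
``100 * (D_obs - D_cf) / D_obs``.  This is a standardization exercise, not
a causal estimate: it assumes the target group could enter the reference
group's settings at will.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .disparity import RateCrossTab, crosstab
from .errors import ConfigurationError, ContractError
from .preprocess import drop_unknown_outcome
from .synthetic import (
    INDEPENDENT,
    UNHOUSED,
    GeneratorConfig,
    PlantedTruth,
    generate_admissions,
    planted_truth,
)

_SHARE_TOL = 1e-6


@dataclass(frozen=True)
class DecompositionResult:
    """Observed and counterfactual rates and the disparity split (percent)."""

    reference: str
    target: str
    observed_rate_reference: float
    observed_rate_target: float
    counterfactual_rate: float
    observed_disparity: float
    counterfactual_disparity: float
    elimination_share: float
    elimination_defined: bool

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def standardized_rate(reference_shares, target_rates) -> float:
    """Share-weighted rate: 100 * sum_s shares[s] * rates[s]/100.

    ``reference_shares`` is a probability vector over settings (sums to 1);
    ``target_rates`` are percents aligned on the same setting order.  A
    setting with an undefined (NaN) target rate and nonzero reference share
    raises: the caller must choose a policy for such cells.
    """
    w = np.asarray(reference_shares, dtype=float)
    r = np.asarray(target_rates, dtype=float)
    if w.shape != r.shape:
        raise ContractError("shares and rates must align on the same settings")
    if abs(w.sum() - 1.0) > _SHARE_TOL:
        raise ContractError("reference shares must sum to 1")
    bad = np.isnan(r) & (w > 0)
    if bad.any():
        raise ContractError(
            "target rate undefined for a setting with nonzero reference share "
            f"(positions {np.flatnonzero(bad).tolist()})"
        )
    return float(np.where(w > 0, w * np.nan_to_num(r), 0.0).sum())


def decompose(
    ct: RateCrossTab,
    reference: str,
    target: str,
    zero_cell_policy: str = "pooled",
) -> DecompositionResult:
    """Fill a :class:`DecompositionResult` from a setting-by-group cross-tab.

    Settings where the target group has no admissions (rate undefined) but
    the reference share is nonzero are resolved by ``zero_cell_policy``:
    ``"pooled"`` substitutes the setting's all-group pooled rate,
    ``"strict"`` raises.  All arithmetic is at full precision.
    """
    if zero_cell_policy not in ("pooled", "strict"):
        raise ConfigurationError(f"unknown zero_cell_policy {zero_cell_policy!r}")
    jr, jt = ct.column_index(reference), ct.column_index(target)
    if ct.total[:, jr].sum() == 0 or ct.total[:, jt].sum() == 0:
        raise ContractError("both groups need at least one admission")
    shares = ct.column_shares[:, jr] / 100.0
    rates = ct.rate[:, jt].copy()
    undefined = np.isnan(rates) & (shares > 0)
    if undefined.any():
        if zero_cell_policy == "strict":
            raise ContractError(
                "target group has no admissions in settings "
                f"{[ct.row_labels[i] for i in np.flatnonzero(undefined)]}"
            )
        pooled_tot = ct.total.sum(axis=1)
        pooled = np.where(pooled_tot > 0, 100.0 * ct.treated.sum(axis=1) / np.maximum(pooled_tot, 1), np.nan)
        rates[undefined] = pooled[undefined]
    r_ref = ct.column_rates[reference]
    r_tgt = ct.column_rates[target]
    r_cf = standardized_rate(shares, rates)
    d_obs = r_ref - r_tgt
    d_cf = r_ref - r_cf
    defined = d_obs != 0.0
    share = 100.0 * (d_obs - d_cf) / d_obs if defined else float("nan")
    return DecompositionResult(
        reference=reference,
        target=target,
        observed_rate_reference=r_ref,
        observed_rate_target=r_tgt,
        counterfactual_rate=r_cf,
        observed_disparity=d_obs,
        counterfactual_disparity=d_cf,
        elimination_share=share,
        elimination_defined=defined,
    )


def recover_from_synthetic(
    config: GeneratorConfig,
    n: int | None = None,
    seed: int | None = None,
    reference: str = INDEPENDENT,
    target: str = UNHOUSED,
) -> tuple[DecompositionResult, PlantedTruth]:
    """Parameter-recovery harness: simulate, decompose, return truth alongside.

    Generates a table from ``config`` (optionally overriding size and seed),
    drops unknown outcomes, builds the setting-by-living-status cross-tab
    and decomposes it; the closed-form planted truth of the same
    configuration is returned for comparison.
    """
    kw = {}
    if n is not None:
        kw["n_admissions"] = n
    if seed is not None:
        kw["seed"] = seed
    if kw:
        config = config.with_(**kw)
    table = generate_admissions(config)
    table, _ = drop_unknown_outcome(table)
    ct = crosstab(table)
    est = decompose(ct, reference, target)
    truth = planted_truth(config, reference, target)
    return est, truth
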