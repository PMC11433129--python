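"""Synthetic admission-table generator with planted, closed-form ground truth.

The generator emulates the statistical structure of coded treatment-admission
records: one row per admission, a living-arrangement variable, a service
setting drawn from a living-status-specific mix, a binary
medication-for-opioid-use-disorder (MOUD) outcome whose probability is set
per (living status, setting) cell, and a bank of coded covariates, some of
which shift the outcome on the log-odds scale.

Two properties make every downstream stage testable without real data:

* ``planted_truth`` returns the exact expected group rates, standardized
  counterfactual rate and disparity-elimination share implied by a
  configuration, with no sampling.
* Covariate log-odds effects are *mean-preserving within each cell*: before
  sampling, the per-cell base logit is recentred (monotone root-find) so the
  cell's marginal outcome rate equals the configured rate exactly.  Effects
  therefore create learnable within-cell signal without moving the planted
  group rates.

The default configuration is calibrated to the study conditions of the 2019
opioid-admissions cohort: per-cell treatment rates and four printed
setting-share values are taken verbatim from the published cross-tab, group
rates hit 44.92 / 34.54 / 28.56 % and the overall rate 40.40 % exactly in
expectation, and the remaining (unpublished) share parameters were solved
once to approximate the published overall setting mix.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .codebook import VariableCodebook, VariableDef
from .errors import ConfigurationError
from .table import NOT_TREATED, OUTCOME, TREATED, AdmissionTable

_PROB_TOL = 1e-9

#: service-setting labels, verbatim from the published cross-tab
SETTING_LABELS = (
    "Ambulatory, detoxification",
    "Ambulatory, intensive outpatient",
    "Ambulatory, non-intensive outpatient",
    "Detox, 24-hour, free-standing residential",
    "Detox, 24-hour, hospital inpatient",
    "Rehab/residential, hospital (non-detox)",
    "Rehab/residential, short term (more than 30 days)",
    "Rehab/residential, short term (30 days or fewer)",
)

INDEPENDENT = "IndependentLiving"
DEPENDENT = "DependentLiving"
UNHOUSED = "Homeless"
UNKNOWN = "Unknown"
LIVING_LABELS = (INDEPENDENT, DEPENDENT, UNHOUSED, UNKNOWN)


@dataclass(frozen=True)
class CovariateSpec:
    """A coded covariate: level probabilities and optional outcome effects.

    ``effects`` are per-level log-odds added to the outcome logit (recentred
    per cell, see module docstring).  ``unknown_rate`` is the probability
    that the drawn value is replaced by the unknown label after the outcome
    has been generated; the true value is discarded.
    """

    name: str
    kind: str  # "ordinal" | "categorical"
    levels: tuple[str, ...]
    probs: tuple[float, ...]
    effects: tuple[float, ...] | None = None
    unknown_rate: float = 0.0

    def validate(self) -> None:
        if self.kind not in ("ordinal", "categorical"):
            raise ConfigurationError(f"{self.name}: bad covariate kind {self.kind!r}")
        if len(self.levels) != len(self.probs):
            raise ConfigurationError(f"{self.name}: levels/probs length mismatch")
        p = np.asarray(self.probs, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > _PROB_TOL:
            raise ConfigurationError(f"{self.name}: level probabilities must sum to 1")
        if self.effects is not None and len(self.effects) != len(self.levels):
            raise ConfigurationError(f"{self.name}: effects length mismatch")
        if not 0.0 <= self.unknown_rate <= 1.0:
            raise ConfigurationError(f"{self.name}: unknown_rate outside [0,1]")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one synthetic study population."""

    n_admissions: int
    living_status_probs: Mapping[str, float]
    setting_shares: Mapping[str, Sequence[float]]
    setting_rates: Mapping[str, Sequence[float]]
    covariates: tuple[CovariateSpec, ...] = ()
    settings: tuple[str, ...] = SETTING_LABELS
    unknown_outcome_rate: float = 0.0
    seed: int = 0

    @property
    def statuses(self) -> tuple[str, ...]:
        return tuple(self.living_status_probs)

    def validate(self) -> None:
        if self.n_admissions < 1:
            raise ConfigurationError("n_admissions must be >= 1")
        p = np.asarray(list(self.living_status_probs.values()), dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > _PROB_TOL:
            raise ConfigurationError("living_status_probs must sum to 1")
        n_set = len(self.settings)
        for g in self.statuses:
            if g not in self.setting_shares or g not in self.setting_rates:
                raise ConfigurationError(f"missing shares/rates for status {g!r}")
            w = np.asarray(self.setting_shares[g], dtype=float)
            r = np.asarray(self.setting_rates[g], dtype=float)
            if w.shape != (n_set,) or r.shape != (n_set,):
                raise ConfigurationError(f"{g}: shares/rates must have {n_set} entries")
            if (w < 0).any() or abs(w.sum() - 1.0) > _PROB_TOL:
                raise ConfigurationError(f"{g}: setting shares must sum to 1")
            if (r < 0).any() or (r > 1).any():
                raise ConfigurationError(f"{g}: rates must lie in [0,1]")
        if not 0.0 <= self.unknown_outcome_rate <= 1.0:
            raise ConfigurationError("unknown_outcome_rate outside [0,1]")
        for cv in self.covariates:
            cv.validate()

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class PlantedTruth:
    """Closed-form expectations implied by a :class:`GeneratorConfig`.

    All quantities are percents.  ``expected_counterfactual_rate`` is the
    directly standardized rate: reference group's setting shares weighting
    the target group's per-setting rates.
    """

    expected_rate_by_group: dict[str, float]
    expected_counterfactual_rate: float
    expected_observed_disparity: float
    expected_counterfactual_disparity: float
    expected_elimination_share: float
    elimination_defined: bool = True


# ---------------------------------------------------------------------------
# effect distribution and per-cell recentring


def _effect_distribution(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the summed covariate log-odds shift.

    Returns (support, probabilities) of the total shift delta, obtained by
    enumerating level combinations of every effect-bearing covariate.
    """
    deltas = np.array([0.0])
    probs = np.array([1.0])
    bearing = [c for c in config.covariates if c.effects is not None]
    size = int(np.prod([len(c.levels) for c in bearing])) if bearing else 1
    if size > 200_000:
        raise ConfigurationError(
            "covariate effect support too large to enumerate exactly "
            f"({size} combinations)"
        )
    for cv in bearing:
        e = np.asarray(cv.effects, dtype=float)
        p = np.asarray(cv.probs, dtype=float)
        deltas = (deltas[:, None] + e[None, :]).ravel()
        probs = (probs[:, None] * p[None, :]).ravel()
    return deltas, probs


def _base_logit(rate: float, deltas: np.ndarray, probs: np.ndarray) -> float:
    """Solve b such that E[expit(b + delta)] equals ``rate``."""
    if rate <= 0.0:
        return -np.inf
    if rate >= 1.0:
        return np.inf
    if len(deltas) == 1:
        return float(logit(rate) - deltas[0])

    def f(b: float) -> float:
        return float(probs @ expit(b + deltas) - rate)

    return brentq(f, -60.0, 60.0, xtol=1e-12)


def _base_logits(config: GeneratorConfig) -> np.ndarray:
    """(status, setting) matrix of recentred base logits."""
    deltas, probs = _effect_distribution(config)
    out = np.empty((len(config.statuses), len(config.settings)))
    for i, g in enumerate(config.statuses):
        for j, r in enumerate(np.asarray(config.setting_rates[g], dtype=float)):
            out[i, j] = _base_logit(float(r), deltas, probs)
    return out


# ---------------------------------------------------------------------------
# generation


def _build_codebook(config: GeneratorConfig) -> VariableCodebook:
    cb = VariableCodebook()
    cb.add(VariableDef("CASEID", "index"))
    cb.add(VariableDef("ADMYR", "ordinal", ("Year2019", UNKNOWN)))
    for cv in config.covariates:
        cb.add(VariableDef(cv.name, cv.kind, tuple(cv.levels) + (UNKNOWN,)))
    cb.add(VariableDef("SERVICES", "categorical", tuple(config.settings) + (UNKNOWN,)))
    statuses = tuple(config.statuses)
    if UNKNOWN not in statuses:
        statuses = statuses + (UNKNOWN,)
    cb.add(VariableDef("LIVARAG", "categorical", statuses))
    cb.add(VariableDef(OUTCOME, "categorical", (NOT_TREATED, TREATED, UNKNOWN)))
    return cb


def generate_admissions(config: GeneratorConfig) -> AdmissionTable:
    """Draw a coded admission table from ``config``.

    Reproducible: the same seed yields a byte-identical table.  Draw order
    is fixed (living status, setting, covariates in declaration order,
    outcome, then unknown contamination) so adding a covariate does not
    perturb earlier columns' streams only downstream ones.
    """
    config.validate()
    n = config.n_admissions
    rng = np.random.default_rng(config.seed)
    statuses = config.statuses

    status_idx = rng.choice(len(statuses), size=n, p=list(config.living_status_probs.values()))
    setting_idx = np.empty(n, dtype=np.int64)
    for i, g in enumerate(statuses):
        mask = status_idx == i
        if mask.any():
            setting_idx[mask] = rng.choice(
                len(config.settings), size=int(mask.sum()), p=np.asarray(config.setting_shares[g], dtype=float)
            )

    level_idx: dict[str, np.ndarray] = {}
    delta = np.zeros(n)
    for cv in config.covariates:
        li = rng.choice(len(cv.levels), size=n, p=np.asarray(cv.probs, dtype=float))
        level_idx[cv.name] = li
        if cv.effects is not None:
            delta += np.asarray(cv.effects, dtype=float)[li]

    base = _base_logits(config)[status_idx, setting_idx]
    with np.errstate(invalid="ignore"):
        p_treat = expit(base + delta)
    treated = rng.random(n) < p_treat

    data: dict[str, object] = {
        "CASEID": np.arange(1, n + 1, dtype=np.int64),
        "ADMYR": np.full(n, "Year2019", dtype=object),
    }
    for cv in config.covariates:
        labels = np.asarray(cv.levels, dtype=object)[level_idx[cv.name]]
        if cv.unknown_rate > 0:
            labels[rng.random(n) < cv.unknown_rate] = UNKNOWN
        data[cv.name] = labels
    data["SERVICES"] = np.asarray(config.settings, dtype=object)[setting_idx]
    data["LIVARAG"] = np.asarray(statuses, dtype=object)[status_idx]
    outcome = np.where(treated, TREATED, NOT_TREATED).astype(object)
    if config.unknown_outcome_rate > 0:
        outcome[rng.random(n) < config.unknown_outcome_rate] = UNKNOWN
    data[OUTCOME] = outcome

    return AdmissionTable(pd.DataFrame(data), _build_codebook(config))


# ---------------------------------------------------------------------------
# planted truth


def planted_truth(
    config: GeneratorConfig,
    reference: str = INDEPENDENT,
    target: str = UNHOUSED,
) -> PlantedTruth:
    """Exact expectations for group rates and the reallocation decomposition.

    No sampling: ``expected_rate_by_group[g] = sum_s shares[g][s]*rates[g][s]``
    (in percent), and the counterfactual standardizes the target group's
    per-setting rates to the reference group's setting mix.
    """
    config.validate()
    for g in (reference, target):
        if g not in config.statuses:
            raise ConfigurationError(f"status {g!r} not in configuration")
    rates_pct = {
        g: float(
            100.0
            * np.asarray(config.setting_shares[g], dtype=float)
            @ np.asarray(config.setting_rates[g], dtype=float)
        )
        for g in config.statuses
    }
    cf = float(
        100.0
        * np.asarray(config.setting_shares[reference], dtype=float)
        @ np.asarray(config.setting_rates[target], dtype=float)
    )
    d_obs = rates_pct[reference] - rates_pct[target]
    d_cf = rates_pct[reference] - cf
    if d_obs != 0.0:
        share = 100.0 * (d_obs - d_cf) / d_obs
        defined = True
    else:
        share = float("nan")
        defined = False
    return PlantedTruth(
        expected_rate_by_group=rates_pct,
        expected_counterfactual_rate=cf,
        expected_observed_disparity=d_obs,
        expected_counterfactual_disparity=d_cf,
        expected_elimination_share=share,
        elimination_defined=defined,
    )


def brute_force_truth(
    config: GeneratorConfig, reference: str = INDEPENDENT, target: str = UNHOUSED
) -> PlantedTruth:
    """Independent oracle: exhaustive enumeration over (status, setting) cells.

    Loops cell by cell with plain Python arithmetic; kept deliberately free
    of the vectorized path used by :func:`planted_truth`.
    """
    rates: dict[str, float] = {}
    for g in config.statuses:
        acc = 0.0
        for s in range(len(config.settings)):
            acc += config.setting_shares[g][s] * config.setting_rates[g][s]
        rates[g] = 100.0 * acc
    cf = 0.0
    for s in range(len(config.settings)):
        cf += config.setting_shares[reference][s] * config.setting_rates[target][s]
    cf *= 100.0
    d_obs = rates[reference] - rates[target]
    d_cf = rates[reference] - cf
    defined = d_obs != 0.0
    share = 100.0 * (d_obs - d_cf) / d_obs if defined else float("nan")
    return PlantedTruth(rates, cf, d_obs, d_cf, share, defined)


# ---------------------------------------------------------------------------
# default (calibrated) configuration

# Per-setting MOUD rates, verbatim from the published cross-tab (percent/100).
_RATES_UNHOUSED = (0.6370, 0.1876, 0.5132, 0.1941, 0.0303, 0.1538, 0.2872, 0.1413)
_RATES_DEPENDENT = (0.3033, 0.1641, 0.6348, 0.1257, 0.0104, 0.6413, 0.2558, 0.2637)
_RATES_INDEPENDENT = (0.4719, 0.2787, 0.6360, 0.1387, 0.0080, 0.3035, 0.2999, 0.2534)
# Unknown-living cells: scaled dependent profile chosen so the overall rate
# closes at 40.40% given the living-status mix below.
_RATES_UNKNOWN = tuple(round(0.80 * r, 6) for r in _RATES_DEPENDENT)

# Setting-share vectors.  Four entries are printed facts (independent:
# 0.5618 / 0.1669; unhoused: 0.2356 / 0.3474); the rest were solved once so
# each group's expected rate and the overall setting mix match the published
# margins (see docs/methods.md).
_SHARES_INDEPENDENT = (
    0.030632, 0.030194, 0.5618, 0.1669,
    0.04966677183967132, 0.004, 0.0974102281603287, 0.059397,
)
_SHARES_DEPENDENT = (
    0.004, 0.32708428514056187, 0.350688, 0.119469,
    0.004, 0.004, 0.004, 0.1867587148594382,
)
_SHARES_UNHOUSED = (
    0.058111, 0.20178007127429703, 0.2356, 0.3474,
    0.004, 0.004, 0.004, 0.14510892872570297,
)
_SHARES_UNKNOWN = (
    0.004, 0.31708754518072413, 0.311285, 0.174438,
    0.004, 0.004, 0.004, 0.18118945481927595,
)

_LIVING_PROBS = {INDEPENDENT: 0.70, DEPENDENT: 0.10, UNHOUSED: 0.12, UNKNOWN: 0.08}


def _default_covariates() -> tuple[CovariateSpec, ...]:
    C = CovariateSpec
    return (
        C("AGE", "ordinal",
          ("Age12To14", "Age15To17", "Age18To20", "Age21To24", "Age25To29",
           "Age30To34", "Age35To39", "Age40To44", "Age45To49", "Age50To54",
           "Age55To64", "Age65Plus"),
          (0.002, 0.008, 0.03, 0.07, 0.16, 0.17, 0.15, 0.12, 0.10, 0.09, 0.08, 0.02),
          unknown_rate=0.001),
        C("GENDER", "categorical", ("Male", "Female"), (0.62, 0.38), unknown_rate=0.01),
        C("RACE", "categorical",
          ("White", "BlackAfricanAmerican", "AmericanIndian", "Asian", "OtherRace"),
          (0.70, 0.14, 0.03, 0.02, 0.11), unknown_rate=0.03),
        C("ETHNIC", "categorical", ("NotHispanic", "Hispanic"), (0.86, 0.14),
          unknown_rate=0.04),
        C("MARSTAT", "categorical",
          ("NeverMarried", "Married", "Separated", "Divorced", "Widowed"),
          (0.60, 0.17, 0.07, 0.13, 0.03), unknown_rate=0.06),
        C("EDUC", "ordinal",
          ("Grade8OrLess", "Grades9To11", "Grade12GED", "College1To3Years",
           "College4YearsPlus"),
          (0.08, 0.22, 0.42, 0.21, 0.07), unknown_rate=0.05),
        C("EMPLOY", "categorical",
          ("FullTime", "PartTime", "Unemployed", "NotInLaborForce"),
          (0.15, 0.07, 0.38, 0.40), unknown_rate=0.03),
        C("DETNLF", "categorical",
          ("Homemaker", "Student", "Retired", "ResidentInstitution",
           "OtherNotInLaborForce"),
          (0.10, 0.05, 0.20, 0.15, 0.50), unknown_rate=0.25),
        C("PSOURCE", "categorical",
          ("IndividualSelf", "AlcoholDrugProvider", "OtherHealthCareProvider",
           "SchoolEducational", "Employer", "OtherCommunityReferral",
           "CourtCriminalJustice"),
          (0.45, 0.12, 0.10, 0.005, 0.005, 0.17, 0.15), unknown_rate=0.02),
        C("DETCRIM", "categorical",
          ("StateFederalCourt", "FormalAdjudication", "Probation",
           "DiversionaryProgram", "DUI", "Prison", "OtherLegalEntity"),
          (0.25, 0.10, 0.30, 0.10, 0.05, 0.10, 0.10), unknown_rate=0.30),
        C("ARRESTS", "ordinal", ("NoArrests", "OneArrest", "TwoPlusArrests"),
          (0.90, 0.07, 0.03), unknown_rate=0.02),
        C("NOPRIOR", "ordinal",
          ("NoPriorTreatment", "OnePrior", "TwoPriors", "ThreePriors",
           "FourPriors", "FivePlusPriors"),
          (0.27, 0.22, 0.15, 0.10, 0.07, 0.19),
          effects=(-0.30, -0.05, 0.05, 0.10, 0.15, 0.20), unknown_rate=0.03),
        C("FREQ1", "ordinal", ("NoUseInPastMonth", "SomeUse", "DailyUse"),
          (0.27, 0.21, 0.52), effects=(-0.20, 0.00, 0.25), unknown_rate=0.04),
        C("SUB1", "categorical",
          ("Heroin", "NonPrescriptionMethadone", "OtherOpiatesSynthetics",
           "Alcohol", "Cocaine"),
          (0.60, 0.025, 0.275, 0.06, 0.04)),
        C("SUB2", "categorical",
          ("NoneReported", "Alcohol", "Cocaine", "Marijuana",
           "Methamphetamine", "Benzodiazepines"),
          (0.38, 0.12, 0.18, 0.17, 0.09, 0.06), unknown_rate=0.08),
        C("STFIPS", "categorical",
          ("California", "Florida", "Illinois", "Kentucky", "Massachusetts",
           "Michigan", "NewYork", "Ohio", "Pennsylvania", "Texas", "Virginia",
           "Washington"),
          (0.16, 0.07, 0.06, 0.04, 0.07, 0.05, 0.17, 0.08, 0.10, 0.07, 0.05, 0.08),
          effects=(0.55, -0.35, 0.15, -0.55, 0.80, -0.10, 0.65, -0.25, 0.30,
                   -0.70, -0.20, 0.10)),
        C("DSMCRIT", "categorical",
          ("OpioidDependence", "OpioidAbuse", "OtherSubstanceDisorder",
           "MentalDisorder"),
          (0.72, 0.10, 0.12, 0.06), unknown_rate=0.10),
        C("PSYPROB", "categorical", ("YesCoOccurring", "NoCoOccurring"),
          (0.38, 0.62), unknown_rate=0.08),
        C("HLTHINS", "categorical",
          ("PrivateInsurance", "Medicaid", "Medicare", "NoInsurance"),
          (0.16, 0.48, 0.08, 0.28), unknown_rate=0.15),
        C("PRIMPAY", "categorical",
          ("SelfPay", "PrivateInsurance", "Medicaid", "Medicare",
           "OtherGovernment", "NoCharge"),
          (0.22, 0.14, 0.40, 0.07, 0.09, 0.08), unknown_rate=0.20),
        C("PRIMINC", "categorical",
          ("Wages", "PublicAssistance", "RetirementPension", "DisabilityIncome",
           "OtherIncome", "NoIncome"),
          (0.30, 0.17, 0.05, 0.13, 0.10, 0.25), unknown_rate=0.15),
        C("DAYWAIT", "ordinal",
          ("WaitZeroDays", "Wait1To7Days", "Wait8To14Days", "Wait15To30Days",
           "Wait31PlusDays"),
          (0.62, 0.24, 0.07, 0.05, 0.02), unknown_rate=0.12),
        C("FREQ_ATND_SELF_HELP", "ordinal",
          ("NoAttendance", "Attended1To3Times", "Attended4To7Times",
           "Attended8To30Times"),
          (0.55, 0.20, 0.12, 0.13), unknown_rate=0.10),
    )


def default_config(n_admissions: int = 200_000, seed: int = 20190) -> GeneratorConfig:
    """The calibrated default study population (see module docstring)."""
    return GeneratorConfig(
        n_admissions=n_admissions,
        living_status_probs=dict(_LIVING_PROBS),
        setting_shares={
            INDEPENDENT: _SHARES_INDEPENDENT,
            DEPENDENT: _SHARES_DEPENDENT,
            UNHOUSED: _SHARES_UNHOUSED,
            UNKNOWN: _SHARES_UNKNOWN,
        },
        setting_rates={
            INDEPENDENT: _RATES_INDEPENDENT,
            DEPENDENT: _RATES_DEPENDENT,
            UNHOUSED: _RATES_UNHOUSED,
            UNKNOWN: _RATES_UNKNOWN,
        },
        covariates=_default_covariates(),
        unknown_outcome_rate=0.073,
        seed=seed,
    )
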