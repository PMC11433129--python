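"""Cohort filters, class balancing, splitting and ordinal/categorical encoding.

The canonical order, mirroring how the analysis cohort is built, is::

    filter_opioid_admissions -> drop_unknown_outcome -> drop_excluded_features
    -> merge_detail_variables -> balance_classes -> split -> encode

Re-running with the same seed reproduces every matrix bit-identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codebook import VariableCodebook
from .errors import (
    BalancingError,
    ConfigurationError,
    SchemaError,
    SplitError,
    ValidationError,
)
from .table import NOT_TREATED, TREATED, AdmissionTable
from .teds_io import merge_detail_variables

#: primary-substance codes defining the opioid cohort
DEFAULT_OPIOID_CODES = frozenset(
    {"Heroin", "NonPrescriptionMethadone", "OtherOpiatesSynthetics"}
)

#: features excluded from modelling (admission year is constant; case ID is an index)
DEFAULT_EXCLUSIONS = ("CASEID", "ADMYR")


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions; validation selects hyperparameters,
    test is the held-out set for final metrics."""

    train_fraction: float = 0.70
    validation_fraction: float = 0.15
    test_fraction: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        fr = (self.train_fraction, self.validation_fraction, self.test_fraction)
        if any(f <= 0 for f in fr):
            raise ConfigurationError("all split fractions must be > 0")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ConfigurationError("split fractions must sum to 1")


@dataclass
class EncodedMatrix:
    """Numeric model-ready matrix with per-feature metadata.

    Ordinal features carry their codebook rank; categorical features carry
    the (stable) codebook level index.  The unknown label is an ordinary
    level, never a missing value.
    """

    values: np.ndarray
    feature_names: list[str]
    ordinal_flags: np.ndarray
    level_maps: dict[str, tuple[str, ...]]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def decode(self) -> pd.DataFrame:
        """Inverse of :func:`encode` (label round-trip)."""
        cols = {}
        for j, name in enumerate(self.feature_names):
            levels = np.asarray(self.level_maps[name], dtype=object)
            cols[name] = levels[self.values[:, j].astype(np.int64)]
        return pd.DataFrame(cols)


def filter_opioid_admissions(
    table: AdmissionTable, opioid_codes=DEFAULT_OPIOID_CODES
) -> AdmissionTable:
    """Keep only rows whose primary substance (SUB1) is an opioid."""
    if "SUB1" not in table.df.columns:
        raise SchemaError("SUB1 column required for the opioid filter")
    keep = table.df["SUB1"].isin(set(opioid_codes))
    if not keep.any():
        warnings.warn("opioid filter removed every row")
    return table.with_df(table.df.loc[keep].reset_index(drop=True))


def drop_unknown_outcome(table: AdmissionTable) -> tuple[AdmissionTable, float]:
    """Remove rows with an unknown outcome; report the dropped fraction."""
    if table.outcome_column not in table.df.columns:
        raise SchemaError(f"outcome column {table.outcome_column!r} missing")
    unknown = table.codebook[table.outcome_column].unknown_label
    bad = table.df[table.outcome_column] == unknown
    frac = float(bad.mean()) if len(bad) else 0.0
    if frac == 1.0:
        warnings.warn("every outcome is unknown; result is empty")
    return table.with_df(table.df.loc[~bad].reset_index(drop=True)), frac


def drop_excluded_features(
    table: AdmissionTable, exclusions=DEFAULT_EXCLUSIONS
) -> AdmissionTable:
    """Drop named columns if present (absent names warn and are ignored)."""
    present = [c for c in exclusions if c in table.df.columns]
    absent = [c for c in exclusions if c not in table.df.columns]
    if absent:
        warnings.warn(f"exclusions not present: {absent}")
    cb = table.codebook.copy()
    for c in present:
        cb.drop(c)
    return table.with_df(table.df.drop(columns=present), cb)


def balance_classes(table: AdmissionTable, seed: int) -> AdmissionTable:
    """Random-undersample the majority outcome class to exact equality.

    All minority rows are retained; for odd majorities the extra rows are
    discarded so counts are exactly equal.  Deterministic for a fixed seed.
    """
    y = table.df[table.outcome_column]
    counts = y.value_counts()
    if TREATED not in counts or NOT_TREATED not in counts:
        raise BalancingError("both outcome classes must be present to balance")
    n_min = int(counts.min())
    minority = counts.idxmin()
    rng = np.random.default_rng(seed)
    keep_idx = []
    for cls in (NOT_TREATED, TREATED):
        idx = np.flatnonzero((y == cls).to_numpy())
        if cls != minority and len(idx) > n_min:
            idx = np.sort(rng.choice(idx, size=n_min, replace=False))
        keep_idx.append(idx)
    keep = np.sort(np.concatenate(keep_idx))
    return table.with_df(table.df.iloc[keep].reset_index(drop=True))


def _allocate(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Largest-remainder rounding of ``n`` into parts ~ proportional."""
    raw = [n * f for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    short = n - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)])
    for k in order[:short]:
        base[k] += 1
    return base


def split(
    table: AdmissionTable, spec: SplitSpec
) -> tuple[AdmissionTable, AdmissionTable, AdmissionTable]:
    """Disjoint stratified train/validation/test partition.

    Stratified by outcome within rounding; the union of the three parts is
    the input row set.  Deterministic for a fixed seed.
    """
    spec.validate()
    if table.n_rows < 3:
        raise SplitError("need at least 3 rows to split")
    fractions = (spec.train_fraction, spec.validation_fraction, spec.test_fraction)
    rng = np.random.default_rng(spec.seed)
    parts: list[list[np.ndarray]] = [[], [], []]
    y = table.df[table.outcome_column].to_numpy()
    for cls in pd.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        sizes = _allocate(len(idx), fractions)
        stops = np.cumsum(sizes)
        parts[0].append(idx[: stops[0]])
        parts[1].append(idx[stops[0]: stops[1]])
        parts[2].append(idx[stops[1]: stops[2]])
    out = []
    for chunk in parts:
        sel = np.sort(np.concatenate(chunk))
        out.append(table.with_df(table.df.iloc[sel].reset_index(drop=True)))
    return out[0], out[1], out[2]


def encode(
    table: AdmissionTable,
    codebook: VariableCodebook | None = None,
    include_outcome: bool = False,
) -> EncodedMatrix:
    """Integer-encode every feature column by codebook level position.

    Ordinal columns map to rank integers respecting the declared order;
    categorical columns get the same stable positional codes (the model
    treats them as unordered splits on arbitrary integers, as is
    conventional for tree learners on coded data).
    """
    cb = codebook or table.codebook
    names = [
        c
        for c in table.df.columns
        if (include_outcome or c != table.outcome_column) and cb[c].kind != "index"
    ]
    n = table.n_rows
    values = np.empty((n, len(names)), dtype=np.float64)
    flags = np.zeros(len(names), dtype=bool)
    level_maps: dict[str, tuple[str, ...]] = {}
    for j, name in enumerate(names):
        var = cb[name]
        lut = {lab: k for k, lab in enumerate(var.levels)}
        col = table.df[name].map(lut)
        if col.isna().any():
            row = int(col.isna().idxmax())
            raise ValidationError(
                f"row {row}, variable {name}: level {table.df[name].iloc[row]!r} "
                "not encodable"
            )
        values[:, j] = col.to_numpy(dtype=np.float64)
        flags[j] = var.kind == "ordinal"
        level_maps[name] = var.levels
        if len(pd.unique(values[:, j])) == 1 and n > 1:
            warnings.warn(f"feature {name} is constant in this table")
    return EncodedMatrix(values, names, flags, level_maps)


def outcome_labels(table: AdmissionTable) -> np.ndarray:
    """0/1 outcome vector; unknown outcomes must have been dropped first."""
    unknown = table.codebook[table.outcome_column].unknown_label
    y = table.df[table.outcome_column]
    if (y == unknown).any():
        raise ValidationError("unknown outcomes present; drop them before labelling")
    return (y == TREATED).to_numpy(dtype=np.int64)


def prepare(
    table: AdmissionTable,
    split_spec: SplitSpec,
    balance_seed: int,
    opioid_codes=DEFAULT_OPIOID_CODES,
    exclusions=DEFAULT_EXCLUSIONS,
):
    """Run the full fixed-order preprocessing pipeline.

    Returns ``(cohort, parts, matrices, labels, dropped_fraction)`` where
    ``cohort`` is the descriptive-statistics population (after filtering and
    merging, before balancing), ``parts``/``matrices``/``labels`` are
    (train, validation, test) triples.
    """
    t = filter_opioid_admissions(table, opioid_codes)
    t, dropped = drop_unknown_outcome(t)
    t = drop_excluded_features(t, exclusions)
    cohort = merge_detail_variables(t)
    balanced = balance_classes(cohort, balance_seed)
    parts = split(balanced, split_spec)
    matrices = tuple(encode(p) for p in parts)
    labels = tuple(outcome_labels(p) for p in parts)
    return cohort, parts, matrices, labels, dropped
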