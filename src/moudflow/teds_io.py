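"""Read/write coded admission tables and apply detail-variable merges.

Files follow the dialect of the national treatment-admissions extract:
a CSV with one header row of upper-case variable names and integer-coded
categories, plus a sidecar YAML codebook mapping codes to labels
(:mod:`moudflow.codebook`).

The merges fold a detail ("child") variable into its parent: the detail
for people not in the labor force into the employment variable, and the
detailed criminal-justice referral into the referral source.  The merged
level keeps the child label verbatim; a child level whose label collides
with a parent level is namespaced ``"CHILD:label"``, and an unknown child
under a detail-triggering parent becomes ``"<trigger>-Unknown"`` so that
unknownness stays its own informative category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codebook import VariableCodebook, VariableDef
from .errors import SchemaError, ValidationError
from .table import AdmissionTable


def write_admissions(table: AdmissionTable, path, codebook_path=None) -> None:
    """Write integer-coded CSV; optionally the codebook YAML alongside."""
    df = table.df
    out = {}
    for name in df.columns:
        var = table.codebook[name]
        if var.kind == "index":
            out[name] = df[name].to_numpy()
        else:
            out[name] = df[name].map(var.codes).astype(np.int64).to_numpy()
    pd.DataFrame(out).to_csv(path, index=False)
    if codebook_path is not None:
        table.codebook.to_yaml(codebook_path)


def read_admissions(path, codebook: VariableCodebook, outcome_column: str = "METHUSE") -> AdmissionTable:
    """Read an integer-coded CSV and resolve codes to labels.

    Columns not declared in the codebook are tolerated with a warning and
    dropped; an integer code with no codebook label raises
    :class:`ValidationError` naming the first offending row and variable.
    """
    raw = pd.read_csv(path)
    known = [c for c in raw.columns if c in codebook]
    extra = [c for c in raw.columns if c not in codebook]
    if extra:
        warnings.warn(f"ignoring columns without codebook entries: {extra}")
    if outcome_column not in known:
        raise SchemaError(f"required outcome column {outcome_column!r} missing")
    data = {}
    for name in known:
        var = codebook[name]
        if var.kind == "index":
            data[name] = raw[name].to_numpy()
            continue
        mapped = raw[name].map(var.labels_by_code)
        if mapped.isna().any():
            row = int(mapped.isna().idxmax())
            raise ValidationError(
                f"row {row}, variable {name}: code {raw[name].iloc[row]!r} "
                "not in codebook"
            )
        data[name] = mapped.to_numpy(dtype=object)
    table = AdmissionTable(pd.DataFrame(data), codebook, outcome_column=outcome_column)
    table.validate()
    return table


@dataclass(frozen=True)
class MergeSpec:
    """Fold ``child`` into ``parent`` where parent equals ``trigger``."""

    parent: str
    child: str
    trigger: str
    name: str


DEFAULT_MERGES = (
    MergeSpec("EMPLOY", "DETNLF", "NotInLaborForce", "EMPLOY_DETNLF"),
    MergeSpec("PSOURCE", "DETCRIM", "CourtCriminalJustice", "PSOURCE_DETCRIM"),
)


def _merge_one(table: AdmissionTable, spec: MergeSpec) -> AdmissionTable:
    df = table.df
    cb = table.codebook
    if spec.name in df.columns and spec.parent not in df.columns:
        warnings.warn(f"{spec.name} already merged; no-op")
        return table
    for col in (spec.parent, spec.child):
        if col not in df.columns:
            raise SchemaError(f"merge {spec.name}: column {col!r} missing")
    parent_var, child_var = cb[spec.parent], cb[spec.child]
    if spec.trigger not in parent_var.levels:
        raise SchemaError(
            f"merge {spec.name}: trigger level {spec.trigger!r} not in {spec.parent}"
        )
    parent_levels = [l for l in parent_var.levels if l != spec.trigger]
    unknown = parent_var.unknown_label
    unknown_detail = f"{spec.trigger}-{child_var.unknown_label}"

    def child_label(lab: str) -> str:
        if lab == child_var.unknown_label:
            return unknown_detail
        if lab in parent_levels:
            return f"{spec.child}:{lab}"  # namespacing fallback on collision
        return lab

    parent_vals = df[spec.parent].to_numpy(dtype=object)
    child_vals = df[spec.child].to_numpy(dtype=object)
    trig = parent_vals == spec.trigger
    merged = parent_vals.copy()
    merged[trig] = [child_label(l) for l in child_vals[trig]]

    levels = [l for l in parent_levels if l != unknown]
    levels += [child_label(l) for l in child_var.levels if l != child_var.unknown_label]
    levels += [unknown_detail, unknown]
    new_cb = cb.copy()
    new_cb.drop(spec.parent)
    new_cb.drop(spec.child)
    new_cb.add(VariableDef(spec.name, "categorical", tuple(levels), unknown_label=unknown))

    cols = {}
    for name in df.columns:
        if name == spec.parent:
            cols[spec.name] = merged
        elif name == spec.child:
            continue
        else:
            cols[name] = df[name].to_numpy()
    return table.with_df(pd.DataFrame(cols, index=df.index), new_cb)


def merge_detail_variables(
    table: AdmissionTable, merges: tuple[MergeSpec, ...] = DEFAULT_MERGES
) -> AdmissionTable:
    """Apply every merge in turn; idempotent on already-merged tables."""
    for spec in merges:
        table = _merge_one(table, spec)
    return table
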