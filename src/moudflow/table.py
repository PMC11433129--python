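"""The in-memory admission table: a labelled DataFrame plus its codebook."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .codebook import VariableCodebook
from .errors import SchemaError, ValidationError

#: default name of the binary medication-receipt outcome column
OUTCOME = "METHUSE"
TREATED, NOT_TREATED = "Yes", "No"


@dataclass
class AdmissionTable:
    """One row per admission; values are level labels resolved via ``codebook``.

    The outcome column is binary (``Yes``/``No``) or the unknown label.
    Operations on tables return new tables; the frame is never mutated in
    place.
    """

    df: pd.DataFrame
    codebook: VariableCodebook
    outcome_column: str = OUTCOME

    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def with_df(self, df: pd.DataFrame, codebook: VariableCodebook | None = None) -> "AdmissionTable":
        return replace(self, df=df, codebook=codebook or self.codebook)

    def validate(self) -> None:
        """Check every coded value resolves to a codebook level.

        Raises :class:`ValidationError` naming the first offending row and
        variable; :class:`SchemaError` if the outcome column is absent.
        """
        if self.outcome_column not in self.df.columns:
            raise SchemaError(f"outcome column {self.outcome_column!r} missing")
        for name in self.df.columns:
            if name not in self.codebook:
                raise SchemaError(f"column {name!r} has no codebook entry")
            var = self.codebook[name]
            if var.kind == "index":
                continue
            allowed = set(var.levels)
            col = self.df[name]
            bad = ~col.isin(allowed)
            if bad.any():
                row = int(bad.idxmax())
                raise ValidationError(
                    f"row {row}, variable {name}: value {col.loc[row]!r} "
                    "not a codebook level"
                )
        out = self.codebook[self.outcome_column]
        non_unknown = [l for l in out.levels if l != out.unknown_label]
        if set(non_unknown) != {TREATED, NOT_TREATED}:
            raise ValidationError(
                f"outcome column must be binary {TREATED}/{NOT_TREATED} plus unknown"
            )
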