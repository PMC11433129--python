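"""Variable codebooks for coded admission tables.

A codebook declares, for every variable, whether it is ordinal or purely
categorical, the ordered list of level labels, the label that stands for
"Unknown", and the integer code written for each level in delimited files.
"Unknown" is always a first-class level, never a missing value: the
analysis treats unknownness itself as informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import ConfigurationError, SchemaError

#: integer written to file for the unknown level (TEDS convention)
UNKNOWN_CODE = -9

KINDS = ("ordinal", "categorical", "index")


@dataclass(frozen=True)
class VariableDef:
    """One variable: its kind, ordered levels and unknown label.

    For ordinal variables the level order is the total order the encoder
    respects (e.g. AGE from youngest to oldest band). ``kind='index'``
    marks free-integer identifier columns (case IDs) that are written
    verbatim and never validated against levels.
    """

    name: str
    kind: str
    levels: tuple[str, ...] = ()
    unknown_label: str = "Unknown"
    codes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigurationError(f"{self.name}: unknown variable kind {self.kind!r}")
        if self.kind == "index":
            return
        if len(set(self.levels)) != len(self.levels):
            raise ConfigurationError(f"{self.name}: duplicate level labels")
        if self.unknown_label not in self.levels:
            raise ConfigurationError(
                f"{self.name}: unknown label {self.unknown_label!r} missing from levels"
            )
        if not self.codes:
            codes = {}
            nxt = 1
            for lab in self.levels:
                if lab == self.unknown_label:
                    codes[lab] = UNKNOWN_CODE
                else:
                    codes[lab] = nxt
                    nxt += 1
            object.__setattr__(self, "codes", codes)
        if set(self.codes) != set(self.levels):
            raise ConfigurationError(f"{self.name}: codes do not cover levels")

    @property
    def labels_by_code(self) -> dict[int, str]:
        return {c: l for l, c in self.codes.items()}

    def rank(self, label: str) -> int:
        """Position of ``label`` in the declared level order."""
        return self.levels.index(label)


class VariableCodebook:
    """Ordered collection of :class:`VariableDef` keyed by variable name."""

    def __init__(self, entries: list[VariableDef] | tuple[VariableDef, ...] = ()):
        self._entries: dict[str, VariableDef] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: VariableDef) -> None:
        if entry.name in self._entries:
            raise ConfigurationError(f"duplicate codebook variable {entry.name}")
        self._entries[entry.name] = entry

    def replace(self, entry: VariableDef) -> None:
        self._entries[entry.name] = entry

    def drop(self, name: str) -> None:
        self._entries.pop(name, None)

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __getitem__(self, name: str) -> VariableDef:
        try:
            return self._entries[name]
        except KeyError:
            raise SchemaError(f"variable {name!r} not in codebook") from None

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def names(self) -> list[str]:
        return list(self._entries)

    def copy(self) -> "VariableCodebook":
        return VariableCodebook(list(self._entries.values()))

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "variables": [
                {
                    "name": e.name,
                    "kind": e.kind,
                    "unknown": e.unknown_label,
                    "levels": [
                        {"code": e.codes[lab], "label": lab} for lab in e.levels
                    ],
                }
                for e in self
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VariableCodebook":
        entries = []
        for v in d["variables"]:
            levels = tuple(lv["label"] for lv in v.get("levels", []))
            codes = {lv["label"]: int(lv["code"]) for lv in v.get("levels", [])}
            entries.append(
                VariableDef(
                    name=v["name"],
                    kind=v["kind"],
                    levels=levels,
                    unknown_label=v.get("unknown", "Unknown"),
                    codes=codes,
                )
            )
        return cls(entries)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "VariableCodebook":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
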