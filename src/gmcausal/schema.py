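"""Variable schemas for cohort tables.

A cohort table is a plain :class:`pandas.DataFrame`, one row per subject.
The schema attaches per-variable metadata that the rest of the pipeline
relies on: the measurement kind (continuous vs. binary), units, and role
constraints used as prior knowledge during structure discovery (exogenous
demographic variables may not acquire parents; the outcome may not acquire
children).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

CONTINUOUS = "continuous"
BINARY = "binary"


@dataclass(frozen=True)
class VariableSchema:
    """Metadata for a single cohort variable.

    Parameters
    ----------
    name : str
        Column name, unique within a schema.
    kind : {"continuous", "binary"}
        Measurement kind. Binary columns hold {0, 1} (missing allowed).
    units : str, optional
        Measurement units, for reporting only.
    may_have_parents : bool, optional
        If False the variable is treated as exogenous during structure
        discovery (no incoming edges allowed).
    may_have_children : bool, optional
        If False the variable is a terminal outcome (no outgoing edges).
    """

    name: str
    kind: str
    units: str = ""
    may_have_parents: bool = True
    may_have_children: bool = True

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, BINARY):
            raise ValueError(f"unknown variable kind {self.kind!r} for {self.name!r}")


#: Schema of the nine-variable cardiometabolic / gray-matter cohort.
#: Sex is coded 1 = male, 0 = female; smoking 1 = current or previous smoker.
#: Age and sex are exogenous; normalized gray matter volume (GMV) is the
#: outcome and may not have children.
DEFAULT_SCHEMA: tuple[VariableSchema, ...] = (
    VariableSchema("age", CONTINUOUS, "years", may_have_parents=False),
    VariableSchema("sex", BINARY, "1=male", may_have_parents=False),
    VariableSchema("smoking", BINARY, "1=ever-smoker"),
    VariableSchema("whr", CONTINUOUS, "waist/hip ratio"),
    VariableSchema("bmi", CONTINUOUS, "kg/m^2"),
    VariableSchema("bfp", CONTINUOUS, "%"),
    VariableSchema("pa", CONTINUOUS, "min/day"),
    VariableSchema("sbp", CONTINUOUS, "mmHg"),
    VariableSchema("gmv", CONTINUOUS, "ml", may_have_children=False),
)


def schema_by_name(schema: Iterable[VariableSchema]) -> dict[str, VariableSchema]:
    out: dict[str, VariableSchema] = {}
    for var in schema:
        if var.name in out:
            raise ValueError(f"duplicate variable name {var.name!r} in schema")
        out[var.name] = var
    return out


def continuous_variables(schema: Iterable[VariableSchema]) -> list[str]:
    return [v.name for v in schema if v.kind == CONTINUOUS]


def binary_variables(schema: Iterable[VariableSchema]) -> list[str]:
    return [v.name for v in schema if v.kind == BINARY]
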