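"""Aggregate-mode population tables.

Published per-capita intake tables report population-weighted mean daily
intake in parallel columns: total, core choices, discretionary choices, and
the discretionary food / beverage split.  An :class:`AggregateTable` holds one
:class:`~dietsim.nutrients.NutrientProfile` per column and lets the scenario
transforms run directly on such a table ("aggregate mode") — useful both as a
worked example and as an exact oracle for the linear transforms.

The printed columns are *not* assumed additive: survey conventions put sports
products and meal replacements inside the "discretionary choices" column but
outside the beverage column, so foods + beverages need not equal choices.
Transforms therefore work in deltas: each column receives the delta of the
items it covers, and the total receives the full delta.

``load_reference()`` returns the bundled Australian Health Survey 2011–12
adult per-capita table (19+ years, n = 9341, one 24-h recall, population
weighted), the base case all worked examples start from.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from importlib import resources
from typing import Dict

import pandas as pd

from .nutrients import MACRO_FIELDS, MICRONUTRIENT_UNITS, NutrientProfile

__all__ = ["AggregateTable", "COLUMNS", "load_reference"]

COLUMNS = (
    "total",
    "core",
    "discretionary",
    "discretionary_foods",
    "discretionary_beverages",
)


@dataclass
class AggregateTable:
    """Per-capita mean intake profiles, one per published column."""

    columns: Dict[str, NutrientProfile] = dc_field(default_factory=dict)

    def __getitem__(self, column: str) -> NutrientProfile:
        return self.columns[column]

    def __setitem__(self, column: str, profile: NutrientProfile) -> None:
        if column not in COLUMNS:
            raise KeyError(f"unknown aggregate column {column!r}")
        self.columns[column] = profile

    def copy(self) -> "AggregateTable":
        return AggregateTable(columns=dict(self.columns))

    def apply_deltas(self, deltas: Dict[str, NutrientProfile]) -> "AggregateTable":
        """Return a new table with per-column deltas applied.

        The total column always receives the sum of the food/beverage-level
        deltas; the discretionary column receives those attributable to
        discretionary items.
        """
        out = self.copy()
        for column, delta in deltas.items():
            out[column] = out[column] + delta
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AggregateTable":
        required = {"field", "unit", *COLUMNS}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"aggregate table missing column(s) {sorted(missing)}")
        table = cls()
        for column in COLUMNS:
            amounts: Dict[str, float] = {}
            micros: Dict[str, float] = {}
            for _, row in df.iterrows():
                name = row["field"]
                value = float(row[column])
                if name in MACRO_FIELDS:
                    amounts[name] = value
                elif name in MICRONUTRIENT_UNITS:
                    micros[name] = value
                else:
                    raise ValueError(f"unknown nutrient field {name!r}")
            table.columns[column] = NutrientProfile(**amounts, micronutrients=micros)
        return table

    @classmethod
    def from_csv(cls, path) -> "AggregateTable":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        names = list(MACRO_FIELDS) + list(MICRONUTRIENT_UNITS)
        units = {**MACRO_FIELDS, **MICRONUTRIENT_UNITS}
        for name in names:
            rows.append(
                {
                    "field": name,
                    "unit": units[name],
                    **{c: self.columns[c].get(name) for c in COLUMNS},
                }
            )
        return pd.DataFrame(rows)


def load_reference() -> AggregateTable:
    """Bundled AHS 2011–12 adult per-capita base-case intake table."""
    with resources.files("dietsim.data").joinpath("ahs_adult_basecase.csv").open() as fh:
        return AggregateTable.from_csv(fh)
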