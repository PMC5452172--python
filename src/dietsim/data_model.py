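"""Domain types, food classification and file I/O for dietary survey data.

The data model mirrors how national nutrition surveys store a 24-h recall:
a food-composition table keyed by 8-digit food code (per-100 g nutrient
values plus classification flags), a person file with population expansion
weights, and an intake file of (person, food code, grams) lines.

Files are UTF-8 text, tab- or comma-delimited (auto-detected from the header
line), with "." as decimal separator.  pandas does the parsing; this module
owns schema validation, unit bookkeeping and referential integrity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import pandas as pd

from .nutrients import (
    MACRO_FIELDS,
    MICRONUTRIENT_UNITS,
    NutrientProfile,
    ProfileInvariantError,
)

__all__ = [
    "CLASS_LABELS",
    "FoodItem",
    "Person",
    "IntakeLine",
    "PopulationDataset",
    "classify",
    "SchemaError",
    "ValidationError",
    "ReferentialError",
    "read_composition_table",
    "write_composition_table",
    "read_persons",
    "write_persons",
    "read_intakes",
    "write_intakes",
]

CLASS_LABELS = (
    "core_food",
    "core_beverage",
    "discretionary_food",
    "discretionary_beverage",
)

DISCRETIONARY_LABELS = frozenset({"discretionary_food", "discretionary_beverage"})


class SchemaError(ValueError):
    """Input file is missing or mis-declares a required column."""


class ValidationError(ValueError):
    """A record carries a physically invalid value."""


class ReferentialError(ValueError):
    """An intake line references an unknown food code or person id."""


@dataclass(frozen=True)
class FoodItem:
    """One coded food: classification flags plus per-100 g composition."""

    food_code: str
    name: str
    subgroup_code: str
    is_discretionary: bool
    is_beverage: bool
    is_water_based: bool = False
    is_alcoholic: bool = False
    is_milk: bool = False
    is_sports_or_meal_replacement: bool = False
    composition: NutrientProfile = field(default_factory=NutrientProfile)

    def validate(self, tolerance: float = 0.02) -> None:
        if self.is_water_based and not self.is_beverage:
            raise ValidationError(
                f"{self.food_code}: water-based flag requires beverage flag"
            )
        if self.is_alcoholic and not self.is_beverage:
            raise ValidationError(
                f"{self.food_code}: alcoholic flag requires beverage flag"
            )
        try:
            self.composition.validate(tolerance=tolerance, context=self.food_code)
        except ProfileInvariantError as exc:
            raise ValidationError(str(exc)) from exc


@dataclass(frozen=True)
class Person:
    """Survey respondent with a positive population expansion weight."""

    person_id: str
    weight: float
    age: Optional[float] = None
    sex: Optional[str] = None

    def validate(self) -> None:
        if not self.weight > 0:
            raise ValidationError(
                f"{self.person_id}: population weight must be > 0, got {self.weight}"
            )


@dataclass(frozen=True)
class IntakeLine:
    """Grams of one food code consumed by one person on the recall day."""

    person_id: str
    food_code: str
    grams: float

    def validate(self) -> None:
        if self.grams < 0:
            raise ValidationError(
                f"{self.person_id}/{self.food_code}: negative grams {self.grams}"
            )


def classify(item: FoodItem, milk_as_food: bool = True) -> str:
    """Map a food to one of the four core/discretionary class labels.

    Milk-family items (plain and flavoured milk) are consumed as liquids but
    behave nutritionally as foods (protein, calcium, satiety; eaten on
    cereal), so with ``milk_as_food`` they classify as food even when the
    beverage flag is set.
    """
    beverage = item.is_beverage and not (milk_as_food and item.is_milk)
    if item.is_discretionary:
        return "discretionary_beverage" if beverage else "discretionary_food"
    return "core_beverage" if beverage else "core_food"


@dataclass
class PopulationDataset:
    """Composition table + persons + intake lines, referentially consistent."""

    foods: Dict[str, FoodItem]
    persons: Dict[str, Person]
    intakes: List[IntakeLine]

    def validate(self) -> None:
        for item in self.foods.values():
            item.validate()
        for person in self.persons.values():
            person.validate()
        bad = []
        for line in self.intakes:
            line.validate()
            if line.food_code not in self.foods or line.person_id not in self.persons:
                bad.append((line.person_id, line.food_code))
        if bad:
            raise ReferentialError(f"intake lines with unknown references: {bad[:10]}")

    def labels(self, milk_as_food: bool = True) -> Dict[str, str]:
        """food_code -> class label for every food in the table."""
        return {
            code: classify(item, milk_as_food=milk_as_food)
            for code, item in self.foods.items()
        }

    def copy(self) -> "PopulationDataset":
        return PopulationDataset(
            foods=dict(self.foods),
            persons=dict(self.persons),
            intakes=list(self.intakes),
        )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_FLAG_COLUMNS = (
    "is_discretionary",
    "is_beverage",
    "is_water_based",
    "is_alcoholic",
    "is_milk",
    "is_sports_or_meal_replacement",
)


def _nutrient_column(name: str) -> str:
    unit = MACRO_FIELDS.get(name) or MICRONUTRIENT_UNITS[name]
    return f"{name}_{unit}_per100g"

# Composition columns carry an explicit unit suffix so a file cannot silently
# change units; the reader checks the suffix against this registry.
COMPOSITION_NUTRIENT_COLUMNS: Mapping[str, str] = {
    _nutrient_column(name): name
    for name in list(MACRO_FIELDS) + list(MICRONUTRIENT_UNITS)
    if name != "grams_food_weight"
}


def _sniff_sep(path: Path) -> str:
    header = Path(path).open("r", encoding="utf-8").readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _read_table(path: Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip",
                     dtype={"food_code": str, "person_id": str,
                            "subgroup_code": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"1", "true", "yes"}
    return bool(value)


def read_composition_table(path, tolerance: float = 0.02) -> Dict[str, FoodItem]:
    """Read and validate a composition table; returns food_code -> FoodItem."""
    required = ["food_code", "name", "subgroup_code", "is_discretionary",
                "is_beverage"]
    df = _read_table(path, required)
    nutrient_cols = [c for c in df.columns if c in COMPOSITION_NUTRIENT_COLUMNS]
    unknown_suffixed = [
        c for c in df.columns
        if c.endswith("_per100g") and c not in COMPOSITION_NUTRIENT_COLUMNS
    ]
    if unknown_suffixed:
        raise SchemaError(
            f"{path}: unrecognised nutrient column(s) {unknown_suffixed}; "
            "check name/unit suffix against the column registry"
        )
    foods: Dict[str, FoodItem] = {}
    for _, row in df.iterrows():
        code = str(row["food_code"])
        if code in foods:
            raise ValidationError(f"duplicate food_code {code}")
        amounts = {"grams_food_weight": 100.0}
        micros: Dict[str, float] = {}
        for col in nutrient_cols:
            name = COMPOSITION_NUTRIENT_COLUMNS[col]
            value = float(row[col]) if pd.notna(row[col]) else 0.0
            if value < 0:
                raise ValidationError(f"{code}: negative {name} ({value})")
            if name in MICRONUTRIENT_UNITS:
                micros[name] = value
            else:
                amounts[name] = value
        item = FoodItem(
            food_code=code,
            name=str(row["name"]),
            subgroup_code=str(row["subgroup_code"]),
            **{flag: _as_bool(row[flag]) if flag in df.columns else False
               for flag in _FLAG_COLUMNS},
            composition=NutrientProfile(**amounts, micronutrients=micros),
        )
        item.validate(tolerance=tolerance)
        foods[code] = item
    return foods


def write_composition_table(foods: Mapping[str, FoodItem], path) -> None:
    """Canonical TSV writer; ``read(write(x)) == x`` for finite values."""
    rows = []
    for code in sorted(foods):
        item = foods[code]
        row = {
            "food_code": item.food_code,
            "name": item.name,
            "subgroup_code": item.subgroup_code,
            **{flag: int(getattr(item, flag)) for flag in _FLAG_COLUMNS},
        }
        for col, name in COMPOSITION_NUTRIENT_COLUMNS.items():
            row[col] = repr(item.composition.get(name) if name in MACRO_FIELDS
                            else item.composition.micronutrients.get(name, 0.0))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_persons(path) -> Dict[str, Person]:
    df = _read_table(path, ["person_id", "weight"])
    persons: Dict[str, Person] = {}
    for _, row in df.iterrows():
        pid = str(row["person_id"])
        if pid in persons:
            raise ValidationError(f"duplicate person_id {pid}")
        person = Person(
            person_id=pid,
            weight=float(row["weight"]),
            age=float(row["age"]) if "age" in df.columns and pd.notna(row["age"]) else None,
            sex=str(row["sex"]) if "sex" in df.columns and pd.notna(row["sex"]) else None,
        )
        person.validate()
        persons[pid] = person
    return persons


def write_persons(persons: Mapping[str, Person], path) -> None:
    rows = [
        {
            "person_id": p.person_id,
            "weight": repr(p.weight),
            "age": "" if p.age is None else repr(p.age),
            "sex": "" if p.sex is None else p.sex,
        }
        for p in sorted(persons.values(), key=lambda p: p.person_id)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_intakes(path, foods: Mapping[str, FoodItem],
                 persons: Mapping[str, Person]) -> List[IntakeLine]:
    """Read intake lines, enforcing referential integrity.

    Zero-gram lines are retained: they carry no nutrients but preserve the
    record count of the recall (trace entries are common in survey data).
    """
    df = _read_table(path, ["person_id", "food_code", "grams"])
    lines: List[IntakeLine] = []
    unknown = []
    for _, row in df.iterrows():
        line = IntakeLine(
            person_id=str(row["person_id"]),
            food_code=str(row["food_code"]),
            grams=float(row["grams"]),
        )
        line.validate()
        if line.food_code not in foods or line.person_id not in persons:
            unknown.append((line.person_id, line.food_code))
        lines.append(line)
    if unknown:
        raise ReferentialError(
            f"{path}: {len(unknown)} intake line(s) with unknown food_code or "
            f"person_id, first offenders: {unknown[:10]}"
        )
    return lines


def write_intakes(intakes: Iterable[IntakeLine], path) -> None:
    rows = [
        {"person_id": l.person_id, "food_code": l.food_code, "grams": repr(l.grams)}
        for l in intakes
    ]
    pd.DataFrame(rows, columns=["person_id", "food_code", "grams"]).to_csv(
        path, sep="\t", index=False
    )
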