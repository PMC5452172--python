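"""Nutrient accounting primitives.

A :class:`NutrientProfile` is the single currency of the package: it holds the
absolute daily amounts (or per-100 g amounts, for food compositions) of every
nutrient tracked by the Australian Health Survey nutrient panel, and supports
the element-wise arithmetic the scenario transforms are built from.

Energy is carried twice: as a stored field (``energy``, kJ) and as a quantity
recomputable from the macronutrients via fixed energy-conversion factors
(kJ/g, including dietary fibre and alcohol).  Survey composition databases
round their printed values, so the two typically disagree by <0.5%; the stored
field scales with gram transforms while compositional transforms update it by
the recomputed delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, Mapping, Tuple

__all__ = [
    "ENERGY_DENSITY_KJ_PER_G",
    "MICRONUTRIENT_UNITS",
    "MACRO_FIELDS",
    "NutrientProfile",
    "ProfileInvariantError",
]

#: Metabolisable-energy conversion factors, kJ per gram.
ENERGY_DENSITY_KJ_PER_G: Mapping[str, float] = {
    "protein": 16.736,
    "carbohydrate": 16.736,
    "total_fat": 37.656,
    "fiber": 8.368,
    "alcohol": 29.288,
}

#: Energy density used when expressing a nutrient as % of energy.  Fatty-acid
#: classes use the fat factor; sugar fractions use the carbohydrate factor.
PERCENT_ENERGY_DENSITY: Mapping[str, float] = {
    "protein": 16.736,
    "carbohydrate": 16.736,
    "total_fat": 37.656,
    "sfa": 37.656,
    "mufa": 37.656,
    "pufa": 37.656,
    "total_sugars": 16.736,
    "added_sugars": 16.736,
    "free_sugars": 16.736,
    "fiber": 8.368,
    "alcohol": 29.288,
}

#: Micronutrient panel: canonical name -> reporting unit.
MICRONUTRIENT_UNITS: Mapping[str, str] = {
    "vitamin_a_re": "ug",
    "thiamine": "mg",
    "riboflavin": "mg",
    "niacin_equivalents": "mg",
    "dietary_folate_equivalents": "ug",
    "vitamin_b6": "mg",
    "vitamin_b12": "ug",
    "vitamin_c": "mg",
    "vitamin_e": "mg",
    "calcium": "mg",
    "iodine": "ug",
    "iron": "mg",
    "magnesium": "mg",
    "phosphorus": "mg",
    "potassium": "mg",
    "selenium": "ug",
    "zinc": "mg",
}

#: Scalar (non-micronutrient) fields, in canonical order, with units.
MACRO_FIELDS: Mapping[str, str] = {
    "grams_food_weight": "g",
    "energy": "kj",
    "protein": "g",
    "total_fat": "g",
    "sfa": "g",
    "mufa": "g",
    "pufa": "g",
    "carbohydrate": "g",
    "total_sugars": "g",
    "added_sugars": "g",
    "free_sugars": "g",
    "sodium": "mg",
    "alcohol": "g",
    "fiber": "g",
}


class ProfileInvariantError(ValueError):
    """A nutrient profile violates a physical consistency constraint."""


@dataclass(frozen=True)
class NutrientProfile:
    """Absolute nutrient amounts (daily intake, or per 100 g of a food).

    All masses in grams except sodium and the micronutrients, which use the
    units of :data:`MACRO_FIELDS` / :data:`MICRONUTRIENT_UNITS`; energy in kJ.
    """

    grams_food_weight: float = 0.0
    energy: float = 0.0
    protein: float = 0.0
    total_fat: float = 0.0
    sfa: float = 0.0
    mufa: float = 0.0
    pufa: float = 0.0
    carbohydrate: float = 0.0
    total_sugars: float = 0.0
    added_sugars: float = 0.0
    free_sugars: float = 0.0
    sodium: float = 0.0
    alcohol: float = 0.0
    fiber: float = 0.0
    micronutrients: Dict[str, float] = field(default_factory=dict)

    # -- arithmetic ---------------------------------------------------------

    def scaled(self, factor: float) -> "NutrientProfile":
        """Every amount multiplied by *factor* (linear gram scaling)."""
        return NutrientProfile(
            **{name: getattr(self, name) * factor for name in MACRO_FIELDS},
            micronutrients={k: v * factor for k, v in self.micronutrients.items()},
        )

    def __add__(self, other: "NutrientProfile") -> "NutrientProfile":
        micros = dict(self.micronutrients)
        for k, v in other.micronutrients.items():
            micros[k] = micros.get(k, 0.0) + v
        return NutrientProfile(
            **{name: getattr(self, name) + getattr(other, name) for name in MACRO_FIELDS},
            micronutrients=micros,
        )

    def __sub__(self, other: "NutrientProfile") -> "NutrientProfile":
        return self + other.scaled(-1.0)

    def __mul__(self, factor: float) -> "NutrientProfile":
        return self.scaled(factor)

    __rmul__ = __mul__

    def replace(self, **changes: float) -> "NutrientProfile":
        return replace(self, **changes)

    # -- access -------------------------------------------------------------

    def get(self, nutrient: str) -> float:
        """Amount of *nutrient*, searching scalar fields then micronutrients."""
        if nutrient in MACRO_FIELDS:
            return getattr(self, nutrient)
        if nutrient in MICRONUTRIENT_UNITS or nutrient in self.micronutrients:
            return self.micronutrients.get(nutrient, 0.0)
        raise KeyError(f"unknown nutrient {nutrient!r}")

    def items(self) -> Iterator[Tuple[str, float]]:
        for name in MACRO_FIELDS:
            yield name, getattr(self, name)
        for name in sorted(self.micronutrients):
            yield name, self.micronutrients[name]

    # -- validation ---------------------------------------------------------

    def validate(self, tolerance: float = 0.02, context: str = "") -> None:
        """Check physical consistency; raise :class:`ProfileInvariantError`.

        *tolerance* is the fractional slack allowed on the fatty-acid closure
        ``sfa + mufa + pufa <= total_fat`` (trans fats and database rounding
        mean the three classes need not sum exactly to total fat).
        """
        where = f" in {context}" if context else ""
        for name, value in self.items():
            if value < -1e-9:
                raise ProfileInvariantError(f"negative amount {name}={value}{where}")
        slack = 1e-9 + tolerance * self.total_fat
        if self.sfa > self.total_fat + 1e-9:
            raise ProfileInvariantError(
                f"sfa ({self.sfa}) exceeds total fat ({self.total_fat}){where}"
            )
        if self.sfa + self.mufa + self.pufa > self.total_fat + slack:
            raise ProfileInvariantError(
                f"sfa+mufa+pufa ({self.sfa + self.mufa + self.pufa}) exceeds "
                f"total fat ({self.total_fat}) beyond tolerance{where}"
            )
        eps = 1e-9
        if not (
            self.added_sugars <= self.free_sugars + eps
            and self.free_sugars <= self.total_sugars + eps
            and self.total_sugars <= self.carbohydrate + eps
        ):
            raise ProfileInvariantError(
                f"sugar ordering violated (added {self.added_sugars} <= free "
                f"{self.free_sugars} <= total {self.total_sugars} <= "
                f"carbohydrate {self.carbohydrate}){where}"
            )

    def is_zero(self) -> bool:
        return all(abs(v) < 1e-12 for _, v in self.items())
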