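"""Population-weighted aggregation and derived base-case metrics.

The base case is the observed single-day intake of the population.  Every
reported quantity is a population-weighted per-capita mean: for nutrient x,

    mean(x) = sum_p w_p * x_p / sum_p w_p

where x_p is person p's daily total and w_p their expansion weight.  Persons
with no intake in the selected classes contribute zero to the numerator but
stay in the denominator (per-capita, not per-consumer).

Derived metrics:

* percent energy (%E): nutrient grams x its kJ/g factor over total energy;
* nutrient density: amount per 1000 kJ, as a ratio of population means;
* percent change: (modelled - base) / base x 100, the primary outcome metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Iterable, Optional

import pandas as pd

from .data_model import CLASS_LABELS, PopulationDataset
from .nutrients import (
    ENERGY_DENSITY_KJ_PER_G,
    MACRO_FIELDS,
    MICRONUTRIENT_UNITS,
    PERCENT_ENERGY_DENSITY,
    NutrientProfile,
)

__all__ = [
    "AggregateProfile",
    "compute_energy",
    "population_mean_intake",
    "percent_energy",
    "nutrient_density",
    "percent_change",
]


class AggregationError(ValueError):
    pass


@dataclass(frozen=True)
class AggregateProfile:
    """Population mean daily intake over a set of class labels."""

    profile: NutrientProfile
    class_filter: FrozenSet[str]
    n_effective: float  # sum of population weights

    def get(self, nutrient: str) -> float:
        return self.profile.get(nutrient)


def compute_energy(profile: NutrientProfile) -> float:
    """Metabolisable energy (kJ) recomputed from the macronutrients."""
    return sum(
        factor * getattr(profile, name)
        for name, factor in ENERGY_DENSITY_KJ_PER_G.items()
    )


def population_mean_intake(
    dataset: PopulationDataset,
    classes: Iterable[str] = CLASS_LABELS,
    exclude_sports_products: bool = False,
    milk_as_food: bool = True,
) -> AggregateProfile:
    """Population-weighted per-capita mean intake over the given classes.

    ``exclude_sports_products`` drops sports products and meal replacements
    from the selection (survey convention: the "discretionary beverages"
    reporting column excludes them while "discretionary choices" includes
    them).
    """
    classes = frozenset(classes)
    unknown = classes - set(CLASS_LABELS)
    if unknown:
        raise AggregationError(f"unknown class label(s) {sorted(unknown)}")
    if not classes:
        raise AggregationError("empty class set")
    total_weight = sum(p.weight for p in dataset.persons.values())
    if not total_weight > 0:
        raise AggregationError("total population weight is zero")

    labels = dataset.labels(milk_as_food=milk_as_food)
    selected = {
        code
        for code, label in labels.items()
        if label in classes
        and not (
            exclude_sports_products
            and dataset.foods[code].is_sports_or_meal_replacement
        )
    }

    total = NutrientProfile()
    if dataset.intakes:
        lines = pd.DataFrame(
            [
                (l.person_id, l.food_code, l.grams)
                for l in dataset.intakes
                if l.food_code in selected
            ],
            columns=["person_id", "food_code", "grams"],
        )
        if len(lines):
            weights = {pid: p.weight for pid, p in dataset.persons.items()}
            lines["w"] = lines["person_id"].map(weights)
            # composition basis grams_food_weight=100 scales to consumed mass
            for code, grp in lines.groupby("food_code"):
                wgrams = float((grp["grams"] * grp["w"]).sum())
                total = total + dataset.foods[code].composition.scaled(wgrams / 100.0)
    mean = total.scaled(1.0 / total_weight)
    return AggregateProfile(
        profile=mean, class_filter=classes, n_effective=total_weight
    )


def percent_energy(profile: NutrientProfile, nutrient: str) -> float:
    """Nutrient's share of total energy (%), via its kJ/g conversion factor."""
    energy = compute_energy(profile)
    if not energy > 0:
        raise AggregationError("percent energy undefined at zero energy")
    try:
        density = PERCENT_ENERGY_DENSITY[nutrient]
    except KeyError:
        raise AggregationError(
            f"{nutrient!r} has no energy conversion factor"
        ) from None
    return profile.get(nutrient) * density / energy * 100.0


def nutrient_density(agg: AggregateProfile, nutrient: str) -> float:
    """Amount per 1000 kJ, computed on aggregate means (ratio of means).

    Uses the tracked energy field (the survey-reported energy), not the
    recomputed value, so densities match published per-capita tables.
    """
    energy = agg.profile.energy
    if not energy > 0:
        raise AggregationError("nutrient density undefined at zero energy")
    return agg.get(nutrient) / energy * 1000.0


def percent_change(
    base: AggregateProfile, modelled: AggregateProfile, nutrient: str
) -> Optional[float]:
    """(modelled - base) / base x 100; ``None`` when the base amount is 0."""
    b = base.get(nutrient)
    if b == 0:
        return None
    return (modelled.get(nutrient) - b) / b * 100.0
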