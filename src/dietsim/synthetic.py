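"""Synthetic single-day dietary survey generator.

Real 24-h recall microdata from national nutrition surveys is
access-restricted, so this module fabricates survey-like
:class:`~dietsim.data_model.PopulationDataset` objects: a small food
archetype table (per-100 g compositions loosely shaped on the contrast
between nutrient-dense core foods and energy-dense, SFA/sodium-rich
discretionary foods and sugar/alcohol-rich discretionary beverages), one
recall day of lognormal portion draws per person, and gamma-distributed
population weights normalised to mean 1.

A deterministic calibration step then rescales grams and compositions so the
population-weighted class means hit the configured per-capita targets (by
default the bundled Australian Health Survey adult table) exactly for grams
and for the headline nutrients, making every pipeline stage testable against
published aggregate arithmetic.

What the generator does **not** emulate: demographic intake gradients,
day-of-week structure, usual-intake (multi-day) variance, or misreporting.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Tuple

import numpy as np

from . import subgroups
from .aggregate import load_reference
from .basecase import compute_energy, population_mean_intake
from .data_model import (
    FoodItem,
    IntakeLine,
    Person,
    PopulationDataset,
    write_composition_table,
    write_intakes,
    write_persons,
)
from .nutrients import MACRO_FIELDS, MICRONUTRIENT_UNITS, NutrientProfile

__all__ = [
    "Archetype",
    "GeneratorConfig",
    "CalibrationError",
    "default_archetypes",
    "default_targets",
    "default_config",
    "generate",
    "calibrate",
    "write_dataset",
]


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class Archetype:
    """One synthetic food: flags, per-100 g composition, intake distribution."""

    food_code: str
    name: str
    subgroup_code: str
    is_discretionary: bool
    is_beverage: bool
    composition: NutrientProfile
    consumer_fraction: float
    portion_median_g: float
    portion_sigma: float
    is_water_based: bool = False
    is_alcoholic: bool = False
    is_milk: bool = False
    is_sports_or_meal_replacement: bool = False

    def as_food(self) -> FoodItem:
        comp = self.composition.replace(
            grams_food_weight=100.0, energy=compute_energy(self.composition)
        )
        return FoodItem(
            food_code=self.food_code,
            name=self.name,
            subgroup_code=self.subgroup_code,
            is_discretionary=self.is_discretionary,
            is_beverage=self.is_beverage,
            is_water_based=self.is_water_based,
            is_alcoholic=self.is_alcoholic,
            is_milk=self.is_milk,
            is_sports_or_meal_replacement=self.is_sports_or_meal_replacement,
            composition=comp,
        )


def _p(**kw) -> NutrientProfile:
    micros = {k: kw.pop(k) for k in list(kw) if k in MICRONUTRIENT_UNITS}
    return NutrientProfile(**kw, micronutrients=micros)


def default_archetypes() -> List[Archetype]:
    """Built-in archetype table covering all four classes, alcohol, water,
    milk-as-food and sports products."""
    A = Archetype
    return [
        # --- core foods ----------------------------------------------------
        A("11100001", "bread, wholemeal", subgroups.BREAD, False, False,
          _p(protein=9.0, total_fat=2.7, sfa=0.45, mufa=1.1, pufa=0.9,
             carbohydrate=45.0, total_sugars=3.5, added_sugars=1.8,
             free_sugars=1.8, sodium=430.0, fiber=4.5,
             thiamine=0.25, riboflavin=0.10, niacin_equivalents=3.0,
             dietary_folate_equivalents=120.0, vitamin_b6=0.05, vitamin_e=0.3,
             calcium=30.0, iodine=45.0, iron=1.2, magnesium=25.0,
             phosphorus=100.0, potassium=110.0, selenium=6.0, zinc=0.7),
          consumer_fraction=0.85, portion_median_g=110.0, portion_sigma=0.35),
        A("12100001", "pasta & rice, cooked", subgroups.COOKED_GRAINS, False, False,
          _p(protein=4.5, total_fat=1.2, sfa=0.25, mufa=0.4, pufa=0.4,
             carbohydrate=26.0, total_sugars=0.8, sodium=3.0, fiber=2.2,
             thiamine=0.05, niacin_equivalents=1.5,
             dietary_folate_equivalents=12.0, iron=0.5, magnesium=20.0,
             phosphorus=60.0, potassium=50.0, selenium=4.0, zinc=0.6),
          consumer_fraction=0.70, portion_median_g=165.0, portion_sigma=0.40),
        A("19100001", "milk, regular fat", subgroups.MILK, False, True,
          _p(protein=3.3, total_fat=3.4, sfa=2.2, mufa=0.9, pufa=0.12,
             carbohydrate=4.9, total_sugars=4.9, sodium=42.0,
             vitamin_a_re=40.0, riboflavin=0.20, vitamin_b12=0.4,
             calcium=117.0, iodine=22.0, magnesium=10.0, phosphorus=93.0,
             potassium=155.0, selenium=2.0, zinc=0.4),
          consumer_fraction=0.80, portion_median_g=180.0, portion_sigma=0.45,
          is_milk=True),
        A("19300001", "cheddar cheese", "193", False, False,
          _p(protein=25.0, total_fat=33.0, sfa=21.0, mufa=9.0, pufa=1.0,
             carbohydrate=0.5, total_sugars=0.5, sodium=650.0,
             vitamin_a_re=280.0, riboflavin=0.4, vitamin_b12=1.1,
             calcium=740.0, iodine=40.0, phosphorus=490.0, potassium=80.0,
             magnesium=28.0, selenium=14.0, zinc=3.6),
          consumer_fraction=0.45, portion_median_g=30.0, portion_sigma=0.50),
        A("24100001", "apple, fresh", subgroups.FRUIT_FRESH, False, False,
          _p(protein=0.3, carbohydrate=12.5, total_sugars=10.8, fiber=2.3,
             sodium=1.0, vitamin_c=5.0, vitamin_e=0.2,
             dietary_folate_equivalents=3.0, calcium=5.0, magnesium=5.0,
             potassium=110.0),
          consumer_fraction=0.60, portion_median_g=145.0, portion_sigma=0.35),
        A("25100001", "mixed vegetables, cooked", subgroups.VEGETABLES_FRESH,
          False, False,
          _p(protein=2.2, total_fat=0.3, carbohydrate=6.0, total_sugars=2.8,
             sodium=25.0, fiber=3.0,
             vitamin_a_re=180.0, thiamine=0.07, riboflavin=0.06,
             niacin_equivalents=1.0, dietary_folate_equivalents=65.0,
             vitamin_b6=0.12, vitamin_c=22.0, vitamin_e=0.5, calcium=30.0,
             iron=0.8, magnesium=16.0, phosphorus=45.0, potassium=260.0,
             selenium=1.0, zinc=0.4),
          consumer_fraction=0.90, portion_median_g=260.0, portion_sigma=0.35),
        A("28100001", "beef, lean, cooked", subgroups.MEAT, False, False,
          _p(protein=28.0, total_fat=9.0, sfa=3.6, mufa=3.9, pufa=0.7,
             sodium=65.0,
             thiamine=0.06, riboflavin=0.20, niacin_equivalents=11.0,
             vitamin_b6=0.40, vitamin_b12=2.2, iron=2.8, magnesium=24.0,
             phosphorus=200.0, potassium=320.0, selenium=17.0, zinc=4.8),
          consumer_fraction=0.80, portion_median_g=150.0, portion_sigma=0.35),
        # --- core beverages ------------------------------------------------
        A("31100001", "tap water", subgroups.WATER, False, True,
          _p(), consumer_fraction=0.90, portion_median_g=700.0,
          portion_sigma=0.50, is_water_based=True),
        A("30100001", "orange juice", subgroups.FRUIT_VEG_JUICE, False, True,
          _p(protein=0.6, carbohydrate=8.8, total_sugars=8.2, free_sugars=8.2,
             vitamin_c=35.0, dietary_folate_equivalents=30.0,
             magnesium=10.0, potassium=130.0),
          consumer_fraction=0.35, portion_median_g=240.0, portion_sigma=0.45,
          is_water_based=True),
        A("31200001", "tea & coffee, with milk", subgroups.TEA_COFFEE, False, True,
          _p(protein=0.5, total_fat=0.4, sfa=0.25, mufa=0.1, pufa=0.02,
             carbohydrate=1.2, total_sugars=1.0, added_sugars=0.5,
             free_sugars=0.5, sodium=5.0, calcium=15.0, potassium=25.0,
             riboflavin=0.02, magnesium=3.0),
          consumer_fraction=0.85, portion_median_g=480.0, portion_sigma=0.45,
          is_water_based=True),
        # --- discretionary foods -------------------------------------------
        A("41100001", "chocolate cake, iced", subgroups.CAKES_BISCUITS, True, False,
          _p(protein=5.0, total_fat=15.0, sfa=6.5, mufa=5.5, pufa=2.2,
             carbohydrate=55.0, total_sugars=35.0, added_sugars=33.0,
             free_sugars=33.0, sodium=350.0, fiber=1.8,
             thiamine=0.06, riboflavin=0.08, dietary_folate_equivalents=20.0,
             vitamin_e=1.0, calcium=40.0, iron=0.9, magnesium=18.0,
             phosphorus=110.0, potassium=120.0, selenium=3.0, zinc=0.5),
          consumer_fraction=0.40, portion_median_g=100.0, portion_sigma=0.45),
        A("42100001", "meat pie", subgroups.PASTRIES_PIES, True, False,
          _p(protein=9.5, total_fat=13.0, sfa=5.8, mufa=5.2, pufa=1.3,
             carbohydrate=25.0, total_sugars=2.5, added_sugars=1.0,
             free_sugars=1.0, sodium=640.0, fiber=1.5,
             vitamin_a_re=10.0, thiamine=0.12, riboflavin=0.10,
             niacin_equivalents=3.0, vitamin_b12=0.4,
             dietary_folate_equivalents=15.0, iron=1.3, magnesium=18.0,
             phosphorus=120.0, potassium=160.0, selenium=8.0, zinc=1.3),
          consumer_fraction=0.30, portion_median_g=205.0, portion_sigma=0.35),
        A("43100001", "milk chocolate bar", subgroups.CONFECTIONERY, True, False,
          _p(protein=6.0, total_fat=28.0, sfa=17.0, mufa=8.5, pufa=1.0,
             carbohydrate=58.0, total_sugars=55.0, added_sugars=52.0,
             free_sugars=52.0, sodium=90.0, fiber=1.5,
             vitamin_a_re=60.0, riboflavin=0.25, vitamin_b12=0.2,
             vitamin_e=0.8, calcium=180.0, iodine=20.0, iron=1.2,
             magnesium=45.0, phosphorus=180.0, potassium=300.0, zinc=1.1),
          consumer_fraction=0.45, portion_median_g=55.0, portion_sigma=0.50),
        A("44100001", "potato crisps", subgroups.SAVOURY_SNACKS, True, False,
          _p(protein=6.0, total_fat=32.0, sfa=14.0, mufa=12.0, pufa=5.0,
             carbohydrate=50.0, total_sugars=0.5, sodium=750.0, fiber=4.0,
             thiamine=0.10, niacin_equivalents=2.0, vitamin_b6=0.50,
             vitamin_c=15.0, vitamin_e=3.0, iron=1.0, magnesium=50.0,
             phosphorus=140.0, potassium=900.0, selenium=2.0, zinc=0.8),
          consumer_fraction=0.35, portion_median_g=60.0, portion_sigma=0.50),
        # --- discretionary beverages ---------------------------------------
        A("51100001", "cola soft drink", subgroups.SOFT_DRINKS, True, True,
          _p(carbohydrate=10.6, total_sugars=10.6, added_sugars=10.6,
             free_sugars=10.6, sodium=8.0, potassium=2.0, phosphorus=15.0),
          consumer_fraction=0.45, portion_median_g=380.0, portion_sigma=0.50,
          is_water_based=True),
        A("51200001", "fruit drink", subgroups.SOFT_DRINKS, True, True,
          _p(carbohydrate=11.0, total_sugars=10.5, added_sugars=9.0,
             free_sugars=10.5, sodium=6.0, fiber=0.2,
             vitamin_a_re=8.0, vitamin_c=18.0, riboflavin=0.01,
             dietary_folate_equivalents=3.0, calcium=4.0, iron=0.1,
             magnesium=3.0, potassium=30.0, vitamin_e=0.05, zinc=0.02),
          consumer_fraction=0.25, portion_median_g=300.0, portion_sigma=0.50,
          is_water_based=True),
        A("51300001", "thickshake, takeaway", "513", True, True,
          _p(protein=3.5, total_fat=3.2, sfa=2.1, mufa=0.9, pufa=0.1,
             carbohydrate=16.0, total_sugars=15.0, added_sugars=10.0,
             free_sugars=10.0, sodium=60.0,
             vitamin_a_re=35.0, riboflavin=0.15, vitamin_b12=0.3,
             calcium=110.0, iodine=15.0, magnesium=10.0, phosphorus=90.0,
             potassium=150.0, zinc=0.4, selenium=1.0),
          consumer_fraction=0.08, portion_median_g=300.0, portion_sigma=0.45),
        A("52100001", "beer, full strength", subgroups.BEER, True, True,
          _p(protein=0.5, carbohydrate=2.6, total_sugars=0.2, alcohol=3.9,
             sodium=4.0,
             riboflavin=0.03, niacin_equivalents=0.6, vitamin_b6=0.05,
             vitamin_b12=0.02, dietary_folate_equivalents=6.0, calcium=4.0,
             iodine=1.0, iron=0.02, magnesium=8.0, phosphorus=25.0,
             potassium=35.0, selenium=0.5, zinc=0.03),
          consumer_fraction=0.35, portion_median_g=450.0, portion_sigma=0.50,
          is_alcoholic=True),
        A("52200001", "red wine", subgroups.WINE, True, True,
          _p(carbohydrate=2.5, total_sugars=0.6, alcohol=10.5, sodium=4.0,
             iodine=0.5, iron=0.4, magnesium=11.0, phosphorus=14.0,
             potassium=110.0, calcium=6.0, riboflavin=0.02, zinc=0.1,
             selenium=0.2),
          consumer_fraction=0.22, portion_median_g=215.0, portion_sigma=0.50,
          is_alcoholic=True),
        A("53100001", "sports drink", subgroups.SPORTS_DRINKS, True, True,
          _p(carbohydrate=6.0, total_sugars=5.8, added_sugars=5.8,
             free_sugars=5.8, sodium=28.0, potassium=12.0),
          consumer_fraction=0.06, portion_median_g=350.0, portion_sigma=0.40,
          is_water_based=True, is_sports_or_meal_replacement=True),
    ]


#: Calibration classes -> class labels they cover.  Core food and beverage
#: columns are not published separately, so core calibrates as one class.
CALIBRATION_CLASSES: Mapping[str, FrozenSet[str]] = {
    "core": frozenset({"core_food", "core_beverage"}),
    "discretionary_foods": frozenset({"discretionary_food"}),
    "discretionary_beverages": frozenset({"discretionary_beverage"}),
}

#: Nutrients given their own calibration factor.  Total/free sugars follow
#: the carbohydrate factor (keeping the sugar-chain invariants food-wise);
#: MUFA/PUFA follow total fat (their split is not published).
_DIRECT_FIELDS = ("protein", "fiber", "sodium", "alcohol")

#: Everything calibration pins exactly to the class targets (energy follows
#: the macronutrients; total/free sugars follow carbohydrate).
CALIBRATED_NUTRIENTS = (
    "grams_food_weight", "protein", "total_fat", "sfa", "carbohydrate",
    "added_sugars", "sodium", "alcohol", "fiber", *MICRONUTRIENT_UNITS,
)


def default_targets() -> Dict[str, NutrientProfile]:
    """Class targets from the bundled AHS adult per-capita table."""
    ref = load_reference()
    return {name: ref[name] for name in CALIBRATION_CLASSES}


@dataclass(frozen=True)
class GeneratorConfig:
    n_persons: int = 500
    seed: int = 0
    target_profile: Dict[str, NutrientProfile] = field(default_factory=default_targets)
    food_archetypes: List[Archetype] = field(default_factory=default_archetypes)
    weight_gamma_shape: float = 8.0
    calibrate: bool = True
    #: generator contract: the discretionary:core consumption-line median
    #: gram ratio should fluctuate around this replacement-ratio target
    median_ratio_target: float = 1.29
    median_ratio_band: Tuple[float, float] = (1.04, 1.54)

    def validate(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        for arch in self.food_archetypes:
            if not 0.0 <= arch.consumer_fraction <= 1.0:
                raise ValueError(f"{arch.food_code}: bad consumer fraction")
            if not (arch.portion_median_g > 0 and arch.portion_sigma > 0):
                raise ValueError(f"{arch.food_code}: bad portion distribution")
            arch.as_food().validate()
        for name, target in self.target_profile.items():
            if name not in CALIBRATION_CLASSES:
                raise ValueError(f"unknown calibration class {name!r}")
            if not (target.grams_food_weight > 0 and target.energy > 0):
                raise CalibrationError(f"{name}: target grams/energy must be > 0")
            recomputed = compute_energy(target)
            if abs(recomputed - target.energy) > 0.1 * target.energy:
                raise CalibrationError(
                    f"{name}: infeasible target — stated energy "
                    f"{target.energy:.1f} kJ vs {recomputed:.1f} kJ from its "
                    "macronutrients"
                )


def generate(config: Optional[GeneratorConfig] = None
             ) -> Tuple[PopulationDataset, Dict]:
    """Draw a survey-like dataset; returns ``(dataset, manifest)``.

    Deterministic for a fixed config: same seed, same bytes.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    foods = {a.food_code: a.as_food() for a in config.food_archetypes}
    persons: Dict[str, Person] = {}
    weights = rng.gamma(config.weight_gamma_shape,
                        1.0 / config.weight_gamma_shape,
                        size=config.n_persons)
    for i in range(config.n_persons):
        pid = f"P{i + 1:05d}"
        persons[pid] = Person(person_id=pid, weight=float(weights[i]))

    intakes: List[IntakeLine] = []
    for i in range(config.n_persons):
        pid = f"P{i + 1:05d}"
        for arch in config.food_archetypes:
            if rng.random() < arch.consumer_fraction:
                grams = float(
                    arch.portion_median_g
                    * np.exp(rng.normal(0.0, arch.portion_sigma))
                )
                intakes.append(IntakeLine(pid, arch.food_code, grams))

    dataset = PopulationDataset(foods=foods, persons=persons, intakes=intakes)
    dataset.validate()
    residuals: Dict = {}
    if config.calibrate:
        dataset, residuals = calibrate(dataset, config.target_profile)
    manifest = {
        "seed": config.seed,
        "n_persons": config.n_persons,
        "n_foods": len(foods),
        "n_intake_lines": len(intakes),
        "calibrated": bool(config.calibrate),
        "calibration": residuals,
    }
    return dataset, manifest


def _class_of_food(dataset: PopulationDataset) -> Dict[str, str]:
    labels = dataset.labels()
    out = {}
    for code, label in labels.items():
        for cls, members in CALIBRATION_CLASSES.items():
            if label in members:
                out[code] = cls
    return out


def calibrate(
    dataset: PopulationDataset,
    targets: Mapping[str, NutrientProfile],
) -> Tuple[PopulationDataset, Dict]:
    """Rescale grams and compositions so class means hit the targets.

    Per class: one gram factor makes the weighted mean intake weight exact;
    per-nutrient composition factors then make protein, fat, carbohydrate,
    fiber, alcohol, SFA, added sugars, sodium and every micronutrient exact,
    with per-food invariant repair (clipped foods are counted in the returned
    residual report).  Stored food energy is recomputed from macronutrients,
    so the class energy means land wherever the published macronutrients put
    them (within the usual <0.5% closure gap of printed tables).
    """
    food_class = _class_of_food(dataset)
    achieved = {
        cls: population_mean_intake(dataset, labels).profile
        for cls, labels in CALIBRATION_CLASSES.items()
        if cls in targets
    }

    # 1) gram factors
    gram_factor: Dict[str, float] = {}
    for cls, target in targets.items():
        current = achieved[cls].grams_food_weight
        if not current > 0:
            raise CalibrationError(
                f"{cls}: zero class intake with nonzero gram target"
            )
        gram_factor[cls] = target.grams_food_weight / current
    new_lines = [
        dc_replace(line, grams=line.grams * gram_factor[food_class[line.food_code]])
        for line in dataset.intakes
    ]

    # 2) per-nutrient composition factors (class means scale linearly)
    def factor(cls: str, name: str) -> float:
        t = targets[cls].get(name)
        m = achieved[cls].get(name) * gram_factor[cls]
        if t == 0:
            return 0.0 if m > 0 else 1.0
        if not m > 0:
            raise CalibrationError(
                f"{cls}: no base intake of {name} but target {t}"
            )
        return t / m

    clipped = 0
    new_foods: Dict[str, FoodItem] = {}
    factors_used: Dict[str, Dict[str, float]] = {cls: {} for cls in targets}
    for code, item in dataset.foods.items():
        cls = food_class[code]
        comp = item.composition
        f_fat = factor(cls, "total_fat")
        f_carb = factor(cls, "carbohydrate")
        f_sfa = factor(cls, "sfa")
        f_added = factor(cls, "added_sugars")
        changes: Dict[str, float] = {
            "total_fat": comp.total_fat * f_fat,
            "mufa": comp.mufa * f_fat,
            "pufa": comp.pufa * f_fat,
            "sfa": comp.sfa * f_sfa,
            "carbohydrate": comp.carbohydrate * f_carb,
            "total_sugars": comp.total_sugars * f_carb,
            "free_sugars": comp.free_sugars * f_carb,
            "added_sugars": comp.added_sugars * f_added,
        }
        for name in _DIRECT_FIELDS:
            changes[name] = comp.get(name) * factor(cls, name)
        micros = {
            name: comp.micronutrients.get(name, 0.0) * factor(cls, name)
            for name in MICRONUTRIENT_UNITS
        }
        factors_used[cls].update(
            {"total_fat": f_fat, "carbohydrate": f_carb, "sfa": f_sfa,
             "added_sugars": f_added}
        )
        # invariant repair, food-wise
        if changes["sfa"] > changes["total_fat"]:
            changes["sfa"] = changes["total_fat"]
            clipped += 1
        unsat = changes["mufa"] + changes["pufa"]
        headroom = changes["total_fat"] - changes["sfa"]
        if unsat > headroom and unsat > 0:
            scale = max(headroom, 0.0) / unsat
            changes["mufa"] *= scale
            changes["pufa"] *= scale
            clipped += 1
        if changes["added_sugars"] > changes["free_sugars"]:
            changes["free_sugars"] = changes["added_sugars"]
            clipped += 1
        if changes["free_sugars"] > changes["total_sugars"]:
            changes["total_sugars"] = changes["free_sugars"]
            clipped += 1
        if changes["total_sugars"] > changes["carbohydrate"]:
            changes["carbohydrate"] = changes["total_sugars"]
            clipped += 1
        new_comp = comp.replace(**changes).replace(grams_food_weight=100.0)
        new_comp = new_comp.replace(energy=compute_energy(new_comp),
                                    micronutrients=micros)
        new_foods[code] = dc_replace(item, composition=new_comp)

    out = PopulationDataset(new_foods, dict(dataset.persons), new_lines)
    out.validate()

    final = {
        cls: population_mean_intake(out, labels).profile
        for cls, labels in CALIBRATION_CLASSES.items()
        if cls in targets
    }
    residuals = {
        "gram_factors": gram_factor,
        "composition_factors": factors_used,
        "clipped_foods": clipped,
        "achieved_vs_target": {
            cls: {
                name: {"achieved": final[cls].get(name), "target": t}
                for name, t in targets[cls].items()
            }
            for cls in targets
        },
    }
    return out, residuals


def _config_hash(config: GeneratorConfig) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:16]


def write_dataset(dataset: PopulationDataset, manifest: Dict, outdir,
                  config: Optional[GeneratorConfig] = None) -> Dict[str, Path]:
    """Write composition/persons/intakes TSVs plus a generator manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "composition": outdir / "composition.tsv",
        "persons": outdir / "persons.tsv",
        "intakes": outdir / "intakes.tsv",
        "manifest": outdir / "generator_manifest.json",
    }
    write_composition_table(dataset.foods, paths["composition"])
    write_persons(dataset.persons, paths["persons"])
    write_intakes(dataset.intakes, paths["intakes"])
    payload = dict(manifest)
    if config is not None:
        payload["config_hash"] = _config_hash(config)
    paths["manifest"].write_text(json.dumps(payload, indent=2, sort_keys=True))
    return paths


def default_config(seed: int = 0, n_persons: int = 500) -> GeneratorConfig:
    return GeneratorConfig(seed=seed, n_persons=n_persons)
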