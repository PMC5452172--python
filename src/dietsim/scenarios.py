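"""Deterministic dietary scenario transforms.

Three scenario families model population-level strategies against
discretionary food and beverage intake:

* **moderation** — consume less: grams of targeted discretionary items are
  scaled by ``1 - reduction_fraction``; optionally part of the *food*-derived
  energy deficit is compensated by eating more core and discretionary foods
  (beverage energy is never compensated: energy compensation after reducing
  liquids is not expected behaviourally);
* **substitution** — swap: removed discretionary grams are replaced by core
  items, scaled by a replacement ratio (grams added per gram removed) and
  distributed across the replacement pool pro-rata to base-case consumption;
* **reformulation** — change the products, not the behaviour: per-100 g
  composition of discretionary items is altered (SFA swapped into unsaturated
  fats at the item's own MUFA:PUFA ratio, added sugars / sodium / alcohol
  reduced), consumption quantities staying constant apart from the removed
  nutrient mass itself.

Every transform is deterministic and runs either on a person-level
:class:`~dietsim.data_model.PopulationDataset` or, in aggregate mode, on an
:class:`~dietsim.aggregate.AggregateTable` of published per-capita means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Union

import numpy as np

from .aggregate import AggregateTable
from .basecase import AggregateProfile, population_mean_intake
from .data_model import (
    CLASS_LABELS,
    FoodItem,
    IntakeLine,
    PopulationDataset,
)
from .nutrients import ENERGY_DENSITY_KJ_PER_G, NutrientProfile
from . import subgroups

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "ReformulationParams",
    "ScenarioError",
    "moderate",
    "compensate_energy",
    "substitute",
    "compute_replacement_ratio",
    "reformulate",
    "run_scenario",
    "run_sensitivity_suite",
    "SENSITIVITY_PRESETS",
]

KJ_PER_G_CARB = ENERGY_DENSITY_KJ_PER_G["carbohydrate"]
KJ_PER_G_ALCOHOL = ENERGY_DENSITY_KJ_PER_G["alcohol"]

PRIMARY_OUTCOMES = ("energy", "sfa", "added_sugars", "sodium", "alcohol")


class ScenarioError(ValueError):
    pass


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ScenarioError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class ReformulationParams:
    """Per-product composition changes applied by the reformulation family."""

    sfa_replace_fraction: float = 0.5
    added_sugar_reduction: float = 0.25
    sodium_reduction: float = 0.20
    alcohol_reduction: float = 0.25
    #: When set, removed added sugar is replaced by an energy-equivalent
    #: sweetener: neither mass nor energy change.  Off = non-nutritive
    #: sweetener or no replacement.
    sweetener_energy_replacement: bool = False

    def validate(self) -> None:
        for name in ("sfa_replace_fraction", "added_sugar_reduction",
                     "sodium_reduction", "alcohol_reduction"):
            _check_fraction(name, getattr(self, name))


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameter block for one scenario."""

    family: str  # moderation | substitution | reformulation
    target: str = "all"  # foods | beverages | all
    reduction_fraction: float = 0.5
    compensation_fraction: float = 0.0
    compensation_pool: FrozenSet[str] = frozenset(
        {"core_food", "discretionary_food"}
    )
    substitution_pool: str = "all_core"  # all_core | fruit_veg_only
    #: grams of replacement added per gram removed; scalar applies to every
    #: subgroup, a mapping must cover every discretionary subgroup present
    #: (a "default" key acts as fallback).
    replacement_ratios: Union[float, Mapping[str, float]] = 1.29
    food_pool_subgroups: FrozenSet[str] = subgroups.FRUIT_VEG_SUBGROUPS
    beverage_pool_subgroups: FrozenSet[str] = subgroups.BEVERAGE_POOL_SUBGROUPS
    reformulation: ReformulationParams = field(default_factory=ReformulationParams)
    name: str = ""

    def validate(self) -> None:
        if self.family not in {"moderation", "substitution", "reformulation"}:
            raise ScenarioError(f"unknown scenario family {self.family!r}")
        if self.target not in {"foods", "beverages", "all"}:
            raise ScenarioError(f"unknown target {self.target!r}")
        _check_fraction("reduction_fraction", self.reduction_fraction)
        _check_fraction("compensation_fraction", self.compensation_fraction)
        if not self.compensation_pool <= set(CLASS_LABELS):
            raise ScenarioError(
                f"unknown compensation pool labels {self.compensation_pool}"
            )
        if self.substitution_pool not in {"all_core", "fruit_veg_only"}:
            raise ScenarioError(
                f"unknown substitution pool {self.substitution_pool!r}"
            )
        ratios = self.replacement_ratios
        values = [ratios] if isinstance(ratios, (int, float)) else list(ratios.values())
        if any(not v > 0 for v in values):
            raise ScenarioError("replacement ratios must be > 0")
        self.reformulation.validate()


@dataclass(frozen=True)
class ScenarioResult:
    spec: ScenarioSpec
    base: AggregateProfile
    modelled: AggregateProfile
    pct_change: Dict[str, Optional[float]]
    modelled_data: Union[PopulationDataset, AggregateTable, None] = None


def _target_labels(target: str) -> FrozenSet[str]:
    return {
        "foods": frozenset({"discretionary_food"}),
        "beverages": frozenset({"discretionary_beverage"}),
        "all": frozenset({"discretionary_food", "discretionary_beverage"}),
    }[target]


def _ratio_for(spec: ScenarioSpec, subgroup: str) -> float:
    ratios = spec.replacement_ratios
    if isinstance(ratios, (int, float)):
        return float(ratios)
    if subgroup in ratios:
        return float(ratios[subgroup])
    if "default" in ratios:
        return float(ratios["default"])
    raise ScenarioError(f"no replacement ratio for subgroup {subgroup!r}")


# ---------------------------------------------------------------------------
# Moderation
# ---------------------------------------------------------------------------

def moderate(data, spec: ScenarioSpec):
    """Reduce targeted discretionary intake, optionally energy-compensating.

    Grams of every targeted line scale by ``1 - reduction_fraction`` (all
    nutrients of an item scale with its grams, so a 50% gram cut is a 50%
    energy cut item-wise).  Compensation then adds back
    ``compensation_fraction`` of the *food*-derived energy deficit across the
    compensation pool, pro-rata to base-case pool energy; the deficit from
    discretionary beverages is never compensated.
    """
    spec.validate()
    if spec.family != "moderation":
        raise ScenarioError("moderate() requires a moderation spec")
    if isinstance(data, AggregateTable):
        return _moderate_aggregate(data, spec)
    return _moderate_persons(data, spec)


def _moderate_persons(dataset: PopulationDataset, spec: ScenarioSpec) -> PopulationDataset:
    f = spec.reduction_fraction
    labels = dataset.labels()
    targeted = _target_labels(spec.target)
    new_lines: List[IntakeLine] = []
    deficit_by_person: Dict[str, float] = {}
    for line in dataset.intakes:
        label = labels[line.food_code]
        if label in targeted:
            new_lines.append(dc_replace(line, grams=line.grams * (1.0 - f)))
            if label == "discretionary_food":
                energy_per_g = dataset.foods[line.food_code].composition.energy / 100.0
                deficit_by_person[line.person_id] = (
                    deficit_by_person.get(line.person_id, 0.0)
                    + f * line.grams * energy_per_g
                )
        else:
            new_lines.append(line)
    out = PopulationDataset(dict(dataset.foods), dict(dataset.persons), new_lines)
    if spec.compensation_fraction > 0 and deficit_by_person:
        out = _compensate_persons(
            out,
            base=dataset,
            deficits=deficit_by_person,
            pool=spec.compensation_pool,
            fraction=spec.compensation_fraction,
        )
    return out


def _compensate_persons(
    dataset: PopulationDataset,
    base: PopulationDataset,
    deficits: Mapping[str, float],
    pool: FrozenSet[str],
    fraction: float,
) -> PopulationDataset:
    """Scale each person's pool lines up pro-rata to base-case pool energy."""
    labels = base.labels()
    # index base pool lines per person: line index -> base energy
    pool_energy: Dict[str, float] = {}
    line_base_energy: List[float] = []
    for line in base.intakes:
        e = 0.0
        if labels[line.food_code] in pool:
            e = line.grams * base.foods[line.food_code].composition.energy / 100.0
            pool_energy[line.person_id] = pool_energy.get(line.person_id, 0.0) + e
        line_base_energy.append(e)

    new_lines: List[IntakeLine] = []
    for idx, line in enumerate(dataset.intakes):
        base_e = line_base_energy[idx]
        deficit = deficits.get(line.person_id, 0.0)
        if base_e > 0 and deficit > 0:
            person_pool = pool_energy[line.person_id]
            add_energy = fraction * deficit * base_e / person_pool
            energy_per_g = (
                dataset.foods[line.food_code].composition.energy / 100.0
            )
            add_grams = add_energy / energy_per_g
            new_lines.append(dc_replace(line, grams=line.grams + add_grams))
        else:
            new_lines.append(line)
    uncovered = [
        pid for pid, d in deficits.items()
        if d > 0 and pool_energy.get(pid, 0.0) <= 0
    ]
    if uncovered:
        raise ScenarioError(
            f"{len(uncovered)} person(s) with an energy deficit have no "
            f"compensation-pool intake, first: {uncovered[:5]}"
        )
    return PopulationDataset(dict(dataset.foods), dict(dataset.persons), new_lines)


def compensate_energy(
    dataset: PopulationDataset,
    deficit_kj: float,
    pool: FrozenSet[str] = frozenset({"core_food", "discretionary_food"}),
    fraction: float = 1.0,
) -> PopulationDataset:
    """Distribute ``fraction * deficit_kj`` over pool items pro-rata to their
    population base-case energy share, scaling grams (population-level
    primitive; :func:`moderate` compensates per person instead)."""
    _check_fraction("fraction", fraction)
    if deficit_kj < 0:
        raise ScenarioError("deficit must be >= 0")
    if fraction == 0.0 or deficit_kj == 0.0:
        return dataset.copy()
    labels = dataset.labels()
    line_energy = [
        line.grams * dataset.foods[line.food_code].composition.energy / 100.0
        if labels[line.food_code] in pool
        else 0.0
        for line in dataset.intakes
    ]
    total = sum(line_energy)
    if not total > 0:
        raise ScenarioError("compensation pool has no energy to scale")
    add = fraction * deficit_kj
    new_lines = [
        dc_replace(line, grams=line.grams * (1.0 + add / total))
        if e > 0
        else line
        for line, e in zip(dataset.intakes, line_energy)
    ]
    return PopulationDataset(dict(dataset.foods), dict(dataset.persons), new_lines)


def _moderate_aggregate(table: AggregateTable, spec: ScenarioSpec) -> AggregateTable:
    f = spec.reduction_fraction
    deltas: Dict[str, NutrientProfile] = {}
    if spec.target in ("foods", "all"):
        d = table["discretionary_foods"].scaled(-f)
        deltas["discretionary_foods"] = d
    if spec.target in ("beverages", "all"):
        d = table["discretionary_beverages"].scaled(-f)
        deltas["discretionary_beverages"] = d
    if spec.target == "all":
        # the choices column includes sports products / meal replacements
        # absent from the food and beverage columns; its own delta carries
        # the full reduction and drives the total.
        full = table["discretionary"].scaled(-f)
    else:
        full = deltas["discretionary_foods" if spec.target == "foods"
                      else "discretionary_beverages"]
    deltas["discretionary"] = full
    deltas["total"] = full
    out = table.apply_deltas(deltas)

    c = spec.compensation_fraction
    if c > 0 and spec.target in ("foods", "all"):
        deficit = f * table["discretionary_foods"].energy
        add = c * deficit
        e_core = table["core"].energy
        e_df = table["discretionary_foods"].energy
        pool_total = e_core + e_df
        if not pool_total > 0:
            raise ScenarioError("compensation pool has no energy to scale")
        comp_deltas: Dict[str, NutrientProfile] = {}
        d_core = table["core"].scaled(add * (e_core / pool_total) / e_core)
        d_foods = table["discretionary_foods"].scaled(
            add * (e_df / pool_total) / e_df
        )
        comp_deltas["core"] = d_core
        comp_deltas["discretionary_foods"] = d_foods
        comp_deltas["discretionary"] = d_foods
        comp_deltas["total"] = d_core + d_foods
        out = out.apply_deltas(comp_deltas)
    return out


# ---------------------------------------------------------------------------
# Substitution
# ---------------------------------------------------------------------------

def substitute(data, spec: ScenarioSpec):
    """Swap part of discretionary intake for core replacements.

    Per discretionary line, ``reduction_fraction`` of its grams is removed
    and ``ratio(subgroup)`` grams of replacement added per gram removed,
    spread over the replacement pool pro-rata to the person's base-case pool
    gram shares (population shares when the person consumes no pool item).
    Discretionary foods draw from all core foods or from fresh fruit &
    vegetables only; discretionary beverages (alcoholic ones included) are
    replaced exclusively by water and fruit/vegetable juices.  No further
    energy compensation applies: replacement ratios already reflect observed
    eating patterns.
    """
    spec.validate()
    if spec.family != "substitution":
        raise ScenarioError("substitute() requires a substitution spec")
    if isinstance(data, AggregateTable):
        return _substitute_aggregate(data, spec)
    return _substitute_persons(data, spec)


def _pool_codes(dataset: PopulationDataset, spec: ScenarioSpec, kind: str) -> List[str]:
    labels = dataset.labels()
    if kind == "food":
        if spec.substitution_pool == "all_core":
            return [c for c, l in labels.items() if l == "core_food"]
        return [
            c for c, l in labels.items()
            if l == "core_food"
            and dataset.foods[c].subgroup_code in spec.food_pool_subgroups
        ]
    return [
        c for c, l in labels.items()
        if l == "core_beverage"
        and dataset.foods[c].subgroup_code in spec.beverage_pool_subgroups
    ]


def _substitute_persons(dataset: PopulationDataset, spec: ScenarioSpec) -> PopulationDataset:
    f = spec.reduction_fraction
    labels = dataset.labels()
    targeted = _target_labels(spec.target)

    pools = {
        "discretionary_food": _pool_codes(dataset, spec, "food"),
        "discretionary_beverage": _pool_codes(dataset, spec, "beverage"),
    }
    for label in targeted:
        if f > 0 and not pools[label]:
            raise ScenarioError(f"empty replacement pool for {label}")

    # base-case pool grams: per person and population-wide (fallback shares)
    person_pool: Dict[str, Dict[str, Dict[str, float]]] = {"discretionary_food": {},
                                                           "discretionary_beverage": {}}
    population_pool: Dict[str, Dict[str, float]] = {"discretionary_food": {},
                                                    "discretionary_beverage": {}}
    pool_membership = {
        label: set(codes) for label, codes in pools.items()
    }
    for line in dataset.intakes:
        for label, members in pool_membership.items():
            if line.food_code in members and line.grams > 0:
                per = person_pool[label].setdefault(line.person_id, {})
                per[line.food_code] = per.get(line.food_code, 0.0) + line.grams
                w = dataset.persons[line.person_id].weight
                population_pool[label][line.food_code] = (
                    population_pool[label].get(line.food_code, 0.0) + w * line.grams
                )

    additions: Dict[str, Dict[str, float]] = {}  # person -> code -> grams

    def _add(person_id: str, shares: Mapping[str, float], grams: float) -> None:
        total = sum(shares.values())
        if not total > 0:
            raise ScenarioError("replacement pool has zero base-case grams")
        dest = additions.setdefault(person_id, {})
        for code, g in shares.items():
            dest[code] = dest.get(code, 0.0) + grams * g / total

    new_lines: List[IntakeLine] = []
    for line in dataset.intakes:
        label = labels[line.food_code]
        if label in targeted and line.grams > 0:
            removed = f * line.grams
            new_lines.append(dc_replace(line, grams=line.grams - removed))
            ratio = _ratio_for(spec, dataset.foods[line.food_code].subgroup_code)
            shares = person_pool[label].get(line.person_id) or population_pool[label]
            _add(line.person_id, shares, removed * ratio)
        else:
            new_lines.append(line)

    # fold additions into existing lines where possible, else append new ones
    consumed: Dict[tuple, int] = {}
    for idx, line in enumerate(new_lines):
        consumed.setdefault((line.person_id, line.food_code), idx)
    for person_id, per in sorted(additions.items()):
        for code, grams in sorted(per.items()):
            key = (person_id, code)
            if key in consumed:
                idx = consumed[key]
                new_lines[idx] = dc_replace(
                    new_lines[idx], grams=new_lines[idx].grams + grams
                )
            else:
                new_lines.append(IntakeLine(person_id, code, grams))
    return PopulationDataset(dict(dataset.foods), dict(dataset.persons), new_lines)


def _substitute_aggregate(table: AggregateTable, spec: ScenarioSpec) -> AggregateTable:
    """Aggregate-mode substitution.

    The published table cannot separate core foods from core beverages, so the
    food-replacement profile is the whole core column per gram; beverage
    replacements are modelled as water (zero nutrients, grams only).
    """
    f = spec.reduction_fraction
    ratio = _ratio_for(spec, "default") if not isinstance(
        spec.replacement_ratios, (int, float)) else float(spec.replacement_ratios)
    deltas: Dict[str, NutrientProfile] = {}
    total_delta = NutrientProfile()
    if spec.target in ("foods", "all"):
        removed = table["discretionary_foods"].scaled(-f)
        grams_removed = f * table["discretionary_foods"].grams_food_weight
        core = table["core"]
        if not core.grams_food_weight > 0:
            raise ScenarioError("empty replacement pool in core column")
        added = core.scaled(ratio * grams_removed / core.grams_food_weight)
        deltas["discretionary_foods"] = removed
        deltas["core"] = added
        total_delta = total_delta + removed + added
    if spec.target in ("beverages", "all"):
        removed = table["discretionary_beverages"].scaled(-f)
        grams_removed = f * table["discretionary_beverages"].grams_food_weight
        added = NutrientProfile(grams_food_weight=ratio * grams_removed)
        deltas["discretionary_beverages"] = removed
        deltas["core"] = deltas.get("core", NutrientProfile()) + added
        total_delta = total_delta + removed + added
    disc_delta = NutrientProfile()
    for key in ("discretionary_foods", "discretionary_beverages"):
        if key in deltas:
            disc_delta = disc_delta + deltas[key]
    deltas["discretionary"] = disc_delta
    deltas["total"] = total_delta
    return table.apply_deltas(deltas)


def compute_replacement_ratio(
    dataset: PopulationDataset,
    source_labels: FrozenSet[str] = frozenset(
        {"discretionary_food", "discretionary_beverage"}
    ),
    target_labels: FrozenSet[str] = frozenset({"core_food", "core_beverage"}),
    source_subgroups: Optional[FrozenSet[str]] = None,
    target_subgroups: Optional[FrozenSet[str]] = None,
    orientation: str = "target_over_source",
) -> float:
    """Replacement ratio from population median consumption-line grams.

    The ratio is the weighted median grams of a target-pool consumption line
    over the weighted median grams of a source-group line: grams of
    replacement to add per gram removed so that typical portion sizes are
    respected.  Orientation ``source_over_target`` inverts the quotient.
    """
    if orientation not in {"target_over_source", "source_over_target"}:
        raise ScenarioError(f"unknown orientation {orientation!r}")
    labels = dataset.labels()

    def _median(group_labels: FrozenSet[str], group_subgroups) -> float:
        grams, weights = [], []
        for line in dataset.intakes:
            if line.grams <= 0:
                continue
            item = dataset.foods[line.food_code]
            if labels[line.food_code] not in group_labels:
                continue
            if group_subgroups is not None and item.subgroup_code not in group_subgroups:
                continue
            grams.append(line.grams)
            weights.append(dataset.persons[line.person_id].weight)
        if not grams:
            raise ScenarioError("empty group in replacement-ratio computation")
        order = np.argsort(grams)
        g = np.asarray(grams)[order]
        w = np.asarray(weights)[order]
        cum = np.cumsum(w)
        return float(g[np.searchsorted(cum, 0.5 * cum[-1])])

    med_source = _median(source_labels, source_subgroups)
    med_target = _median(target_labels, target_subgroups)
    ratio = med_target / med_source
    return ratio if orientation == "target_over_source" else 1.0 / ratio


# ---------------------------------------------------------------------------
# Reformulation
# ---------------------------------------------------------------------------

def _reformulate_profile(profile: NutrientProfile, params: ReformulationParams):
    """Apply reformulation to one composition/column profile.

    Returns ``(new_profile, removed_mass_g, removed_energy_kj)`` where the
    removed mass is sugar + alcohol + sodium (mg -> g) grams taken out of the
    product, and the removed energy follows from the carbohydrate and alcohol
    conversion factors (total fat is unchanged by the SFA swap).
    """
    d_sfa = params.sfa_replace_fraction * profile.sfa
    mufa, pufa = profile.mufa, profile.pufa
    unsat = mufa + pufa
    if unsat > 0:
        mufa += d_sfa * mufa / unsat
        pufa += d_sfa * pufa / unsat
    else:  # no observed unsaturated split: even swap
        mufa += 0.5 * d_sfa
        pufa += 0.5 * d_sfa

    d_sugar = params.added_sugar_reduction * profile.added_sugars
    d_na = params.sodium_reduction * profile.sodium
    d_alc = params.alcohol_reduction * profile.alcohol

    removed_mass = d_alc + d_na / 1000.0
    removed_energy = KJ_PER_G_ALCOHOL * d_alc
    carb_delta = d_sugar
    if params.sweetener_energy_replacement:
        # energy-equivalent sweetener: sugar leaves, its mass and energy stay
        carb_delta = 0.0
    else:
        removed_mass += d_sugar
        removed_energy += KJ_PER_G_CARB * d_sugar

    new = profile.replace(
        grams_food_weight=profile.grams_food_weight - removed_mass,
        energy=profile.energy - removed_energy,
        sfa=profile.sfa - d_sfa,
        mufa=mufa,
        pufa=pufa,
        carbohydrate=max(profile.carbohydrate - carb_delta, 0.0),
        total_sugars=max(profile.total_sugars - d_sugar, 0.0),
        free_sugars=max(profile.free_sugars - d_sugar, 0.0),
        added_sugars=profile.added_sugars - d_sugar,
        sodium=profile.sodium - d_na,
        alcohol=profile.alcohol - d_alc,
    )
    return new, removed_mass, removed_energy


def reformulate(data, spec: ScenarioSpec):
    """Reformulate targeted discretionary products.

    Person-level: each targeted food's per-100 g composition is transformed
    and re-expressed per 100 g of the reformulated product; intake grams
    scale by the mass-retention factor so nutrient deliveries follow the new
    recipe exactly.  Aggregate mode applies the same arithmetic per column.
    """
    spec.validate()
    if spec.family != "reformulation":
        raise ScenarioError("reformulate() requires a reformulation spec")
    if isinstance(data, AggregateTable):
        return _reformulate_aggregate(data, spec)
    return _reformulate_persons(data, spec)


def _reformulate_persons(dataset: PopulationDataset, spec: ScenarioSpec) -> PopulationDataset:
    labels = dataset.labels()
    targeted = _target_labels(spec.target)
    new_foods: Dict[str, FoodItem] = {}
    retention: Dict[str, float] = {}
    for code, item in dataset.foods.items():
        if labels[code] not in targeted:
            new_foods[code] = item
            continue
        new_comp, removed_mass, _ = _reformulate_profile(
            item.composition, spec.reformulation
        )
        rho = (100.0 - removed_mass) / 100.0
        if rho <= 0:  # degenerate: product was pure removed nutrient
            rho = 0.0
            renorm = NutrientProfile()
        else:
            renorm = new_comp.scaled(1.0 / rho).replace(grams_food_weight=100.0)
        new_foods[code] = dc_replace(item, composition=renorm)
        retention[code] = rho
    new_lines = [
        dc_replace(line, grams=line.grams * retention[line.food_code])
        if line.food_code in retention
        else line
        for line in dataset.intakes
    ]
    return PopulationDataset(new_foods, dict(dataset.persons), new_lines)


def _reformulate_aggregate(table: AggregateTable, spec: ScenarioSpec) -> AggregateTable:
    params = spec.reformulation
    columns = {
        "foods": ["discretionary_foods"],
        "beverages": ["discretionary_beverages"],
        "all": ["discretionary_foods", "discretionary_beverages", "discretionary"],
    }[spec.target]
    deltas: Dict[str, NutrientProfile] = {}
    for column in columns:
        new, _, _ = _reformulate_profile(table[column], params)
        deltas[column] = new - table[column]
    if spec.target != "all":
        deltas["discretionary"] = deltas[columns[0]]
        deltas["total"] = deltas[columns[0]]
    else:
        deltas["total"] = deltas["discretionary"]
    return table.apply_deltas(deltas)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

_FAMILY_TRANSFORM = {
    "moderation": moderate,
    "substitution": substitute,
    "reformulation": reformulate,
}


def _aggregate_of(data) -> AggregateProfile:
    if isinstance(data, AggregateTable):
        return AggregateProfile(
            profile=data["total"],
            class_filter=frozenset(CLASS_LABELS),
            n_effective=1.0,
        )
    return population_mean_intake(data)


def run_scenario(data, spec: ScenarioSpec) -> ScenarioResult:
    """Apply one scenario and report base vs modelled per-capita profiles."""
    spec.validate()
    modelled_data = _FAMILY_TRANSFORM[spec.family](data, spec)
    base = _aggregate_of(data)
    modelled = _aggregate_of(modelled_data)
    pct: Dict[str, Optional[float]] = {}
    for name, base_value in base.profile.items():
        pct[name] = (
            None
            if base_value == 0
            else (modelled.profile.get(name) - base_value) / base_value * 100.0
        )
    return ScenarioResult(
        spec=spec, base=base, modelled=modelled, pct_change=pct,
        modelled_data=modelled_data,
    )


SENSITIVITY_PRESETS: Dict[str, Dict[str, ScenarioSpec]] = {
    "moderation": {
        "primary": ScenarioSpec("moderation", "all", 0.5, 0.0, name="moderation/comp0"),
        "lower": ScenarioSpec("moderation", "all", 0.5, 0.25, name="moderation/comp25"),
        "upper": ScenarioSpec("moderation", "all", 0.5, 0.75, name="moderation/comp75"),
    },
    "substitution": {
        "all_core": ScenarioSpec(
            "substitution", "all", 0.5, substitution_pool="all_core",
            name="substitution/all_core",
        ),
        "fruit_veg_only": ScenarioSpec(
            "substitution", "all", 0.5, substitution_pool="fruit_veg_only",
            name="substitution/fruit_veg",
        ),
    },
    "reformulation": {
        "lower": ScenarioSpec(
            "reformulation", "all",
            reformulation=ReformulationParams(0.25, 0.10, 0.10, 0.25),
            name="reformulation/lower",
        ),
        "primary": ScenarioSpec(
            "reformulation", "all",
            reformulation=ReformulationParams(0.50, 0.25, 0.20, 0.25),
            name="reformulation/primary",
        ),
        "upper": ScenarioSpec(
            "reformulation", "all",
            reformulation=ReformulationParams(0.75, 0.40, 0.40, 0.50),
            name="reformulation/upper",
        ),
    },
}


def run_sensitivity_suite(data, family: str) -> Dict[str, ScenarioResult]:
    """Primary + lower/upper parameter sets for one scenario family."""
    try:
        presets = SENSITIVITY_PRESETS[family]
    except KeyError:
        raise ScenarioError(f"unknown scenario family {family!r}") from None
    return {key: run_scenario(data, spec) for key, spec in presets.items()}
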