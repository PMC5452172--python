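import pytest

from dietsim import (
    FoodItem,
    IntakeLine,
    NutrientProfile,
    Person,
    PopulationDataset,
    load_reference,
)
from dietsim.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def table1():
    """Bundled AHS adult per-capita base-case table (aggregate mode)."""
    return load_reference()


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Calibrated synthetic survey, 300 persons, fixed seed."""
    dataset, manifest = generate(GeneratorConfig(seed=42, n_persons=300))
    return dataset, manifest


def _food(code, subgroup="411", disc=True, bev=False, energy=None, **comp):
    profile = NutrientProfile(grams_food_weight=100.0, **comp)
    if energy is not None:
        profile = profile.replace(energy=energy)
    return FoodItem(
        food_code=code,
        name=code,
        subgroup_code=subgroup,
        is_discretionary=disc,
        is_beverage=bev,
        composition=profile,
    )


@pytest.fixture()
def tiny_dataset():
    """Two persons, one core food + one discretionary food, hand-checkable.

    Base-case weighted means: sodium (1*50 + 3*100)/4 = 87.5 mg etc.
    """
    foods = {
        "C1": _food("C1", subgroup="111", disc=False, energy=600.0,
                    carbohydrate=30.0, sodium=400.0, protein=5.0),
        "D1": _food("D1", subgroup="411", disc=True, energy=1500.0,
                    carbohydrate=50.0, total_sugars=30.0, added_sugars=25.0,
                    free_sugars=25.0, sodium=300.0, total_fat=15.0, sfa=7.0,
                    mufa=4.0, pufa=2.0),
    }
    persons = {
        "P1": Person("P1", weight=1.0),
        "P2": Person("P2", weight=3.0),
    }
    intakes = [
        IntakeLine("P1", "C1", 100.0),
        IntakeLine("P1", "D1", 50.0),
        IntakeLine("P2", "C1", 200.0),
        IntakeLine("P2", "D1", 100.0),
    ]
    ds = PopulationDataset(foods=foods, persons=persons, intakes=intakes)
    ds.validate()
    return ds
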