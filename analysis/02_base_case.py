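#!/usr/bin/env python
"""Base-case profile: per-class per-capita means and derived metrics.

Reads the synthetic survey written by 01_generate_population.py, builds the
per-class intake report, and prints the derived quantities a base case is
judged by: percent-of-energy shares, nutrient density of core vs
discretionary choices, and the energy-closure check (stored vs recomputed
energy).
"""

from pathlib import Path

from dietsim import (
    AggregateProfile,
    compute_energy,
    nutrient_density,
    percent_energy,
    population_mean_intake,
)
from dietsim.data_model import (
    PopulationDataset,
    read_composition_table,
    read_intakes,
    read_persons,
)
from dietsim.reporting import basecase_report

ROOT = Path(__file__).resolve().parents[1]


def load_synthetic() -> PopulationDataset:
    base = ROOT / "scratch" / "synthetic"
    foods = read_composition_table(base / "composition.tsv")
    persons = read_persons(base / "persons.tsv")
    intakes = read_intakes(base / "intakes.tsv", foods, persons)
    return PopulationDataset(foods=foods, persons=persons, intakes=intakes)


def main() -> None:
    dataset = load_synthetic()
    report = basecase_report(dataset)
    out = ROOT / "results" / "base_case_profile.tsv"
    out.parent.mkdir(exist_ok=True)
    report.to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")

    total = population_mean_intake(dataset).profile
    core = population_mean_intake(dataset,
                                  ["core_food", "core_beverage"])
    disc = population_mean_intake(
        dataset, ["discretionary_food", "discretionary_beverage"]
    )
    print(f"per-capita energy: {total.energy:.1f} kJ "
          f"(recomputed from macronutrients: {compute_energy(total):.1f} kJ)")
    print(f"discretionary share of energy: "
          f"{disc.profile.energy / total.energy * 100:.1f}%")
    print(f"protein {percent_energy(total, 'protein'):.1f}%E, "
          f"SFA {percent_energy(total, 'sfa'):.1f}%E, "
          f"added sugars {percent_energy(total, 'added_sugars'):.1f}%E, "
          f"alcohol {percent_energy(total, 'alcohol'):.1f}%E")
    print(f"nutrient density: core choices "
          f"{nutrient_density(core, 'grams_food_weight'):.1f} g/1000 kJ, "
          f"discretionary choices "
          f"{nutrient_density(disc, 'grams_food_weight'):.1f} g/1000 kJ")


if __name__ == "__main__":
    main()
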