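"""Report tables, scenario configuration files and run manifests.

Output conventions follow published per-capita intake tables: amounts to one
decimal place, percent-of-energy in parentheses, percent changes with an
explicit sign.  Tidy TSVs are the canonical artifact; figures are optional.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional

import pandas as pd
import yaml

from . import __version__
from .aggregate import AggregateTable
from .basecase import compute_energy, population_mean_intake
from .data_model import PopulationDataset
from .nutrients import (
    MACRO_FIELDS,
    MICRONUTRIENT_UNITS,
    PERCENT_ENERGY_DENSITY,
    NutrientProfile,
)
from .scenarios import (
    PRIMARY_OUTCOMES,
    ReformulationParams,
    ScenarioResult,
    ScenarioSpec,
)

__all__ = [
    "basecase_report",
    "scenario_report",
    "sensitivity_report",
    "spec_from_dict",
    "load_scenario_config",
    "write_run_manifest",
]

#: Report columns and the class labels each aggregates over.
REPORT_COLUMNS = {
    "total": dict(classes=("core_food", "core_beverage",
                           "discretionary_food", "discretionary_beverage")),
    "core": dict(classes=("core_food", "core_beverage")),
    "discretionary": dict(classes=("discretionary_food",
                                   "discretionary_beverage")),
    "discretionary_foods": dict(classes=("discretionary_food",)),
    "discretionary_beverages": dict(classes=("discretionary_beverage",),
                                    exclude_sports_products=True),
}


def _fmt(value: float) -> str:
    return f"{value:.1f}"


def _cell(profile: NutrientProfile, name: str, total_energy: float) -> str:
    # %E is always a share of *total* energy intake, also in class columns
    value = profile.get(name)
    if name in PERCENT_ENERGY_DENSITY and total_energy > 0:
        pe = value * PERCENT_ENERGY_DENSITY[name] / total_energy * 100.0
        return f"{_fmt(value)} ({_fmt(pe)})"
    return _fmt(value)


def basecase_report(data) -> pd.DataFrame:
    """Per-class per-capita intake table (amounts, %E in parentheses).

    Accepts a person-level dataset (columns aggregated with the survey
    conventions: sports products excluded from the beverage column) or an
    aggregate table (columns reported as stored).
    """
    if isinstance(data, AggregateTable):
        profiles = {name: data[name] for name in REPORT_COLUMNS}
    else:
        profiles = {
            name: population_mean_intake(
                data,
                cfg["classes"],
                exclude_sports_products=cfg.get("exclude_sports_products", False),
            ).profile
            for name, cfg in REPORT_COLUMNS.items()
        }
    names = list(MACRO_FIELDS) + list(MICRONUTRIENT_UNITS)
    units = {**MACRO_FIELDS, **MICRONUTRIENT_UNITS}
    total_energy = compute_energy(profiles["total"])
    rows = [
        {
            "nutrient": name,
            "unit": units[name],
            **{col: _cell(profiles[col], name, total_energy)
               for col in REPORT_COLUMNS},
        }
        for name in names
    ]
    return pd.DataFrame(rows)


def scenario_report(result: ScenarioResult) -> pd.DataFrame:
    """Tidy base/modelled/percent-change table for one scenario."""
    units = {**MACRO_FIELDS, **MICRONUTRIENT_UNITS}
    rows = []
    for name, base_value in result.base.profile.items():
        pct = result.pct_change.get(name)
        rows.append(
            {
                "scenario": result.spec.name or result.spec.family,
                "family": result.spec.family,
                "target": result.spec.target,
                "nutrient": name,
                "unit": units[name],
                "base_value": round(base_value, 6),
                "modelled_value": round(result.modelled.profile.get(name), 6),
                "pct_change": "" if pct is None else f"{pct:+.1f}",
                "primary_outcome": name in PRIMARY_OUTCOMES,
            }
        )
    return pd.DataFrame(rows)


def sensitivity_report(results: Mapping[str, ScenarioResult]) -> pd.DataFrame:
    """Envelope table (one row per nutrient, one pct-change column per
    preset) mirroring error-bar figures."""
    presets = list(results)
    any_result = next(iter(results.values()))
    rows = []
    for name, _ in any_result.base.profile.items():
        row = {"nutrient": name}
        for preset in presets:
            pct = results[preset].pct_change.get(name)
            row[f"pct_change_{preset}"] = "" if pct is None else f"{pct:+.1f}"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scenario configuration files
# ---------------------------------------------------------------------------

def spec_from_dict(payload: Mapping) -> ScenarioSpec:
    payload = dict(payload)
    reform = payload.pop("reformulation", None)
    if reform is not None:
        payload["reformulation"] = ReformulationParams(**reform)
    for key in ("compensation_pool", "food_pool_subgroups",
                "beverage_pool_subgroups"):
        if key in payload:
            payload[key] = frozenset(payload[key])
    spec = ScenarioSpec(**payload)
    spec.validate()
    return spec


def load_scenario_config(path) -> Dict[str, ScenarioSpec]:
    """Load a YAML/JSON scenario configuration: name -> spec."""
    text = Path(path).read_text(encoding="utf-8")
    payload = yaml.safe_load(text)
    if not isinstance(payload, Mapping) or "scenarios" not in payload:
        raise ValueError(f"{path}: expected a mapping with a 'scenarios' key")
    out = {}
    for name, entry in payload["scenarios"].items():
        entry = dict(entry)
        entry.setdefault("name", name)
        out[name] = spec_from_dict(entry)
    return out


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def _file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_run_manifest(outdir, inputs: Iterable = (), seed: Optional[int] = None,
                       extra: Optional[Mapping] = None) -> Path:
    """Record command line, input hashes, seed and version for re-runs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "argv": sys.argv,
        "version": __version__,
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "inputs": {str(p): _file_hash(p) for p in inputs},
    }
    if extra:
        manifest.update(extra)
    path = outdir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
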