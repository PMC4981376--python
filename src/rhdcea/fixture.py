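"""Bundled hypothetical-country example: write the input bundle to disk.

The bundle holds the base-case parameter and cost tables as CSV, a synthetic
life table matching a life expectancy at birth of 68 years, and a scenario
YAML with 10% baseline coverage scaled to 70% (PP), 92% (SP) and 95%
(either surgery option).  Regeneration is byte-identical.
"""
from __future__ import annotations

from pathlib import Path

import yaml

from .lifetable import synth_life_table
from .parameters import CostSet, ParameterSet, default_scenarios

__all__ = ["generate_fixture"]


def generate_fixture(out_dir: str | Path, e0: float = 68.0) -> dict[str, Path]:
    """Write the example input bundle; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "parameters": out / "parameters.csv",
        "costs": out / "costs.csv",
        "life_table": out / "life_table.csv",
        "config": out / "scenarios.yaml",
    }
    ParameterSet.base_case().to_csv(paths["parameters"])
    CostSet.base_case().to_csv(paths["costs"])
    synth_life_table(e0).to_frame()[["age", "q"]].to_csv(
        paths["life_table"], index=False)

    scenarios = []
    for s in default_scenarios():
        scenarios.append({
            "name": s.name,
            "intervention": s.intervention,
            "coverage_ante": s.coverage_ante,
            "coverage_post": s.coverage_post,
            "population_reference": s.population_reference,
        })
    config = {
        "parameters": "parameters.csv",
        "costs": "costs.csv",
        "life_table": "life_table.csv",
        "gdp_per_capita": 1300,
        "discount_rate": 0.03,
        "cycles": 100,
        "scenarios": scenarios,
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return paths
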