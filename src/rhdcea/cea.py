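"""Cost-effectiveness engine: ICERs, league tables, NMB, CEACs, and the
model/results objects tying the Markov, outcomes and costing layers together.

Each scale-up scenario is evaluated as an ante/post pair of cohort traces.
The incremental cost is the program cost plus the change in discounted
lifetime healthcare costs; the incremental effect is DALYs averted.  ICERs
follow the usual quadrant conventions: cost-saving interventions report a
negative ratio, interventions with non-positive health gains are flagged
rather than given a ratio.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .costing import healthcare_costs, program_cost
from .lifetable import LifeTable, synth_life_table
from .markov import CohortTrace, run_cohort
from .outcomes import (dalys, dalys_averted, disability_weights,
                       healthy_life_expectancy_gain)
from .parameters import (PROGRAM_COST_OF, CostSet, ModelInputs, ParameterSet,
                         ScenarioConfig, ValidationError, default_scenarios,
                         load_parameters)

__all__ = [
    "IcerValue", "ScenarioResult", "icer", "gdp_multiple", "nmb",
    "league_table", "ceac", "evaluate_scenario", "RhdCeaModel", "RhdCeaResults",
]

COST_SAVING = "cost saving"
DOMINATED = "dominated"
SW_QUADRANT = "SW-quadrant"


@dataclass(frozen=True)
class IcerValue:
    """An ICER value with its dominance flag (value is None when withheld)."""

    value: Optional[float]
    flag: Optional[str] = None

    @property
    def defined(self) -> bool:
        return self.value is not None

    def __str__(self) -> str:
        if self.value is None:
            return self.flag or "undefined"
        s = f"{self.value:,.2f}"
        return f"{s} ({self.flag})" if self.flag else s


def icer(delta_cost: float, delta_effect: float) -> IcerValue:
    """Incremental cost-effectiveness ratio with quadrant handling.

    Positive health gains yield a ratio (negative and flagged cost-saving when
    costs fall); non-positive gains yield a dominance flag with the ratio
    withheld.
    """
    if delta_effect > 0:
        value = delta_cost / delta_effect
        return IcerValue(value=value, flag=COST_SAVING if delta_cost < 0 else None)
    if delta_cost >= 0:
        return IcerValue(value=None, flag=DOMINATED)
    return IcerValue(value=None, flag=SW_QUADRANT)


def gdp_multiple(icer_value: IcerValue, gdp_per_capita: float) -> Optional[float]:
    """ICER as a multiple of GDP per capita, rounded to one decimal.

    Defined only for positive ICERs; cost-saving and dominated options have
    no meaningful multiple.
    """
    if gdp_per_capita <= 0:
        raise ValidationError("gdp_per_capita must be > 0")
    if icer_value.defined and icer_value.value > 0:
        return round(icer_value.value / gdp_per_capita, 1)
    return None


def nmb(cost: float, effect: float, wtp: float) -> float:
    """Net monetary benefit ``wtp * effect - cost``."""
    if wtp < 0:
        raise ValidationError("willingness to pay must be >= 0")
    return wtp * effect - cost


@dataclass(frozen=True)
class ScenarioResult:
    """Deterministic evaluation of one scale-up scenario."""

    name: str
    intervention: str
    delta_cost: float
    delta_effect: float
    icer: IcerValue
    gdp_multiple: Optional[float]
    hle_gain: float
    population_dalys_averted: float
    healthcare_cost_ante: float
    healthcare_cost_post: float
    program_cost: float
    daly_ante: float
    daly_post: float


def league_table(results: Sequence[ScenarioResult],
                 gdp_per_capita: Optional[float] = None) -> pd.DataFrame:
    """Scenarios ranked by ICER, cost-saving first, dominated last.

    The GDP-multiple column prints one decimal for positive ICERs and "---"
    otherwise.
    """
    if len(results) == 0:
        raise ValidationError("league table requires at least one result")
    rows = []
    for r in results:
        gm = r.gdp_multiple
        if gdp_per_capita is not None:
            gm = gdp_multiple(r.icer, gdp_per_capita)
        sort_key = r.icer.value if r.icer.defined else math.inf
        rows.append({
            "scenario": r.name,
            "icer": r.icer.value,
            "flag": r.icer.flag or "",
            "gdp_multiple": gm if gm is not None else "---",
            "delta_cost": r.delta_cost,
            "dalys_averted": r.delta_effect,
            "hle_gain": r.hle_gain,
            "_key": sort_key,
        })
    df = pd.DataFrame(rows).sort_values(["_key", "scenario"], kind="stable")
    return df.drop(columns="_key").reset_index(drop=True)


def ceac(psa, wtp_grid, include_status_quo: bool = True) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves from PSA trials.

    For each willingness-to-pay value, the fraction of trials in which each
    option (the scenarios, plus the status quo at zero incremental cost and
    effect) attains the highest net monetary benefit.  Fractions sum to 1 at
    every grid point; ties break toward the option listed first (status quo
    first when included).
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.ndim != 1 or wtp_grid.size == 0:
        raise ValidationError("wtp_grid must be a non-empty 1-D array")
    if np.any(np.diff(wtp_grid) < 0):
        raise ValidationError("wtp_grid must be sorted ascending")
    names = list(psa.scenario_names)
    if not names or psa.n_trials < 1:
        raise ValidationError("PSA must contain at least one trial")
    n = psa.n_trials
    # (options, trials) arrays of incremental cost and effect
    costs = np.stack([psa.results[name][:, 0] for name in names])
    effects = np.stack([psa.results[name][:, 1] for name in names])
    options = names
    if include_status_quo:
        costs = np.vstack([np.zeros(n), costs])
        effects = np.vstack([np.zeros(n), effects])
        options = ["Status quo"] + names

    out = np.zeros((wtp_grid.size, len(options)))
    for i, wtp in enumerate(wtp_grid):
        benefit = wtp * effects - costs
        best = np.argmax(benefit, axis=0)  # first index wins ties
        counts = np.bincount(best, minlength=len(options))
        out[i] = counts / n
    df = pd.DataFrame(out, columns=options)
    df.insert(0, "wtp", wtp_grid)
    return df


def evaluate_scenario(params: ParameterSet, costs: CostSet,
                      life_table: LifeTable,
                      scenario: ScenarioConfig) -> ScenarioResult:
    """Run the ante/post traces of one scenario and derive its CEA outputs."""
    rate = scenario.discount_rate
    trace_ante = run_cohort(params, life_table, scenario,
                            scenario.coverage_ante, label="ante")
    trace_post = run_cohort(params, life_table, scenario,
                            scenario.coverage_post, label="post")

    hc_ante = healthcare_costs(trace_ante, costs, rate)
    hc_post = healthcare_costs(trace_post, costs, rate)
    prog = program_cost(scenario, costs[PROGRAM_COST_OF[scenario.intervention]],
                        rate=rate)

    w = disability_weights(params)
    d_ante = dalys(trace_ante, w, life_table, rate)
    d_post = dalys(trace_post, w, life_table, rate)
    delta_effect = d_ante.daly - d_post.daly
    delta_cost = hc_post + prog - hc_ante

    ratio = icer(delta_cost, delta_effect)
    return ScenarioResult(
        name=scenario.name,
        intervention=scenario.intervention,
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        icer=ratio,
        gdp_multiple=gdp_multiple(ratio, scenario.gdp_per_capita),
        hle_gain=healthy_life_expectancy_gain(trace_ante, trace_post, w),
        population_dalys_averted=(delta_effect * scenario.population_reference
                                  / scenario.cycles),
        healthcare_cost_ante=hc_ante,
        healthcare_cost_post=hc_post,
        program_cost=prog,
        daly_ante=d_ante.daly,
        daly_post=d_post.daly,
    )


class RhdCeaModel:
    """Lifetime Markov cohort cost-effectiveness model of ARF/RHD control.

    Parameters
    ----------
    parameters : ParameterSet
        Epidemiological inputs (transition probabilities, effect sizes,
        disability weights, milestone ages).
    costs : CostSet
        State and program costs (2010 US$).
    life_table : LifeTable
        Background mortality of the modeled country.
    scenarios : sequence of ScenarioConfig
        Coverage scale-up scenarios to compare.

    Examples
    --------
    >>> model = RhdCeaModel.base_case()
    >>> results = model.fit()
    >>> print(results.summary())           # doctest: +SKIP
    """

    def __init__(self, parameters: ParameterSet, costs: CostSet,
                 life_table: LifeTable,
                 scenarios: Sequence[ScenarioConfig]):
        if not scenarios:
            raise ValidationError("at least one scenario is required")
        self.parameters = parameters
        self.costs = costs
        self.life_table = life_table
        self.scenarios = list(scenarios)

    @classmethod
    def base_case(cls, e0: float = 68.0) -> "RhdCeaModel":
        """Bundled hypothetical-country inputs (synthetic life table)."""
        return cls(ParameterSet.base_case(), CostSet.base_case(),
                   synth_life_table(e0), default_scenarios())

    @classmethod
    def from_config(cls, path) -> "RhdCeaModel":
        """Build from a YAML config referencing the CSV input tables."""
        inputs: ModelInputs = load_parameters(path)
        life = inputs.life_table or synth_life_table(68.0)
        scenarios = inputs.scenarios or default_scenarios()
        return cls(inputs.parameters, inputs.costs, life, scenarios)

    def fit(self) -> "RhdCeaResults":
        """Deterministic base-case evaluation of every scenario."""
        results = [evaluate_scenario(self.parameters, self.costs,
                                     self.life_table, s)
                   for s in self.scenarios]
        return RhdCeaResults(self, results)

    def traces(self, scenario: ScenarioConfig) -> tuple[CohortTrace, CohortTrace]:
        """(ante, post) cohort traces of one scenario."""
        return (run_cohort(self.parameters, self.life_table, scenario,
                           scenario.coverage_ante, label="ante"),
                run_cohort(self.parameters, self.life_table, scenario,
                           scenario.coverage_post, label="post"))

    def tornado(self, scenario: ScenarioConfig | str, **kwargs) -> pd.DataFrame:
        from .sensitivity import tornado
        return tornado(self.parameters, self.costs, self.life_table,
                       self._resolve(scenario), **kwargs)

    def run_psa(self, n_trials: int = 2000, seed: int = 0):
        from .sensitivity import run_psa
        return run_psa(self.parameters, self.costs, self.life_table,
                       self.scenarios, n_trials=n_trials, seed=seed)

    def _resolve(self, scenario) -> ScenarioConfig:
        if isinstance(scenario, ScenarioConfig):
            return scenario
        for s in self.scenarios:
            if s.name == scenario or s.intervention == scenario:
                return s
        raise ValidationError(f"unknown scenario {scenario!r}")


class RhdCeaResults:
    """Deterministic results of an :class:`RhdCeaModel` evaluation."""

    def __init__(self, model: RhdCeaModel, results: Sequence[ScenarioResult]):
        self.model = model
        self.scenario_results = list(results)

    def __getitem__(self, name: str) -> ScenarioResult:
        for r in self.scenario_results:
            if r.name == name or r.intervention == name:
                return r
        raise KeyError(name)

    def league_table(self) -> pd.DataFrame:
        return league_table(self.scenario_results)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.scenario_results:
            rows.append({
                "scenario": r.name,
                "intervention": r.intervention,
                "delta_cost": r.delta_cost,
                "dalys_averted": r.delta_effect,
                "icer": r.icer.value,
                "flag": r.icer.flag or "",
                "gdp_multiple": r.gdp_multiple,
                "hle_gain": r.hle_gain,
                "population_dalys_averted_per_year": r.population_dalys_averted,
                "healthcare_cost_ante": r.healthcare_cost_ante,
                "healthcare_cost_post": r.healthcare_cost_post,
                "program_cost": r.program_cost,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable league table."""
        df = self.league_table().copy()
        df["icer"] = [
            "---" if v is None or (isinstance(v, float) and math.isnan(v))
            else f"${v:,.2f}" for v in df["icer"]
        ]
        df["delta_cost"] = df["delta_cost"].map(lambda v: f"${v:,.2f}")
        df["dalys_averted"] = df["dalys_averted"].map(lambda v: f"{v:.4f}")
        df["hle_gain"] = df["hle_gain"].map(lambda v: f"{v:.2f}")
        header = ("ARF/RHD scale-up cost-effectiveness (per reference "
                  "individual, discounted)")
        return header + "\n" + "=" * len(header) + "\n" + df.to_string(index=False)
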