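"""Model inputs: epidemiological parameters, costs, and scenario configuration.

The parameter table mirrors the published base case for the hypothetical
low-income country: annual transition probabilities of the ARF/RHD natural
history, intervention effect sizes (proportional risk reductions), GBD
disability weights, and average ages of disease milestones.  Each row carries
a point estimate with low/high uncertainty bounds and the distribution family
used for probabilistic sensitivity analysis.  Costs are in nominal 2010 US$
from a health-system perspective.
"""
from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import pandas as pd
import yaml

FAMILIES = frozenset({"beta", "dirichlet", "lognormal", "gamma"})

PARAMETER_KINDS = ("probability", "risk_reduction", "disability_weight", "age")

INTERVENTIONS = ("PP", "SP", "VS_build", "VS_refer")

#: Intervention scenario -> the transition lever it moves.  Both surgery
#: delivery options move the same clinical lever and differ only in program
#: cost.
LEVER_OF = {"PP": "PP", "SP": "SP", "VS_build": "VS", "VS_refer": "VS"}


class ValidationError(ValueError):
    """An input table or scenario violates a model invariant."""


@dataclass(frozen=True)
class ParameterEstimate:
    """One uncertain model input with PSA distribution metadata.

    Parameters
    ----------
    name : str
        Canonical identifier (snake_case).
    base, low, high : float
        Point estimate and uncertainty bounds (interpreted as a 95% interval
        when fitting PSA distributions).
    family : str
        PSA distribution family: ``beta``, ``dirichlet``, ``lognormal`` or
        ``gamma``.
    kind : str
        Domain of the quantity: ``probability``, ``risk_reduction``,
        ``disability_weight`` or ``age``.
    competing_group : str, optional
        Rows sharing a group are competing exits from one state and are
        sampled jointly from a Dirichlet.
    age_window : (int, int), optional
        Ages (inclusive) during which ``base`` applies; the probability is
        zero before the window.
    decays_after_window : bool
        If True the probability decays exponentially (rate 0.1/yr) past the
        window's end.
    """

    name: str
    base: float
    low: float
    high: float
    family: str
    kind: str = "probability"
    competing_group: Optional[str] = None
    age_window: Optional[tuple[int, int]] = None
    decays_after_window: bool = False
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(
                f"parameter {self.name!r}: unknown distribution family "
                f"{self.family!r} (must be one of {sorted(FAMILIES)})"
            )
        if self.kind not in PARAMETER_KINDS:
            raise ValidationError(
                f"parameter {self.name!r}: unknown kind {self.kind!r}"
            )
        if not (self.low <= self.base <= self.high):
            raise ValidationError(
                f"parameter {self.name!r}: bounds must satisfy "
                f"low <= base <= high, got ({self.low}, {self.base}, {self.high})"
            )
        if self.kind in ("probability", "disability_weight"):
            if self.low < 0 or self.high > 1:
                raise ValidationError(
                    f"parameter {self.name!r}: {self.kind} bounds must lie in "
                    f"[0, 1], got ({self.low}, {self.high})"
                )
        if self.kind == "risk_reduction" and not (0 < self.base < 1):
            raise ValidationError(
                f"parameter {self.name!r}: risk reductions are proportional "
                f"and must lie strictly in (0, 1), got {self.base}"
            )
        if self.age_window is not None:
            a0, a1 = self.age_window
            if a0 > a1 or a0 < 0:
                raise ValidationError(
                    f"parameter {self.name!r}: invalid age window {self.age_window}"
                )

    def replace(self, **changes) -> "ParameterEstimate":
        return dataclasses.replace(self, **changes)


def _p(name, base, low, high, family, label, *, kind="probability",
       group=None, window=None, decays=False) -> ParameterEstimate:
    return ParameterEstimate(
        name=name, base=base, low=low, high=high, family=family, kind=kind,
        competing_group=group, age_window=window, decays_after_window=decays,
        label=label,
    )


#: Base-case parameter table for the hypothetical country (annual values).
BASE_PARAMETERS: tuple[ParameterEstimate, ...] = (
    _p("arf_first_incidence", 0.00045, 0.00030, 0.00060, "beta",
       "Chance of ARF (first episode)", window=(5, 14), decays=True),
    _p("rhd_progression_first", 0.360, 0.241, 0.479, "dirichlet",
       "Chance of progression to RHD (ARF first episode)", group="arf_first_exits"),
    _p("arf_cfr_first", 0.010, 0.005, 0.020, "dirichlet",
       "Case-fatality rate from ARF (first episode)", group="arf_first_exits"),
    _p("arf_recurrence", 0.113, 0.075, 0.150, "beta",
       "Chance of ARF (recurrence)", window=(5, 24), decays=True),
    _p("arf_cfr_recurrence", 0.020, 0.010, 0.040, "dirichlet",
       "Case-fatality rate from ARF (recurrence)", group="arf_recur_exits"),
    _p("rhd_progression_recurrence", 0.720, 0.482, 0.958, "dirichlet",
       "Chance of progression to RHD (ARF recurrence)", group="arf_recur_exits"),
    _p("hf_progression", 0.008, 0.005, 0.011, "dirichlet",
       "Chance of progression to chronic HF", group="rhd_exits"),
    _p("hf_remission", 0.000, 0.000, 0.000, "dirichlet",
       "Chance of remission from chronic HF", group="hf_exits"),
    _p("hf_death", 0.125, 0.088, 0.166, "dirichlet",
       "Chance of death from HF", group="hf_exits"),
    _p("stroke_incidence", 0.003, 0.002, 0.004, "dirichlet",
       "Chance of developing AF and stroke", group="rhd_exits"),
    _p("stroke_death", 0.167, 0.130, 0.190, "beta",
       "Chance of death given stroke"),
    _p("rr_primary_prevention", 0.320, 0.210, 0.480, "lognormal",
       "Risk reduction from primary prevention", kind="risk_reduction"),
    _p("rr_secondary_prevention", 0.450, 0.220, 0.920, "lognormal",
       "Risk reduction from secondary prevention", kind="risk_reduction"),
    _p("rr_valve_surgery", 0.800, 0.690, 0.910, "lognormal",
       "Risk reduction from valve surgery", kind="risk_reduction"),
    _p("dw_arf", 0.005, 0.003, 0.007, "beta",
       "ARF disability weight", kind="disability_weight"),
    _p("dw_rhd", 0.041, 0.026, 0.062, "beta",
       "RHD disability weight", kind="disability_weight"),
    _p("dw_hf", 0.179, 0.122, 0.251, "beta",
       "HF disability weight", kind="disability_weight"),
    _p("dw_stroke", 0.070, 0.046, 0.099, "beta",
       "Stroke disability weight", kind="disability_weight"),
    _p("age_first_arf", 8, 5, 11, "gamma",
       "Average age of ARF first attack", kind="age"),
    _p("age_recurrence", 12, 8, 16, "gamma",
       "Average age of ARF recurrence", kind="age"),
    _p("age_rhd", 24, 14, 34, "gamma",
       "Average age of RHD prevalence", kind="age"),
)

_PARAM_REGISTRY: dict[str, ParameterEstimate] = {p.name: p for p in BASE_PARAMETERS}
_PARAM_BY_LABEL: dict[str, str] = {p.label: p.name for p in BASE_PARAMETERS}

REQUIRED_PARAMETERS = frozenset(_PARAM_REGISTRY)


class ParameterSet(Mapping):
    """Validated collection of all required :class:`ParameterEstimate` rows."""

    def __init__(self, estimates: Iterable[ParameterEstimate]):
        self._estimates: dict[str, ParameterEstimate] = {}
        for est in estimates:
            if est.name in self._estimates:
                raise ValidationError(f"duplicate parameter row {est.name!r}")
            self._estimates[est.name] = est
        missing = REQUIRED_PARAMETERS - self._estimates.keys()
        if missing:
            labels = sorted(_PARAM_REGISTRY[m].label for m in missing)
            raise ValidationError(f"missing required parameter row(s): {labels}")

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, name: str) -> ParameterEstimate:
        return self._estimates[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._estimates)

    def __len__(self) -> int:
        return len(self._estimates)

    def value(self, name: str) -> float:
        """Point estimate for one row."""
        return self._estimates[name].base

    def groups(self) -> dict[str, list[ParameterEstimate]]:
        """Competing-transition groups keyed by group name."""
        out: dict[str, list[ParameterEstimate]] = {}
        for est in self._estimates.values():
            if est.competing_group:
                out.setdefault(est.competing_group, []).append(est)
        return out

    def with_values(self, values: Mapping[str, float]) -> "ParameterSet":
        """New set with point estimates replaced (bounds widened to cover).

        Used by sensitivity analyses, where a sampled or extreme value may
        fall outside the printed interval.
        """
        new = []
        for name, est in self._estimates.items():
            if name in values:
                v = float(values[name])
                est = est.replace(base=v, low=min(est.low, v), high=max(est.high, v))
            new.append(est)
        return ParameterSet(new)

    # I/O ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for est in self._estimates.values():
            w = est.age_window
            rows.append({
                "name": est.label or est.name,
                "base": est.base, "low": est.low, "high": est.high,
                "family": est.family,
                "group": est.competing_group or "",
                "window_start": "" if w is None else w[0],
                "window_end": "" if w is None else w[1],
            })
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ParameterSet":
        df = pd.read_csv(path, dtype={"name": str})
        estimates = []
        for _, row in df.iterrows():
            raw = str(row["name"]).strip()
            name = _PARAM_BY_LABEL.get(raw, raw)
            if name not in _PARAM_REGISTRY:
                raise ValidationError(f"unknown parameter row {raw!r}")
            ref = _PARAM_REGISTRY[name]

            def _get(col, default):
                if col in row and not pd.isna(row[col]) and str(row[col]) != "":
                    return row[col]
                return default

            window = ref.age_window
            ws, we = _get("window_start", None), _get("window_end", None)
            if ws is not None and we is not None:
                window = (int(ws), int(we))
            estimates.append(ref.replace(
                base=float(_get("base", ref.base)),
                low=float(_get("low", ref.low)),
                high=float(_get("high", ref.high)),
                family=str(_get("family", ref.family)),
                competing_group=str(_get("group", ref.competing_group) or "") or None,
                age_window=window,
            ))
        return cls(estimates)

    @classmethod
    def base_case(cls) -> "ParameterSet":
        return cls(BASE_PARAMETERS)

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and self._estimates == other._estimates


# --------------------------------------------------------------------------
# Costs
# --------------------------------------------------------------------------

COST_KINDS = ("state_cost", "program_cost")


@dataclass(frozen=True)
class CostItem:
    """One cost row: 2010 US$ per person-cycle (state) or per capita (program)."""

    name: str
    base: float
    low: float
    high: float
    kind: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in COST_KINDS:
            raise ValidationError(f"cost {self.name!r}: unknown kind {self.kind!r}")
        if not (0 <= self.low <= self.base <= self.high):
            raise ValidationError(
                f"cost {self.name!r}: bounds must satisfy 0 <= low <= base <= "
                f"high, got ({self.low}, {self.base}, {self.high})"
            )

    def replace(self, **changes) -> "CostItem":
        return dataclasses.replace(self, **changes)


def _c(name, base, low, high, kind, label) -> CostItem:
    return CostItem(name=name, base=base, low=low, high=high, kind=kind, label=label)


BASE_COSTS: tuple[CostItem, ...] = (
    _c("cost_arf_hospitalization", 1490.00, 745.00, 2235.00, "state_cost",
       "ARF hospitalization"),
    _c("cost_remission_sp", 288.00, 144.00, 432.00, "state_cost",
       "Remission (secondary prevention)"),
    _c("cost_rhd_sp", 617.10, 308.55, 925.65, "state_cost",
       "RHD (secondary prevention)"),
    _c("cost_severe_hf", 957.10, 478.55, 1435.65, "state_cost",
       "Severe HF"),
    _c("cost_stroke_af", 617.10, 308.55, 925.65, "state_cost",
       "Stroke and AF"),
    _c("cost_pp_program", 3.66, 1.83, 5.48, "program_cost",
       "Primary prevention component"),
    _c("cost_sp_program", 2226.59, 1113.30, 3339.89, "program_cost",
       "Secondary prevention component"),
    _c("cost_vs_build_program", 25626.54, 12813.27, 38439.80, "program_cost",
       "Scale up of surgery: build center"),
    _c("cost_vs_refer_program", 3711.69, 1855.84, 5567.53, "program_cost",
       "Scale up of surgery: refer abroad"),
)

_COST_REGISTRY: dict[str, CostItem] = {c.name: c for c in BASE_COSTS}
_COST_BY_LABEL: dict[str, str] = {c.label: c.name for c in BASE_COSTS}

REQUIRED_COSTS = frozenset(_COST_REGISTRY)

#: Program-cost item funding each scale-up scenario.
PROGRAM_COST_OF = {
    "PP": "cost_pp_program",
    "SP": "cost_sp_program",
    "VS_build": "cost_vs_build_program",
    "VS_refer": "cost_vs_refer_program",
}


class CostSet(Mapping):
    """Validated collection of all required :class:`CostItem` rows."""

    def __init__(self, items: Iterable[CostItem]):
        self._items: dict[str, CostItem] = {}
        for item in items:
            if item.name in self._items:
                raise ValidationError(f"duplicate cost row {item.name!r}")
            self._items[item.name] = item
        missing = REQUIRED_COSTS - self._items.keys()
        if missing:
            labels = sorted(_COST_REGISTRY[m].label for m in missing)
            raise ValidationError(f"missing required cost row(s): {labels}")

    def __getitem__(self, name: str) -> CostItem:
        return self._items[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._items)

    def __len__(self) -> int:
        return len(self._items)

    def value(self, name: str) -> float:
        return self._items[name].base

    def with_values(self, values: Mapping[str, float]) -> "CostSet":
        new = []
        for name, item in self._items.items():
            if name in values:
                v = float(values[name])
                item = item.replace(base=v, low=min(item.low, v),
                                    high=max(item.high, v))
            new.append(item)
        return CostSet(new)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"name": c.label or c.name, "base": c.base, "low": c.low,
             "high": c.high, "kind": c.kind}
            for c in self._items.values()
        ])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CostSet":
        df = pd.read_csv(path, dtype={"name": str})
        items = []
        for _, row in df.iterrows():
            raw = str(row["name"]).strip()
            name = _COST_BY_LABEL.get(raw, raw)
            if name not in _COST_REGISTRY:
                raise ValidationError(f"unknown cost row {raw!r}")
            ref = _COST_REGISTRY[name]

            def _get(col, default):
                if col in row and not pd.isna(row[col]) and str(row[col]) != "":
                    return row[col]
                return default

            items.append(ref.replace(
                base=float(_get("base", ref.base)),
                low=float(_get("low", ref.low)),
                high=float(_get("high", ref.high)),
                kind=str(_get("kind", ref.kind)),
            ))
        return cls(items)

    @classmethod
    def base_case(cls) -> "CostSet":
        return cls(BASE_COSTS)

    def __eq__(self, other) -> bool:
        return isinstance(other, CostSet) and self._items == other._items


# --------------------------------------------------------------------------
# Scenarios
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """One coverage scale-up scenario (ante -> post).

    ``start_age`` and ``start_state`` default per intervention: the primary
    prevention reference case is a newborn in the general population (WELL at
    age 0); the secondary prevention reference case has a history of ARF
    (RF remission, average age of first attack); the surgery reference case
    has prevalent RHD (average age of RHD prevalence).
    """

    name: str
    intervention: str
    coverage_ante: float
    coverage_post: float
    discount_rate: float = 0.03
    cycles: int = 100
    start_age: Optional[int] = None
    gdp_per_capita: float = 1300.0
    population_reference: float = 1.0
    background_coverage: Optional[float] = None

    def __post_init__(self) -> None:
        if self.intervention not in INTERVENTIONS:
            raise ValidationError(
                f"scenario {self.name!r}: unknown intervention "
                f"{self.intervention!r} (must be one of {INTERVENTIONS})"
            )
        if not (0 <= self.coverage_ante <= self.coverage_post <= 1):
            raise ValidationError(
                f"scenario {self.name!r}: scale-up requires "
                f"0 <= coverage_ante <= coverage_post <= 1, got "
                f"({self.coverage_ante}, {self.coverage_post})"
            )
        if self.cycles < 1:
            raise ValidationError(f"scenario {self.name!r}: cycles must be >= 1")
        if self.discount_rate < 0:
            raise ValidationError(
                f"scenario {self.name!r}: discount_rate must be >= 0"
            )

    @property
    def lever(self) -> str:
        return LEVER_OF[self.intervention]

    def resolve_start_age(self, params: ParameterSet) -> int:
        if self.start_age is not None:
            return int(self.start_age)
        if self.lever == "PP":
            return 0
        if self.lever == "SP":
            return int(round(params.value("age_first_arf")))
        return int(round(params.value("age_rhd")))

    def coverage_map(self, coverage: float) -> dict[str, float]:
        """Coverage per lever with the focal lever at ``coverage``.

        Non-focal interventions stay at the background (ante) level in both
        arms of a scale-up comparison.
        """
        bg = self.background_coverage
        if bg is None:
            bg = self.coverage_ante
        cov = {"PP": bg, "SP": bg, "VS": bg}
        cov[self.lever] = float(coverage)
        return cov


def default_scenarios(*, gdp_per_capita: float = 1300.0,
                      discount_rate: float = 0.03,
                      cycles: int = 100) -> list[ScenarioConfig]:
    """The four hypothetical-country scale-up scenarios.

    Baseline coverage is 10% for every intervention; targets are 70% (PP),
    92% (SP) and 95% (either surgery option).  Reference populations: 20.9M
    total population (PP), 83,300 individuals with ARF history (1.7% of the
    4.9M aged 5-24), 49,000 prevalent RHD cases (1% of the 4.9M).
    """
    common = dict(discount_rate=discount_rate, cycles=cycles,
                  gdp_per_capita=gdp_per_capita)
    return [
        ScenarioConfig(name="Scale up PP", intervention="PP",
                       coverage_ante=0.10, coverage_post=0.70,
                       population_reference=20_900_000, **common),
        ScenarioConfig(name="Scale up SP", intervention="SP",
                       coverage_ante=0.10, coverage_post=0.92,
                       population_reference=83_300, **common),
        ScenarioConfig(name="VS: build surgical center", intervention="VS_build",
                       coverage_ante=0.10, coverage_post=0.95,
                       population_reference=49_000, **common),
        ScenarioConfig(name="VS: refer for surgery abroad", intervention="VS_refer",
                       coverage_ante=0.10, coverage_post=0.95,
                       population_reference=49_000, **common),
    ]


# --------------------------------------------------------------------------
# Config loading (YAML referencing the two CSV tables)
# --------------------------------------------------------------------------

@dataclass
class ModelInputs:
    parameters: ParameterSet
    costs: CostSet
    life_table: Optional[object] = None  # LifeTable; kept loose to avoid cycle
    scenarios: list[ScenarioConfig] = field(default_factory=list)


def load_parameters(path: str | Path) -> ModelInputs:
    """Load and validate a YAML config referencing parameter/cost CSV tables.

    The YAML may also name a life-table CSV (columns ``age,q``) or request a
    synthetic one via ``life_expectancy_at_birth``, and list scenarios.
    Omitted fields fall back to the bundled base case.
    """
    from .lifetable import LifeTable, synth_life_table

    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    base = path.parent

    if "parameters" in cfg:
        params = ParameterSet.from_csv(base / cfg["parameters"])
    else:
        params = ParameterSet.base_case()
    if "costs" in cfg:
        costs = CostSet.from_csv(base / cfg["costs"])
    else:
        costs = CostSet.base_case()

    life = None
    if "life_table" in cfg:
        life = LifeTable.from_csv(base / cfg["life_table"])
    elif "life_expectancy_at_birth" in cfg:
        life = synth_life_table(float(cfg["life_expectancy_at_birth"]))

    shared = {k: cfg[k] for k in ("discount_rate", "cycles", "gdp_per_capita")
              if k in cfg}
    if "scenarios" in cfg and not cfg["scenarios"]:
        raise ValidationError(
            f"config {path.name}: the scenario list is empty; list at least "
            "one scale-up scenario or omit the key to use the defaults"
        )
    scenarios = []
    for s in cfg.get("scenarios", []):
        kwargs = dict(shared)
        kwargs.update(s)
        scenarios.append(ScenarioConfig(**kwargs))
    return ModelInputs(parameters=params, costs=costs, life_table=life,
                       scenarios=scenarios)
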