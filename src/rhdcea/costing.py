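"""Healthcare and program costs (health-system perspective, 2010 US$).

State costs accrue per person-cycle along a trace and are discounted like the
health outcomes.  By default every occupant of a state accrues its cost (the
standard Markov costing convention); ``sp_coverage`` optionally restricts the
two secondary-prevention state costs (remission and chronic RHD on
prophylaxis) to the covered fraction of occupants.  Program costs enter as
per-reference-individual discounted amounts, either as a precomputed
component or from a costing worksheet with annualized capital.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .markov import N_STATES, CohortTrace, State
from .outcomes import discount_factor
from .parameters import CostItem, CostSet, ScenarioConfig, ValidationError

__all__ = [
    "ProgramCosting", "annualize_capital", "state_cost_vector",
    "healthcare_costs", "program_cost",
]


def annualize_capital(capital: float, useful_life: float, rate: float) -> float:
    """Equivalent annual cost of a one-time capital outlay.

    Standard capital-recovery factor ``capital * r / (1 - (1+r)^-L)``;
    straight-line ``capital / L`` at rate 0.
    """
    if capital < 0:
        raise ValidationError("capital must be >= 0")
    if useful_life < 1:
        raise ValidationError("useful_life must be >= 1 year")
    if rate == 0:
        return capital / useful_life
    return capital * rate / (1.0 - (1.0 + rate) ** (-useful_life))


def state_cost_vector(costs: CostSet, sp_coverage: float = 1.0) -> np.ndarray:
    """Per-state annual cost vector at a given secondary-prevention coverage."""
    if not (0 <= sp_coverage <= 1):
        raise ValidationError("sp_coverage must lie in [0, 1]")
    c = np.zeros(N_STATES)
    c[State.ARF_FIRST] = c[State.ARF_RECUR] = costs.value("cost_arf_hospitalization")
    c[State.RF_REMISSION] = sp_coverage * costs.value("cost_remission_sp")
    c[State.RHD] = sp_coverage * costs.value("cost_rhd_sp")
    c[State.SEVERE_HF] = costs.value("cost_severe_hf")
    c[State.STROKE_AF] = costs.value("cost_stroke_af")
    return c


def healthcare_costs(trace: CohortTrace, costs: CostSet, rate: float,
                     sp_coverage: float = 1.0) -> float:
    """Discounted lifetime healthcare cost per reference individual."""
    cvec = state_cost_vector(costs, sp_coverage)
    occ = trace.occupancy[:-1]
    df = discount_factor(np.arange(occ.shape[0]), rate)
    return float(df @ (occ @ cvec))


@dataclass(frozen=True)
class ProgramCosting:
    """Program-cost worksheet for one scale-up scenario.

    ``per_capita_components`` are already-per-capita discounted amounts
    (e.g. half of the secondary-prevention program component for the
    referral-based surgery option) added after dividing the discounted
    program stream by the reference population.
    """

    capital: float = 0.0
    useful_life: float = 30.0
    recurrent_annual: float = 0.0
    admin_loading: float = 0.0
    unit_cost_per_case: float = 0.0
    cases_per_year: float = 0.0
    per_capita_components: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("capital", "recurrent_annual", "unit_cost_per_case",
                     "cases_per_year", "admin_loading"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.useful_life < 1:
            raise ValidationError("useful_life must be >= 1 year")

    def annual_total(self, rate: float) -> float:
        """Annualized capital + recurrent + admin-loaded case costs."""
        return (annualize_capital(self.capital, self.useful_life, rate)
                + self.recurrent_annual
                + self.unit_cost_per_case * self.cases_per_year
                * (1.0 + self.admin_loading))


def program_cost(scenario: ScenarioConfig, costing, horizon: int = 30,
                 rate: float = 0.03) -> float:
    """Discounted per-reference-individual program cost of a scale-up.

    A precomputed component (a :class:`CostItem` or bare number) passes
    through unchanged.  A :class:`ProgramCosting` worksheet is expanded to a
    discounted annual stream over ``horizon`` years and divided by the
    scenario's reference population.
    """
    if horizon < 1:
        raise ValidationError("horizon must be >= 1 year")
    if costing is None:
        raise ValidationError(
            "supply either a precomputed program-cost component or a "
            "ProgramCosting worksheet"
        )
    if isinstance(costing, CostItem):
        return float(costing.base)
    if isinstance(costing, (int, float)):
        return float(costing)
    if isinstance(costing, ProgramCosting):
        stream = costing.annual_total(rate) * discount_factor(
            np.arange(horizon), rate).sum()
        per_capita = stream / scenario.population_reference
        return float(per_capita + sum(costing.per_capita_components.values()))
    raise ValidationError(f"unsupported program costing object: {costing!r}")
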