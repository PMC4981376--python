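"""Health outcomes: discounted DALYs (YLL + YLD) and healthy life expectancy.

YLD accrues disability-weighted time in diseased states; YLL counts remaining
life expectancy at the age of each disease death, with background deaths
excluded (the comparison of ante and post arms is then net of background
mortality by construction).  Remaining life-years at death are discounted as
an annuity continuing from the death cycle, consistent with discounting all
health outcomes at the same annual rate.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from collections.abc import Mapping

import numpy as np

from .lifetable import LifeTable
from .markov import ALIVE_STATES, N_STATES, CohortTrace, State
from .parameters import ParameterSet, ValidationError

__all__ = [
    "DalyBreakdown", "discount_factor", "annuity_factor", "disability_weights",
    "yld", "yll", "dalys", "dalys_averted", "healthy_life_expectancy_gain",
]


def discount_factor(cycle, rate: float):
    """Discount factor ``(1 + rate)^(-cycle)``; cycle 0 is undiscounted."""
    c = np.asarray(cycle, dtype=float)
    if np.any(c < 0):
        raise ValidationError("cycle must be >= 0")
    if rate < 0:
        raise ValidationError("rate must be >= 0")
    out = (1.0 + rate) ** (-c)
    return float(out) if np.isscalar(cycle) else out


def annuity_factor(years: float, rate: float) -> float:
    """Present value of a stream of 1 life-year over ``years`` years.

    Whole years are discounted from the start of the stream (first year
    undiscounted); a fractional final year contributes proportionally.
    Equals ``years`` at rate 0.
    """
    if years < 0:
        raise ValidationError("years must be >= 0")
    if rate == 0:
        return float(years)
    n = int(math.floor(years))
    frac = years - n
    whole = (1.0 - (1.0 + rate) ** (-n)) / (1.0 - 1.0 / (1.0 + rate))
    return whole + frac * (1.0 + rate) ** (-n)


def disability_weights(params: ParameterSet) -> np.ndarray:
    """Per-state disability-weight vector (dead and well states weigh 0)."""
    w = np.zeros(N_STATES)
    w[State.ARF_FIRST] = w[State.ARF_RECUR] = params.value("dw_arf")
    w[State.RHD] = params.value("dw_rhd")
    w[State.SEVERE_HF] = params.value("dw_hf")
    w[State.STROKE_AF] = params.value("dw_stroke")
    return w


def _weight_vector(weights) -> np.ndarray:
    if isinstance(weights, ParameterSet):
        w = disability_weights(weights)
    elif isinstance(weights, Mapping):
        w = np.zeros(N_STATES)
        for state, val in weights.items():
            w[State[state] if isinstance(state, str) else State(state)] = val
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != (N_STATES,):
        raise ValidationError(f"weights must have {N_STATES} entries")
    if np.any(w < 0) or np.any(w > 1):
        raise ValidationError("disability weights must lie in [0, 1]")
    return w


def yld(trace: CohortTrace, weights, rate: float) -> float:
    """Discounted years lived with disability along a trace."""
    w = _weight_vector(weights)
    occ = trace.occupancy[:-1]  # years lived: rows 0..cycles-1
    df = discount_factor(np.arange(occ.shape[0]), rate)
    return float(df @ (occ @ w))


def yll(trace: CohortTrace, life_table: LifeTable, rate: float) -> float:
    """Discounted years of life lost to disease deaths along a trace.

    Each new entry into the disease-death state at cycle k loses the
    life-table remaining expectancy at that age, discounted as an annuity
    from cycle k.  Background deaths contribute nothing.
    """
    deaths = trace.new_entries(State.DEAD_DISEASE)
    total = 0.0
    for k in np.nonzero(deaths > 0)[0]:
        age = min(trace.start_age + int(k), life_table.closing_age)
        total += deaths[k] * discount_factor(int(k), rate) * annuity_factor(
            float(life_table.e[age]), rate)
    return total


@dataclass(frozen=True)
class DalyBreakdown:
    yll: float
    yld: float

    @property
    def daly(self) -> float:
        return self.yll + self.yld


def dalys(trace: CohortTrace, weights, life_table: LifeTable,
          rate: float) -> DalyBreakdown:
    return DalyBreakdown(yll=yll(trace, life_table, rate),
                         yld=yld(trace, weights, rate))


def _check_comparable(trace_ante: CohortTrace, trace_post: CohortTrace) -> None:
    if (trace_ante.start_age != trace_post.start_age
            or trace_ante.cycles != trace_post.cycles):
        raise ValidationError(
            "ante and post traces must share start age and cycle count"
        )


def dalys_averted(trace_ante: CohortTrace, trace_post: CohortTrace, weights,
                  life_table: LifeTable, rate: float) -> float:
    """DALY difference (ante minus post); positive when scale-up improves health."""
    _check_comparable(trace_ante, trace_post)
    a = dalys(trace_ante, weights, life_table, rate)
    p = dalys(trace_post, weights, life_table, rate)
    return a.daly - p.daly


def healthy_life_expectancy_gain(trace_ante: CohortTrace,
                                 trace_post: CohortTrace, weights) -> float:
    """Undiscounted gain in disability-adjusted years lived (post minus ante)."""
    _check_comparable(trace_ante, trace_post)
    w = _weight_vector(weights)
    alive = list(ALIVE_STATES)

    def _healthy_years(trace: CohortTrace) -> float:
        occ = trace.occupancy[:-1][:, alive]
        return float((occ @ (1.0 - w[alive])).sum())

    return _healthy_years(trace_post) - _healthy_years(trace_ante)
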