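"""Markov natural-history model of ARF/RHD with coverage-weighted transitions.

Nine states: WELL, a one-cycle first-episode ARF tunnel, RF remission, a
one-cycle recurrent-ARF tunnel, chronic RHD, severe RHD with heart failure,
chronic stroke/AF, and two absorbing death states (disease vs background).
Intervention coverage enters as a weighted average of the transition
probability with and without the intervention: primary prevention lowers the
first-ARF probability, secondary prevention the recurrence probability, and
valve surgery the heart-failure death probability.

Background mortality competes with disease transitions within a cycle: the
background death probability q(age) is applied first and the disease
transitions are distributed among survivors, which keeps every row
stochastic for any admissible parameter draw.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd

from .lifetable import LifeTable
from .parameters import ParameterSet, ScenarioConfig, ValidationError

DECAY_RATE = 0.1  # per year, exponential decay of ARF risk past its age window


class State(IntEnum):
    WELL = 0
    ARF_FIRST = 1
    RF_REMISSION = 2
    ARF_RECUR = 3
    RHD = 4
    SEVERE_HF = 5
    STROKE_AF = 6
    DEAD_DISEASE = 7
    DEAD_OTHER = 8


N_STATES = len(State)
ALIVE_STATES = tuple(s for s in State if s not in (State.DEAD_DISEASE, State.DEAD_OTHER))
ABSORBING_STATES = (State.DEAD_DISEASE, State.DEAD_OTHER)

#: Reference starting state of each intervention lever's cohort.
START_STATE_OF = {"PP": State.WELL, "SP": State.RF_REMISSION, "VS": State.RHD}


class ModelConstructionError(ValueError):
    """Transition probabilities out of a state compose to an invalid row."""


def _check_unit(value, name: str) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValidationError(f"{name} must lie in [0, 1], got {value}")


def weighted_transition(tp_on, tp_off, coverage):
    """Coverage-weighted average transition probability.

    ``c * tp_on + (1 - c) * tp_off``: the covered fraction experiences the
    probability under the intervention, the rest the untreated probability.
    """
    _check_unit(tp_on, "tp_on")
    _check_unit(tp_off, "tp_off")
    _check_unit(coverage, "coverage")
    return coverage * np.asarray(tp_on, dtype=float) + (1.0 - coverage) * np.asarray(tp_off, dtype=float)


def decayed_probability(tp0, delta_t):
    """Exponential decay of a baseline probability past its age window.

    ``tp_t = tp_0 * exp(-0.1 * delta_t)`` with ``delta_t`` in years.
    """
    _check_unit(tp0, "tp0")
    dt = np.asarray(delta_t, dtype=float)
    if np.any(dt < 0):
        raise ValidationError(f"delta_t must be >= 0, got {delta_t}")
    out = np.asarray(tp0, dtype=float) * np.exp(-DECAY_RATE * dt)
    if np.isscalar(tp0) and np.isscalar(delta_t):
        return float(out)
    return out


def effective_probability(tp_off, risk_reduction, coverage):
    """Intervention-modified transition probability at partial coverage.

    The covered fraction experiences ``tp_off * (1 - RR)``.
    """
    _check_unit(risk_reduction, "risk_reduction")
    tp_off = np.asarray(tp_off, dtype=float)
    return weighted_transition(tp_off * (1.0 - risk_reduction), tp_off, coverage)


def windowed_probability(base: float, window, decays: bool, ages) -> np.ndarray:
    """Age profile of a probability with an age window and optional decay.

    Zero before the window start, ``base`` inside the window, and (if
    ``decays``) exponentially decayed past the window end, else zero.
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    if window is None:
        return np.full_like(ages, float(base))
    a0, a1 = window
    out = np.zeros_like(ages)
    inside = (ages >= a0) & (ages <= a1)
    out[inside] = base
    after = ages > a1
    if decays and np.any(after):
        out[after] = decayed_probability(base, ages[after] - a1)
    return out


def build_transition_matrices(params: ParameterSet, life_table: LifeTable,
                              ages, coverage) -> np.ndarray:
    """One-cycle transition matrices for an array of ages.

    ``coverage`` maps lever name ("PP", "SP", "VS") to the coverage
    proportion in force.  Returns an array of shape ``(n_ages, 9, 9)`` whose
    rows are probability vectors.
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    if isinstance(coverage, (int, float)):
        coverage = {"PP": float(coverage), "SP": float(coverage), "VS": float(coverage)}
    for lever in ("PP", "SP", "VS"):
        _check_unit(coverage[lever], f"coverage[{lever}]")

    n = ages.size
    v = params.value

    est_first = params["arf_first_incidence"]
    p_first = effective_probability(
        windowed_probability(est_first.base, est_first.age_window,
                             est_first.decays_after_window, ages),
        v("rr_primary_prevention"), coverage["PP"])

    est_rec = params["arf_recurrence"]
    p_rec = effective_probability(
        windowed_probability(est_rec.base, est_rec.age_window,
                             est_rec.decays_after_window, ages),
        v("rr_secondary_prevention"), coverage["SP"])

    p_hf_death = float(effective_probability(
        v("hf_death"), v("rr_valve_surgery"), coverage["VS"]))

    cfr1, prog1 = v("arf_cfr_first"), v("rhd_progression_first")
    cfr2, prog2 = v("arf_cfr_recurrence"), v("rhd_progression_recurrence")
    p_hf, p_stroke = v("hf_progression"), v("stroke_incidence")
    p_stroke_death = v("stroke_death")
    p_hf_rem = v("hf_remission")

    D = np.zeros((n, N_STATES, N_STATES))
    S = State

    D[:, S.WELL, S.ARF_FIRST] = p_first
    D[:, S.WELL, S.WELL] = 1.0 - p_first

    # ARF tunnels: all mass exits each cycle.
    rem1 = 1.0 - cfr1 - prog1
    D[:, S.ARF_FIRST, S.DEAD_DISEASE] = cfr1
    D[:, S.ARF_FIRST, S.RHD] = prog1
    D[:, S.ARF_FIRST, S.RF_REMISSION] = rem1

    D[:, S.RF_REMISSION, S.ARF_RECUR] = p_rec
    D[:, S.RF_REMISSION, S.RF_REMISSION] = 1.0 - p_rec

    rem2 = 1.0 - cfr2 - prog2
    D[:, S.ARF_RECUR, S.DEAD_DISEASE] = cfr2
    D[:, S.ARF_RECUR, S.RHD] = prog2
    D[:, S.ARF_RECUR, S.RF_REMISSION] = rem2

    # Stroke acute mortality is applied on entry, so the chronic stroke state
    # carries no further disease mortality.
    D[:, S.RHD, S.SEVERE_HF] = p_hf
    D[:, S.RHD, S.STROKE_AF] = p_stroke * (1.0 - p_stroke_death)
    D[:, S.RHD, S.DEAD_DISEASE] = p_stroke * p_stroke_death
    D[:, S.RHD, S.RHD] = 1.0 - p_hf - p_stroke

    D[:, S.SEVERE_HF, S.DEAD_DISEASE] = p_hf_death
    D[:, S.SEVERE_HF, S.RHD] = p_hf_rem
    D[:, S.SEVERE_HF, S.SEVERE_HF] = 1.0 - p_hf_death - p_hf_rem

    D[:, S.STROKE_AF, S.STROKE_AF] = 1.0

    if np.any(D < -1e-15):
        bad = np.argwhere(np.min(D, axis=(0, 2)) < -1e-15)
        state = State(int(bad[0])).name if bad.size else "?"
        raise ModelConstructionError(
            f"competing transition probabilities out of state {state} exceed 1"
        )
    np.clip(D, 0.0, 1.0, out=D)

    # Compose with background mortality: q(age) first, disease among survivors.
    q = life_table.q_at(ages)
    M = D * (1.0 - q)[:, None, None]
    M[:, :, S.DEAD_OTHER] += q[:, None]
    for s in ABSORBING_STATES:
        M[:, s, :] = 0.0
        M[:, s, s] = 1.0

    sums = M.sum(axis=2)
    if not np.allclose(sums, 1.0, atol=1e-12, rtol=0.0):
        raise ModelConstructionError("transition matrix rows do not sum to 1")
    return M


def build_matrix(params: ParameterSet, life_table: LifeTable, age: float,
                 coverage) -> np.ndarray:
    """Single-age transition matrix; see :func:`build_transition_matrices`."""
    return build_transition_matrices(params, life_table, [age], coverage)[0]


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy of a reference cohort.

    ``occupancy`` has ``cycles + 1`` rows: row k is the distribution at the
    start of cycle k (row 0 is the initial distribution).  Rows 0..cycles-1
    represent years lived and accrue disability and state costs; deaths
    arriving in row k are attributed to cycle k.
    """

    occupancy: np.ndarray
    start_age: int
    label: str = ""

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        object.__setattr__(self, "occupancy", occ)
        if occ.ndim != 2 or occ.shape[1] != N_STATES:
            raise ValidationError(
                f"occupancy must be (cycles+1, {N_STATES}), got {occ.shape}"
            )
        if not np.allclose(occ.sum(axis=1), 1.0, atol=1e-10, rtol=0.0):
            raise ValidationError("cycle occupancies must sum to 1")
        for s in ABSORBING_STATES:
            if np.any(np.diff(occ[:, s]) < -1e-12):
                raise ValidationError(
                    f"absorbing-state occupancy must be non-decreasing ({State(s).name})"
                )

    @property
    def cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def ages(self) -> np.ndarray:
        return self.start_age + np.arange(self.occupancy.shape[0])

    def new_entries(self, state: State) -> np.ndarray:
        """Per-row new mass entering ``state`` (row 0 counts initial mass)."""
        col = self.occupancy[:, state]
        return np.diff(col, prepend=0.0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=[s.name for s in State])
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_cohort(params: ParameterSet, life_table: LifeTable,
               scenario: ScenarioConfig, coverage: float,
               label: str = "") -> CohortTrace:
    """Lifetime trace of the scenario's reference cohort at one coverage level.

    The cohort starts fully in the scenario's reference state at its start
    age and is propagated through the age-specific matrices for
    ``scenario.cycles`` one-year cycles.
    """
    _check_unit(coverage, "coverage")
    start_age = scenario.resolve_start_age(params)
    cov = scenario.coverage_map(coverage)
    ages = start_age + np.arange(scenario.cycles)
    matrices = build_transition_matrices(params, life_table, ages, cov)

    occ = np.zeros((scenario.cycles + 1, N_STATES))
    occ[0, START_STATE_OF[scenario.lever]] = 1.0
    for k in range(scenario.cycles):
        occ[k + 1] = occ[k] @ matrices[k]
    return CohortTrace(occupancy=occ, start_age=start_age, label=label)
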