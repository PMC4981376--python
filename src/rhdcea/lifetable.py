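"""Period life tables: background mortality and remaining life expectancy.

The model accepts a country life table (columns ``age,q``) or generates a
synthetic one matching a target life expectancy at birth, for settings like
the hypothetical country (e0 = 68 years) where no table is published.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import ValidationError

__all__ = ["LifeTable", "expectancy_from_mortality", "synth_life_table"]


def expectancy_from_mortality(q: np.ndarray) -> np.ndarray:
    """Remaining life expectancy per age from annual death probabilities.

    Deaths are assumed to occur mid-interval, so the year of death contributes
    half a survived year: ``e(a) = sum_{t>=1} prod_{k=a..a+t-1}(1-q_k) + 0.5``.
    Computed by the backward recurrence ``e(a) = (1-q_a)(1 + e(a+1) - 0.5) + 0.5``
    with ``e`` beyond the closing age equal to 0.5.
    """
    q = np.asarray(q, dtype=float)
    if q.ndim != 1 or q.size == 0:
        raise ValidationError("q must be a non-empty 1-D array")
    if np.any(q < 0) or np.any(q > 1):
        raise ValidationError("death probabilities must lie in [0, 1]")
    e = np.empty_like(q)
    nxt = 0.5
    for a in range(q.size - 1, -1, -1):
        nxt = (1.0 - q[a]) * (1.0 + nxt - 0.5) + 0.5
        e[a] = nxt
    return e


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed background mortality ``q`` and life expectancy ``e``."""

    q: np.ndarray
    e: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        e = np.asarray(self.e, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "e", e)
        if q.shape != e.shape or q.ndim != 1:
            raise ValidationError("q and e must be 1-D arrays of equal length")
        if q.size < 2:
            raise ValidationError("life table must cover at least ages 0..1")
        if np.any(q < 0) or np.any(q > 1):
            raise ValidationError("q(a) must lie in [0, 1] for every age")
        if q[-1] != 1.0:
            raise ValidationError("life table must close with q(A) = 1")
        if np.any(e < 0):
            raise ValidationError("life expectancy must be non-negative")
        # Allow the infant-mortality hump but forbid implausible jumps.
        if np.any(e[1:] >= e[:-1] + 1.0):
            raise ValidationError(
                "e(a+1) must be < e(a) + 1 (life expectancy rises faster than age)"
            )

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.q.size)

    @property
    def closing_age(self) -> int:
        return self.q.size - 1

    @classmethod
    def from_mortality(cls, q: np.ndarray) -> "LifeTable":
        q = np.asarray(q, dtype=float)
        return cls(q=q, e=expectancy_from_mortality(q))

    def q_at(self, age) -> np.ndarray:
        """Background mortality at (possibly beyond-table) ages, capped at A."""
        idx = np.minimum(np.asarray(age, dtype=int), self.closing_age)
        return self.q[idx]

    def e_at(self, age) -> np.ndarray:
        idx = np.minimum(np.asarray(age, dtype=int), self.closing_age)
        return self.e[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "q": self.q, "e": self.e})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path)
        if "q" not in df.columns:
            raise ValidationError("life table CSV must have a 'q' column")
        df = df.sort_values("age") if "age" in df.columns else df
        return cls.from_mortality(df["q"].to_numpy(dtype=float))


def synth_life_table(e0: float, closing_age: int = 100, *,
                     child_hazard: float = 0.0015,
                     gompertz_slope: float = 0.09,
                     tol: float = 0.01) -> LifeTable:
    """Synthesize a life table hitting a target life expectancy at birth.

    The hazard is a two-component schedule: a constant child/adult background
    hazard plus a Gompertz senescent term ``B * exp(slope * age)``.  The
    senescent level ``B`` is solved by bisection so the computed e(0) matches
    ``e0`` to within ``tol`` years.  Deterministic given its arguments.
    """
    if not (30 <= e0 <= 90):
        raise ValidationError(f"target e0 must lie in [30, 90] years, got {e0}")
    ages = np.arange(closing_age + 1, dtype=float)

    def _table(logB: float) -> np.ndarray:
        hazard = child_hazard + np.exp(logB) * np.exp(gompertz_slope * ages)
        q = 1.0 - np.exp(-hazard)
        q[-1] = 1.0
        return q

    def _e0(logB: float) -> float:
        return expectancy_from_mortality(_table(logB))[0]

    lo, hi = np.log(1e-10), np.log(1.0)  # senescent level bounds
    e_hi, e_lo = _e0(lo), _e0(hi)  # e0 decreases in B
    if not (e_lo - tol <= e0 <= e_hi + tol):
        raise ValidationError(
            f"target e0={e0} unreachable with this hazard family; achievable "
            f"range is [{e_lo:.1f}, {e_hi:.1f}] years"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        val = _e0(mid)
        if abs(val - e0) <= tol:
            return LifeTable.from_mortality(_table(mid))
        if val > e0:
            lo = mid
        else:
            hi = mid
    return LifeTable.from_mortality(_table(0.5 * (lo + hi)))
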