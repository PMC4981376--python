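"""Univariate (tornado) and probabilistic sensitivity analysis.

Distribution fitting follows method-of-moments conventions with the printed
low/high bounds read as 95% intervals (sd = (high - low) / (2 * 1.96)):

* probabilities and disability weights -> beta (uniform(low, high) fallback
  when the moments are infeasible);
* competing transitions out of one state -> a joint Dirichlet whose mean is
  the base shares (closed with the implicit remainder) and whose
  concentration matches the largest-variance member;
* proportional risk reductions -> lognormal on the relative-risk scale
  (median of 1 - RR equals 1 - base), samples clipped into (0, 1);
* ages and all costs -> gamma with mean equal to the base value.

Rows whose bounds collapse to the base value sample degenerately, so a PSA
over degenerate inputs reproduces the deterministic result.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cea import evaluate_scenario
from .lifetable import LifeTable
from .parameters import (CostItem, CostSet, ParameterEstimate, ParameterSet,
                         ScenarioConfig, ValidationError)

logger = logging.getLogger(__name__)

Z95 = 2 * 1.96  # width of a 95% normal interval in standard deviations
_EPS = 1e-9

__all__ = [
    "FittedDistribution", "PSAResult", "fit_distribution",
    "fit_dirichlet_group", "sample_inputs", "tornado", "run_psa",
]


@dataclass(frozen=True)
class FittedDistribution:
    """A fitted PSA distribution for one input (or one Dirichlet group)."""

    family: str
    names: tuple[str, ...]
    params: dict

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        """Draw samples; Dirichlet draws return one value per member name."""
        p = self.params
        if self.family == "degenerate":
            vals = np.asarray(p["values"], dtype=float)
            return vals if size is None else np.tile(vals, (size, 1))
        if self.family == "beta":
            return rng.beta(p["a"], p["b"], size=size)
        if self.family == "uniform":
            return rng.uniform(p["low"], p["high"], size=size)
        if self.family == "gamma":
            return rng.gamma(p["shape"], p["scale"], size=size)
        if self.family == "lognormal":
            # fitted on the 1 - RR (relative risk) scale
            rr = 1.0 - rng.lognormal(p["mu"], p["sigma"], size=size)
            return np.clip(rr, _EPS, 1.0 - _EPS)
        if self.family == "dirichlet":
            alpha = np.asarray(p["alpha"], dtype=float)
            pos = alpha > 0
            n = 1 if size is None else size
            out = np.zeros((n, alpha.size))
            out[:, pos] = rng.dirichlet(alpha[pos], size=n)
            # drop the implicit remainder column, keep named members
            out = out[:, : len(self.names)]
            return out[0] if size is None else out
        raise ValidationError(f"unknown fitted family {self.family!r}")


def _sd_from_bounds(low: float, high: float) -> float:
    return (high - low) / Z95


def fit_distribution(estimate: ParameterEstimate | CostItem) -> FittedDistribution:
    """Fit the PSA distribution of one (non-Dirichlet) input row."""
    base, low, high = estimate.base, estimate.low, estimate.high
    sd = _sd_from_bounds(low, high)
    name = (estimate.name,)
    family = getattr(estimate, "family", "gamma")  # costs are gamma-distributed

    if sd == 0:
        return FittedDistribution("degenerate", name, {"values": [base]})

    if family == "lognormal":
        # risk reductions, fitted on the relative-risk scale 1 - RR
        mu = np.log(1.0 - base)
        sigma = (np.log(1.0 - low) - np.log(1.0 - high)) / Z95
        return FittedDistribution("lognormal", name, {"mu": mu, "sigma": sigma})

    if family == "beta":
        var = sd * sd
        if base <= 0 or base >= 1 or var >= base * (1.0 - base):
            msg = (f"beta moments infeasible for {estimate.name!r} "
                   f"(mean {base}, sd {sd:.4g}); falling back to "
                   f"uniform({low}, {high})")
            logger.warning(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
            return FittedDistribution("uniform", name, {"low": low, "high": high})
        nu = base * (1.0 - base) / var - 1.0
        return FittedDistribution("beta", name,
                                  {"a": base * nu, "b": (1.0 - base) * nu})

    if family in ("gamma", "dirichlet"):
        # Dirichlet rows varied individually (tornado) use their marginal fit;
        # joint sampling goes through fit_dirichlet_group.
        if family == "dirichlet" and (base <= 0 or base >= 1):
            return FittedDistribution("degenerate", name, {"values": [base]})
        if base <= 0:
            return FittedDistribution("uniform", name, {"low": low, "high": high})
        var = sd * sd
        return FittedDistribution("gamma", name,
                                  {"shape": base * base / var,
                                   "scale": var / base})

    raise ValidationError(f"cannot fit family {family!r}")


def fit_dirichlet_group(estimates: Sequence[ParameterEstimate]) -> FittedDistribution:
    """Joint Dirichlet over competing transitions out of one state.

    The mean vector equals the base shares, closed with the implicit
    remainder (the stay probability); the concentration is chosen so the
    member with the largest method-of-moments variance matches that variance.
    Members with zero base share are structural zeros and stay exactly zero.
    """
    if not estimates:
        raise ValidationError("empty Dirichlet group")
    group = estimates[0].competing_group
    names = tuple(e.name for e in estimates)
    shares = np.array([e.base for e in estimates], dtype=float)
    total = shares.sum()
    if total > 1 + 1e-12:
        raise ValidationError(
            f"Dirichlet group {group!r}: base shares sum to {total:.6f} > 1 "
            "(no remainder mass left)"
        )
    remainder = max(0.0, 1.0 - total)
    mean = np.append(shares, remainder)

    variances = np.array([_sd_from_bounds(e.low, e.high) ** 2 for e in estimates])
    if np.all(variances == 0):
        return FittedDistribution("degenerate", names, {"values": shares})
    i = int(np.argmax(variances))
    p = shares[i]
    conc = p * (1.0 - p) / variances[i] - 1.0
    if conc <= 0:
        raise ValidationError(
            f"Dirichlet group {group!r}: member {names[i]!r} variance too "
            "large for a valid concentration"
        )
    return FittedDistribution("dirichlet", names, {"alpha": mean * conc})


def _build_sampler(params: ParameterSet, costs: CostSet):
    """Ordered list of fitted distributions covering every uncertain input."""
    fits: list[FittedDistribution] = []
    groups = params.groups()
    for gname in sorted(groups):
        members = sorted(groups[gname], key=lambda e: e.name)
        fits.append(fit_dirichlet_group(members))
    for name in sorted(params):
        if params[name].competing_group:
            continue
        fits.append(fit_distribution(params[name]))
    for name in sorted(costs):
        fits.append(fit_distribution(costs[name]))
    return fits


def sample_inputs(params: ParameterSet, costs: CostSet,
                  rng: np.random.Generator,
                  fits: Optional[list[FittedDistribution]] = None,
                  ) -> tuple[ParameterSet, CostSet, dict]:
    """One joint draw of every uncertain input.

    Returns the perturbed parameter and cost sets plus a flat name->value
    digest of the draw.
    """
    if fits is None:
        fits = _build_sampler(params, costs)
    draw: dict[str, float] = {}
    for fit in fits:
        values = np.atleast_1d(fit.sample(rng))
        for name, value in zip(fit.names, values):
            draw[name] = float(value)
    p_new = params.with_values({k: v for k, v in draw.items() if k in params})
    c_new = costs.with_values({k: v for k, v in draw.items() if k in costs})
    return p_new, c_new, draw


# --------------------------------------------------------------------------
# Tornado (one-way) analysis
# --------------------------------------------------------------------------

def tornado(params: ParameterSet, costs: CostSet, life_table: LifeTable,
            scenario: ScenarioConfig,
            discount_bounds: tuple[float, float] = (0.0, 0.06),
            top: int = 10) -> pd.DataFrame:
    """One-way sensitivity of a scenario's ICER to every input.

    Each input in turn is set to its low and high bound (all else at base)
    and the ICER recomputed; the impact is ``|ICER(high) - ICER(low)|``.
    The discount rate is included as an input, varied over
    ``discount_bounds``.  Dominance flags at an extreme are recorded in
    place of a number and such bars are ranked after all numeric ones.
    """
    import dataclasses

    def _icer_at(p: ParameterSet, c: CostSet, scen: ScenarioConfig):
        return evaluate_scenario(p, c, life_table, scen).icer

    rows = []
    for name in sorted(params):
        est = params[name]
        lo = _icer_at(params.with_values({name: est.low}), costs, scenario)
        hi = _icer_at(params.with_values({name: est.high}), costs, scenario)
        rows.append((name, est.low, est.high, lo, hi))
    for name in sorted(costs):
        item = costs[name]
        lo = _icer_at(params, costs.with_values({name: item.low}), scenario)
        hi = _icer_at(params, costs.with_values({name: item.high}), scenario)
        rows.append((name, item.low, item.high, lo, hi))
    r_lo, r_hi = discount_bounds
    lo = _icer_at(params, costs, dataclasses.replace(scenario, discount_rate=r_lo))
    hi = _icer_at(params, costs, dataclasses.replace(scenario, discount_rate=r_hi))
    rows.append(("discount_rate", r_lo, r_hi, lo, hi))

    out = []
    for name, low, high, ic_lo, ic_hi in rows:
        impact = (abs(ic_hi.value - ic_lo.value)
                  if ic_lo.defined and ic_hi.defined else np.nan)
        out.append({
            "input": name, "low": low, "high": high,
            "icer_low": ic_lo.value if ic_lo.defined else ic_lo.flag,
            "icer_high": ic_hi.value if ic_hi.defined else ic_hi.flag,
            "impact": impact,
        })
    df = pd.DataFrame(out)
    df = df.sort_values(["impact", "input"], ascending=[False, True],
                        na_position="last", kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["top10"] = df["rank"] <= top
    return df


# --------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# --------------------------------------------------------------------------

@dataclass
class PSAResult:
    """Per-trial incremental (cost, effect) pairs for each scenario."""

    samples: pd.DataFrame
    results: dict[str, np.ndarray]  # scenario name -> (n_trials, 2)
    seed: int
    n_trials: int
    resampled: int = 0

    @property
    def scenario_names(self) -> list[str]:
        return list(self.results)

    def summary(self) -> pd.DataFrame:
        """Mean incremental cost/effect, ICER of means, mean and 95% credible
        interval of the per-trial ICERs (trials with positive health gains)."""
        rows = []
        for name, arr in self.results.items():
            dc, de = arr[:, 0], arr[:, 1]
            pos = de > 0
            trial_icers = dc[pos] / de[pos]
            rows.append({
                "scenario": name,
                "mean_delta_cost": dc.mean(),
                "mean_dalys_averted": de.mean(),
                "icer_of_means": dc.mean() / de.mean() if de.mean() > 0 else np.nan,
                "icer_mean": trial_icers.mean() if trial_icers.size else np.nan,
                "icer_2.5%": (np.percentile(trial_icers, 2.5)
                              if trial_icers.size else np.nan),
                "icer_97.5%": (np.percentile(trial_icers, 97.5)
                               if trial_icers.size else np.nan),
                "trials_with_gain": int(pos.sum()),
            })
        return pd.DataFrame(rows)


def run_psa(params: ParameterSet, costs: CostSet, life_table: LifeTable,
            scenarios: Sequence[ScenarioConfig], n_trials: int = 2000,
            seed: int = 0) -> PSAResult:
    """Joint Monte-Carlo PSA over all model inputs.

    Per-trial random substreams are spawned from the root seed with a
    counter, so the sampled inputs of trial k do not depend on how many
    scenarios are evaluated.  Trials whose sampled inputs compose to an
    invalid transition matrix are resampled (the run aborts if more than 1%
    of trials need resampling).
    """
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    fits = _build_sampler(params, costs)
    child_seeds = np.random.SeedSequence(seed).spawn(n_trials)

    digests = []
    results = {s.name: np.empty((n_trials, 2)) for s in scenarios}
    resampled = 0
    for k in range(n_trials):
        rng = np.random.default_rng(child_seeds[k])
        for attempt in range(100):
            try:
                p_k, c_k, draw = sample_inputs(params, costs, rng, fits)
                for scen in scenarios:
                    res = evaluate_scenario(p_k, c_k, life_table, scen)
                    results[scen.name][k] = (res.delta_cost, res.delta_effect)
                break
            except (ValidationError, ValueError):
                resampled += 1
                logger.warning("PSA trial %d resampled (attempt %d)", k, attempt + 1)
        else:
            raise RuntimeError(f"PSA trial {k} failed after 100 resamples")
        digests.append(draw)
        if resampled > max(1, 0.01 * n_trials) + 1:
            raise RuntimeError(
                f"more than 1% of PSA trials required resampling ({resampled})"
            )
    samples = pd.DataFrame(digests)
    return PSAResult(samples=samples, results=results, seed=seed,
                     n_trials=n_trials, resampled=resampled)
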