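"""One-way (tornado) and probabilistic sensitivity analysis.

Cost parameters are sampled from gamma distributions, utilities and
probabilities from beta, and starting age and weight from (truncated)
normal distributions.  Hyperparameters come from the method of moments
using the printed mean and either a printed SD or SD = (upper - lower)
/ (2 * 1.96).  Re-runs share random-number streams (common random
numbers) so measured sensitivity reflects the parameters rather than
Monte-Carlo noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import StrategyOutcome, run_cohort
from .frontier import net_monetary_benefit, pairwise_icer
from .parameters import (
    LINE_UTILITY_KEYS,
    ModelConfig,
    ParameterError,
    Registry,
    STRATEGY_NAMES,
    build_strategies,
)

__all__ = [
    "ParamSpec",
    "default_param_specs",
    "sample_psa_draw",
    "one_way_tornado",
    "run_psa",
    "ceac",
    "DEFAULT_WTP_GRID",
]

DEFAULT_WTP_GRID = np.arange(0, 300_001, 10_000, dtype=float)


@dataclass(frozen=True)
class ParamSpec:
    """One perturbable input: dotted registry path, bounds, PSA law."""

    name: str
    path: str
    base: float
    low: float
    high: float
    dist: str = "fixed"  # gamma | beta | normal | fixed
    sd: float | None = None

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ParameterError(
                f"{self.name}: bounds must bracket the base value "
                f"({self.low} <= {self.base} <= {self.high} fails)"
            )
        if self.dist not in ("gamma", "beta", "normal", "fixed"):
            raise ParameterError(f"{self.name}: unknown distribution {self.dist!r}")
        if self.dist == "beta" and not 0.0 <= self.base <= 1.0:
            raise ParameterError(f"{self.name}: beta requires a unit-interval base")

    @property
    def sd_effective(self) -> float:
        return self.sd if self.sd is not None else (self.high - self.low) / (2 * 1.96)

    def draw(self, rng: np.random.Generator) -> float:
        m, s = self.base, self.sd_effective
        if self.dist == "fixed" or s <= 0 or m == 0 and self.dist != "normal":
            return m
        if self.dist == "gamma":
            shape = (m / s) ** 2
            return float(rng.gamma(shape, s**2 / m))
        if self.dist == "beta":
            feasible = m * (1.0 - m)
            if s**2 >= feasible:
                warnings.warn(
                    f"{self.name}: beta SD {s:.4g} infeasible for mean {m}; clamped"
                )
                s = 0.95 * feasible**0.5
            kappa = feasible / s**2 - 1.0
            return float(rng.beta(m * kappa, (1.0 - m) * kappa))
        # truncated normal: resample into the stated range
        for _ in range(100):
            v = rng.normal(m, s)
            if self.low <= v <= self.high:
                return float(v)
        return m


def _cost_bounds(entry: Mapping) -> tuple[float, float]:
    return float(entry["low"]), float(entry["high"])


def default_param_specs(registry: Registry) -> list[ParamSpec]:
    """The registry's sensitivity set: costs (gamma), utilities and AE
    probabilities (beta), weight and starting age (normal).  Parameters
    without a printed range vary by +/-20% of the base value."""
    raw = registry.raw
    specs: list[ParamSpec] = []
    for drug, entry in raw["drug_unit_cost"].items():
        lo, hi = _cost_bounds(entry)
        specs.append(
            ParamSpec(
                f"cost_{drug}", f"drug_unit_cost.{drug}.cost",
                float(entry["cost"]), lo, hi, "gamma",
            )
        )
    e = raw["bsc_cost_per_cycle"]
    specs.append(
        ParamSpec("cost_bsc", "bsc_cost_per_cycle.cost", float(e["cost"]),
                  *_cost_bounds(e), "gamma")
    )
    for key, entry in raw["ae_management_cost"].items():
        specs.append(
            ParamSpec(
                f"ae_cost_{key}", f"ae_management_cost.{key}.cost",
                float(entry["cost"]), *_cost_bounds(entry), "gamma",
            )
        )
    for fee in ("iv_first", "iv_sequential"):
        entry = raw["administration_cost"][fee]
        specs.append(
            ParamSpec(
                f"admin_{fee}", f"administration_cost.{fee}.cost",
                float(entry["cost"]), *_cost_bounds(entry), "gamma",
            )
        )
    for key in (*LINE_UTILITY_KEYS, "bsc"):
        entry = raw["utilities"][key]
        specs.append(
            ParamSpec(
                f"utility_{key}", f"utilities.{key}.value", float(entry["value"]),
                float(entry["low"]), float(entry["high"]), "beta",
                sd=float(entry["sd"]) if "sd" in entry else None,
            )
        )
    e = raw["disutility_ae"]
    specs.append(
        ParamSpec("disutility_ae", "disutility_ae.value", float(e["value"]),
                  float(e["low"]), float(e["high"]), "beta")
    )
    for block, tag in (("prob_discontinue_ae", "p_disc"), ("prob_death_ae", "p_death")):
        for key, value in raw[block].items():
            v = float(value)
            specs.append(
                ParamSpec(
                    f"{tag}_{key}", f"{block}.{key}", v,
                    0.8 * v, min(1.2 * v, 1.0), "beta" if v > 0 else "fixed",
                )
            )
    for name, key, dist in (("weight", "weight", "normal"),
                            ("start_age", "start_age", "normal")):
        entry = raw[key]
        specs.append(
            ParamSpec(
                name, f"{key}.value", float(entry["value"]),
                float(entry["low"]), float(entry["high"]), dist,
            )
        )
    return specs


def sample_psa_draw(
    specs: Sequence[ParamSpec], registry: Registry, rng: np.random.Generator
) -> Registry:
    """One joint parameter draw applied to the registry."""
    return registry.with_overrides({s.path: s.draw(rng) for s in specs})


def _pair_outcomes(
    registry: Registry,
    names: Sequence[str],
    n_patients: int,
    seed,
    config_kwargs: Mapping | None = None,
    build_kwargs: Mapping | None = None,
) -> dict[str, StrategyOutcome]:
    strategies = build_strategies(registry, **(build_kwargs or {}))
    config = registry.config(**(config_kwargs or {}))
    fees = registry.admin_fees()
    return {
        name: run_cohort(
            strategies[name],
            config,
            n_patients=n_patients,
            seed=seed,
            life_table=registry.life_table,
            iv_fees=fees,
        )
        for name in names
    }


def one_way_tornado(
    registry: Registry,
    comparison: tuple[str, str],
    *,
    n_patients: int = 2000,
    seed: int = 0,
    specs: Sequence[ParamSpec] | None = None,
    config_kwargs: Mapping | None = None,
) -> pd.DataFrame:
    """ICER of ``comparison[0]`` vs ``comparison[1]`` with each parameter
    pushed to its bounds, everything else at base; sorted by span."""
    if specs is None:
        specs = default_param_specs(registry)
    rows = []
    for spec in specs:
        icers = {}
        for side, value in (("low", spec.low), ("high", spec.high)):
            reg = registry.with_overrides({spec.path: value})
            oc = _pair_outcomes(reg, comparison, n_patients, seed, config_kwargs)
            icers[side] = pairwise_icer(oc[comparison[0]], oc[comparison[1]])
        rows.append(
            {
                "param": spec.name,
                "low": spec.low,
                "high": spec.high,
                "icer_low": icers["low"],
                "icer_high": icers["high"],
                "span": abs(icers["high"] - icers["low"]),
            }
        )
    df = pd.DataFrame.from_records(rows)
    return df.sort_values("span", ascending=False, kind="stable").reset_index(drop=True)


def run_psa(
    registry: Registry,
    strategies: Sequence[str] = STRATEGY_NAMES,
    n_iterations: int = 2000,
    n_patients: int = 5000,
    *,
    seed: int = 0,
    specs: Sequence[ParamSpec] | None = None,
    config_kwargs: Mapping | None = None,
) -> pd.DataFrame:
    """Per-iteration cohort outcomes under joint parameter draws.

    Within an iteration every strategy shares one patient-level stream
    (common random numbers); iteration i is reproducible from
    (seed, i) alone.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if specs is None:
        specs = default_param_specs(registry)
    rows = []
    for i in range(n_iterations):
        param_rng = np.random.default_rng(np.random.SeedSequence([seed, 91, i]))
        reg = sample_psa_draw(specs, registry, param_rng)
        outcomes = _pair_outcomes(
            reg, strategies, n_patients, [seed, 17, i], config_kwargs
        )
        for name, oc in outcomes.items():
            rows.append(
                {
                    "iteration": i,
                    "strategy": name,
                    "cost": oc.mean_cost,
                    "ly": oc.mean_ly,
                    "qaly": oc.mean_qaly,
                }
            )
    return pd.DataFrame.from_records(rows)


def ceac(
    psa_table: pd.DataFrame, wtp_grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves from a PSA table.

    At each willingness-to-pay value, a strategy's probability is the
    fraction of iterations in which it attains the maximal net monetary
    benefit; exact ties share the iteration equally.  Rows sum to one.
    """
    if psa_table.empty:
        raise ValueError("PSA table is empty")
    if wtp_grid is None:
        wtp_grid = DEFAULT_WTP_GRID
    cost = psa_table.pivot(index="iteration", columns="strategy", values="cost")
    qaly = psa_table.pivot(index="iteration", columns="strategy", values="qaly")
    strategies = list(cost.columns)
    probs = np.zeros((len(wtp_grid), len(strategies)))
    c = cost.to_numpy()
    q = qaly.to_numpy()
    for w, wtp in enumerate(wtp_grid):
        nmb = wtp * q - c
        best = nmb.max(axis=1, keepdims=True)
        winners = np.isclose(nmb, best)
        probs[w] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    return pd.DataFrame(probs, index=pd.Index(wtp_grid, name="wtp"), columns=strategies)
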