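"""Synthetic inputs with known ground truth.

Every stage of the pipeline can be exercised without external data:
digitized KM curves with risk tables (standing in for published trial
figures), Gompertz-shaped life tables, and random (cost, QALY) strategy
tables for stress-testing the frontier algorithm.  All generators are
pure functions of their seed and spec.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import StrategyOutcome
from .kmrecon import DigitizedKM, km_estimate
from .parameters import LifeTable
from .survival import PseudoIPD, SurvivalModel

__all__ = [
    "SyntheticKMSpec",
    "generate_km_fixture",
    "generate_life_table_fixture",
    "generate_toy_strategy_table",
]


@dataclass(frozen=True)
class SyntheticKMSpec:
    """Recipe for a synthetic digitized survival figure.

    ``censoring`` is "none", "uniform" (uniform on (0, censoring_param))
    or "exponential" (rate censoring_param per month).  The digitization
    grid mimics reading a published figure at ``grid_months`` spacing
    with risk-table anchors every ``risk_spacing_months``.
    """

    model: SurvivalModel
    n_patients: int
    censoring: str = "none"
    censoring_param: float | None = None
    grid_months: float = 1.0
    risk_spacing_months: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 10:
            raise ValueError("need at least 10 patients")
        if self.censoring not in ("none", "uniform", "exponential"):
            raise ValueError(f"unknown censoring mechanism {self.censoring!r}")
        if self.censoring != "none" and not (self.censoring_param or 0) > 0:
            raise ValueError("censoring_param must be positive")


def generate_km_fixture(spec: SyntheticKMSpec) -> tuple[DigitizedKM, PseudoIPD]:
    """Simulate from the generating model and digitize the resulting KM curve.

    Returns the digitized curve (grid-sampled step function plus risk
    table) together with the underlying truth IPD for oracle checks.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(1e-12, 1.0 - 1e-12, spec.n_patients)
    t_event = np.asarray(spec.model.isf(u))
    if spec.censoring == "none":
        obs, event = t_event, np.ones(spec.n_patients, dtype=int)
    else:
        if spec.censoring == "uniform":
            c = rng.uniform(0.0, spec.censoring_param, spec.n_patients)
        else:
            c = rng.exponential(1.0 / spec.censoring_param, spec.n_patients)
        obs = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
    truth = PseudoIPD(obs, event)

    t_max = float(obs.max())
    full = km_estimate(truth)
    grid = np.arange(0.0, t_max + spec.grid_months, spec.grid_months)
    grid = grid[grid <= t_max + 1e-9]
    if grid[-1] < t_max - 1e-9:  # keep the end of follow-up on the curve
        grid = np.append(grid, t_max)
    idx = np.searchsorted(full.times, grid, side="right") - 1
    surv = full.survival[np.maximum(idx, 0)]
    anchors = np.arange(0.0, t_max, spec.risk_spacing_months)
    if anchors.size < 2:
        anchors = np.array([0.0, t_max / 2.0])
    n_at_risk = np.array([(obs >= a - 1e-12).sum() for a in anchors])
    curve = DigitizedKM(
        times=grid,
        survival=surv,
        risk_times=anchors,
        n_at_risk=n_at_risk,
        n_total=spec.n_patients,
    )
    return curve, truth


def generate_life_table_fixture(
    base_q62: float, slope: float, age_min: int = 62, age_max: int = 100
) -> LifeTable:
    """Gompertz-shaped annual mortality: q(age) = min(1, q62 * slope^(age-62))."""
    if not 0.0 < base_q62 < 1.0:
        raise ValueError("base_q62 must lie in (0, 1)")
    if slope < 1.0:
        raise ValueError("slope must be >= 1")
    ages = np.arange(age_min, age_max + 1)
    q = np.minimum(1.0, base_q62 * slope ** (ages - 62))
    return LifeTable(ages, q)


def generate_toy_strategy_table(
    n_strategies: int, rng: np.random.Generator
) -> list[StrategyOutcome]:
    """Random (cost, QALY) tables spanning dominated, extendedly dominated
    and frontier configurations, for frontier stress tests."""
    if n_strategies < 2:
        raise ValueError("need at least two strategies")
    cost = rng.uniform(50_000.0, 600_000.0, n_strategies)
    qaly = rng.uniform(1.0, 4.0, n_strategies)
    return [
        StrategyOutcome(
            strategy=f"s{i:02d}",
            mean_cost=float(cost[i]),
            mean_ly=float(qaly[i] * 1.3),
            mean_qaly=float(qaly[i]),
            mean_ly_undiscounted=float(qaly[i] * 1.4),
            se_cost=0.0,
            se_ly=0.0,
            se_qaly=0.0,
            n_patients=0,
            seed=None,
        )
        for i in range(n_strategies)
    ]
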