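"""Scenario analyses as declarative overrides of the base configuration.

Four scenario families: (1) restricted time horizon (5/10/20 years);
(2) a fixed fraction of patients electing best supportive care instead
of next-line treatment when leaving first or second line; (3) nivolumab
or axitinib replacing cabozantinib as second-line therapy, with a
cross-substitution for strategies already using the replacement drug in
first line; (4) indication-specific pricing, a multiplicative cut to
the first-line nivolumab acquisition price.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .engine import StrategyOutcome, run_cohort
from .frontier import FrontierResult, compute_frontier, pairwise_icer
from .parameters import ParameterError, Registry, STRATEGY_NAMES, build_strategies

__all__ = ["ScenarioSpec", "ScenarioResult", "run_scenario"]


@dataclass(frozen=True)
class ScenarioSpec:
    """At most one scenario family active; everything else stays at base."""

    name: str
    time_horizon_years: float | None = None
    bsc_switch_fraction: float | None = None
    second_line_substitution: str | None = None
    first_line_nivolumab_price_multiplier: float | None = None

    def __post_init__(self) -> None:
        active = [
            v
            for v in (
                self.time_horizon_years,
                self.bsc_switch_fraction,
                self.second_line_substitution,
                self.first_line_nivolumab_price_multiplier,
            )
            if v is not None
        ]
        if len(active) > 1:
            raise ParameterError(
                f"scenario {self.name!r}: at most one override family per run"
            )
        if self.bsc_switch_fraction is not None and not (
            0.0 <= self.bsc_switch_fraction <= 1.0
        ):
            raise ParameterError("bsc_switch_fraction outside [0, 1]")
        if self.second_line_substitution not in (None, "nivolumab", "axitinib"):
            raise ParameterError(
                "second_line_substitution must be nivolumab or axitinib"
            )
        if (
            self.first_line_nivolumab_price_multiplier is not None
            and self.first_line_nivolumab_price_multiplier < 0
        ):
            raise ParameterError("price multiplier must be non-negative")


@dataclass(frozen=True)
class ScenarioResult:
    name: str
    outcomes: dict[str, StrategyOutcome]
    frontier: FrontierResult
    pair: tuple[str, str] | None
    pair_icer: float | None

    def report(self) -> pd.DataFrame:
        table = self.frontier.table.copy()
        table.insert(0, "scenario", self.name)
        return table


def run_scenario(
    spec: ScenarioSpec,
    registry: Registry,
    *,
    n_patients: int = 5000,
    seed: int = 0,
    strategies: Sequence[str] = STRATEGY_NAMES,
    pair: tuple[str, str] | None = None,
) -> ScenarioResult:
    """Apply the scenario's overrides, rerun the comparative analysis with
    the base seed, and report the frontier plus an optional paired ICER."""
    build_kwargs = {}
    if spec.second_line_substitution is not None:
        build_kwargs["second_line_substitution"] = spec.second_line_substitution
    if spec.first_line_nivolumab_price_multiplier is not None:
        build_kwargs["first_line_nivolumab_price_multiplier"] = (
            spec.first_line_nivolumab_price_multiplier
        )
    config_kwargs = {}
    if spec.time_horizon_years is not None:
        config_kwargs["time_horizon_years"] = spec.time_horizon_years
    if spec.bsc_switch_fraction is not None:
        config_kwargs["bsc_switch_fraction"] = spec.bsc_switch_fraction

    built = build_strategies(registry, **build_kwargs)
    config = registry.config(**config_kwargs)
    fees = registry.admin_fees()
    outcomes = {
        name: run_cohort(
            built[name],
            config,
            n_patients=n_patients,
            seed=seed,
            life_table=registry.life_table,
            iv_fees=fees,
        )
        for name in strategies
    }
    frontier = compute_frontier(list(outcomes.values()))
    icer = None
    if pair is not None:
        icer = pairwise_icer(outcomes[pair[0]], outcomes[pair[1]])
    return ScenarioResult(
        name=spec.name, outcomes=outcomes, frontier=frontier, pair=pair, pair_icer=icer
    )
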