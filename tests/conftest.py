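import numpy as np
import pytest

from rccsim import load_parameters
from rccsim.parameters import (
    BscSpec,
    DrugComponent,
    RegimenPhase,
    RegimenSpec,
    StrategySpec,
    TreatmentLineSpec,
)
from rccsim.survival import SurvivalModel


@pytest.fixture(scope="session")
def registry():
    return load_parameters()


@pytest.fixture(scope="session")
def strategies(registry):
    return registry.strategies()


@pytest.fixture(scope="session")
def base_config(registry):
    return registry.config()


@pytest.fixture(scope="session")
def iv_fees(registry):
    return registry.admin_fees()


def simple_regimen(cost_per_cycle: float) -> RegimenSpec:
    """A one-drug flat regimen costing ``cost_per_cycle`` per cycle."""
    return RegimenSpec(
        name="toy",
        phases=(
            RegimenPhase(
                components=(
                    DrugComponent(
                        drug="toy",
                        dosing_basis="flat",
                        dose_amount=100.0,
                        administrations_per_cycle=1,
                        unit_size=100.0,
                        unit_cost=cost_per_cycle,
                    ),
                ),
                iv_first=0,
                iv_sequential=0,
            ),
        ),
    )


def toy_strategy(
    name="toy",
    pfs_scale=10.0,
    pfs_shape=1.4,
    p_disc=0.1,
    p_death=0.01,
    utility=0.8,
    drug_cost=1000.0,
    ae_cost=500.0,
    bsc_scale=12.0,
    bsc_cost=800.0,
    bsc_utility=0.5,
) -> StrategySpec:
    """A three-line strategy with identical simple lines, for engine tests."""
    line = TreatmentLineSpec(
        name=name + "_line",
        pfs_model=SurvivalModel("loglogistic", pfs_shape, pfs_scale),
        p_discontinue_ae=p_disc,
        p_death_ae=p_death,
        regimen=simple_regimen(drug_cost),
        ae_management_cost=ae_cost,
        utility=utility,
    )
    return StrategySpec(
        name=name,
        lines=(line, line, line),
        bsc=BscSpec(
            os_model=SurvivalModel("loglogistic", 1.6, bsc_scale),
            cost_per_cycle=bsc_cost,
            utility=bsc_utility,
        ),
    )


def random_strategy(rng: np.random.Generator, name: str) -> StrategySpec:
    """A randomized but valid strategy for oracle-equivalence stress tests."""
    def rand_model():
        family = rng.choice(["weibull", "loglogistic", "lognormal", "exponential"])
        if family == "exponential":
            return SurvivalModel("exponential", float(rng.uniform(2.0, 12.0)))
        return SurvivalModel(
            family, float(rng.uniform(0.9, 2.5)), float(rng.uniform(4.0, 25.0))
        )

    lines = tuple(
        TreatmentLineSpec(
            name=f"{name}_l{i}",
            pfs_model=rand_model(),
            p_discontinue_ae=float(rng.uniform(0.0, 0.5)),
            p_death_ae=float(rng.uniform(0.0, 0.08)),
            regimen=simple_regimen(float(rng.uniform(500.0, 40_000.0))),
            ae_management_cost=float(rng.uniform(0.0, 8000.0)),
            utility=float(rng.uniform(0.55, 0.95)),
        )
        for i in range(3)
    )
    bsc = BscSpec(
        os_model=SurvivalModel(
            "loglogistic", float(rng.uniform(1.2, 2.2)), float(rng.uniform(6.0, 20.0))
        ),
        cost_per_cycle=float(rng.uniform(300.0, 3000.0)),
        utility=float(rng.uniform(0.35, 0.6)),
    )
    return StrategySpec(name=name, lines=lines, bsc=bsc)
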