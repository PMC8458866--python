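"""Per-cycle and per-event direct costs (2021 USD, payer perspective).

Four components: drug acquisition, IV administration fees, one-off
adverse-event management on line entry, and best-supportive-care cost
per cycle.  Weight-based IV doses round *up* to whole billing units (no
vial sharing); oral drugs are costed per day on drug at the printed unit
strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .parameters import (
    BscSpec,
    DrugComponent,
    ParameterError,
    RegimenSpec,
    TreatmentLineSpec,
)

__all__ = [
    "CostBreakdown",
    "component_cost_per_cycle",
    "drug_cost_per_cycle",
    "administration_cost_per_cycle",
    "ae_management_cost",
    "bsc_cost_per_cycle",
    "line_cycle_cost",
]

IV_FIRST_FEE = 148.3  # default CMS fee, USD; overridden from the registry
IV_SEQUENTIAL_FEE = 71.88


@dataclass(frozen=True)
class CostBreakdown:
    drug: float = 0.0
    administration: float = 0.0
    ae_management: float = 0.0
    bsc: float = 0.0

    def __post_init__(self) -> None:
        for name in ("drug", "administration", "ae_management", "bsc"):
            if getattr(self, name) < 0:
                raise ParameterError(f"cost component {name} must be >= 0")

    @property
    def total(self) -> float:
        return self.drug + self.administration + self.ae_management + self.bsc


def component_cost_per_cycle(component: DrugComponent, weight_kg: float) -> float:
    """Billing units consumed per cycle times unit cost for one drug."""
    if weight_kg <= 0:
        raise ParameterError("weight must be positive")
    if component.dosing_basis == "flat":
        dose_mg = component.dose_amount
    elif component.dosing_basis == "per_kg":
        dose_mg = component.dose_amount * weight_kg
    elif component.dosing_basis == "oral_daily":
        dose_mg = component.dose_amount
    else:  # pragma: no cover - guarded in DrugComponent
        raise ParameterError(f"unknown dosing basis {component.dosing_basis!r}")
    units = max(1, math.ceil(dose_mg / component.unit_size - 1e-9))
    return units * component.administrations_per_cycle * component.unit_cost


def drug_cost_per_cycle(
    line: TreatmentLineSpec, weight_kg: float, cycle_in_line: int = 0
) -> float:
    """Acquisition cost of the line's regimen for one 42-day cycle."""
    phase = line.regimen.phase_at(cycle_in_line)
    return sum(component_cost_per_cycle(c, weight_kg) for c in phase.components)


def administration_cost_per_cycle(
    regimen: RegimenSpec,
    cycle_in_line: int = 0,
    iv_first_fee: float = IV_FIRST_FEE,
    iv_sequential_fee: float = IV_SEQUENTIAL_FEE,
) -> float:
    """Infusion fees for one cycle; zero for all-oral regimens."""
    phase = regimen.phase_at(cycle_in_line)
    return phase.iv_first * iv_first_fee + phase.iv_sequential * iv_sequential_fee


def ae_management_cost(line: TreatmentLineSpec) -> float:
    """One-time adverse-event management charge, applied on line entry."""
    return line.ae_management_cost


def bsc_cost_per_cycle(bsc: BscSpec) -> float:
    return bsc.cost_per_cycle


def line_cycle_cost(
    line: TreatmentLineSpec,
    weight_kg: float,
    cycle_in_line: int = 0,
    iv_first_fee: float = IV_FIRST_FEE,
    iv_sequential_fee: float = IV_SEQUENTIAL_FEE,
) -> CostBreakdown:
    """Drug plus administration cost for one cycle of an active line."""
    return CostBreakdown(
        drug=drug_cost_per_cycle(line, weight_kg, cycle_in_line),
        administration=administration_cost_per_cycle(
            line.regimen, cycle_in_line, iv_first_fee, iv_sequential_fee
        ),
    )
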