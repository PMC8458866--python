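"""Parameter registry: survival models, adverse-event probabilities,
unit costs, utilities, regimens, treatment sequences and the background
life table.

The registry is loaded from a structured YAML file shipped with the
package (``data/parameters.yaml``) together with a tab-separated
life-table fixture, and every other module reads from it.  Overrides are
addressed by dotted paths into the raw document, which is what the
sensitivity- and scenario-analysis machinery perturbs.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .survival import SurvivalModel

__all__ = [
    "ParameterError",
    "annual_to_cycle_prob",
    "LifeTable",
    "DrugComponent",
    "RegimenPhase",
    "RegimenSpec",
    "TreatmentLineSpec",
    "BscSpec",
    "StrategySpec",
    "ModelConfig",
    "Registry",
    "load_parameters",
    "build_strategies",
    "STRATEGY_NAMES",
    "LINE_UTILITY_KEYS",
]

STRATEGY_NAMES = (
    "lenvatinib_pembrolizumab",
    "nivolumab_cabozantinib",
    "nivolumab_ipilimumab",
    "pembrolizumab_axitinib",
    "avelumab_axitinib",
    "sunitinib",
)

LINE_UTILITY_KEYS = ("line1", "line2", "line3")


class ParameterError(ValueError):
    """A registry entry is missing or out of range; the message names it."""


def annual_to_cycle_prob(q_annual, cycle_days: float) -> float:
    """Convert an annual death probability to a ``cycle_days``-day one.

    Assumes a constant hazard within the year:
    ``1 - (1 - q)**(cycle_days/365.25)``.  ``q = 1`` maps to certain
    death within the cycle.
    """
    q = np.asarray(q_annual, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ParameterError(f"q_annual must lie in [0, 1], got {q_annual}")
    if cycle_days <= 0:
        raise ParameterError("cycle_days must be positive")
    out = -np.expm1((cycle_days / 365.25) * np.log1p(-np.minimum(q, 1.0 - 1e-15)))
    out = np.where(q >= 1.0, 1.0, out)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities q(age); lookups clamp to the table span."""

    age: np.ndarray
    q_annual: np.ndarray

    def __post_init__(self) -> None:
        age = np.asarray(self.age, dtype=int)
        q = np.asarray(self.q_annual, dtype=float)
        if age.shape != q.shape or age.ndim != 1 or age.size == 0:
            raise ParameterError("life table must be parallel 1-d age/q arrays")
        if np.any(np.diff(age) != 1):
            raise ParameterError("life-table ages must be consecutive integers")
        if np.any((q < 0) | (q > 1)):
            raise ParameterError("life-table q_annual must lie in [0, 1]")
        object.__setattr__(self, "age", age)
        object.__setattr__(self, "q_annual", q)

    def q_at(self, age):
        """q(age) with fractional ages floored and out-of-span ages clamped."""
        idx = np.clip(
            np.floor(np.asarray(age, dtype=float)).astype(int) - self.age[0],
            0,
            self.age.size - 1,
        )
        out = self.q_annual[idx]
        return out if np.ndim(age) else float(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.age, "q_annual": self.q_annual})

    @classmethod
    def read_tsv(cls, path) -> "LifeTable":
        df = pd.read_csv(path, sep="\t")
        return cls(df["age"].to_numpy(), df["q_annual"].to_numpy())

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class DrugComponent:
    drug: str
    dosing_basis: str  # flat | per_kg | oral_daily
    dose_amount: float  # mg per administration (flat), mg/kg (per_kg), mg/day (oral)
    administrations_per_cycle: float  # administrations (IV) or days on drug (oral)
    unit_size: float  # mg per billing unit
    unit_cost: float  # USD per billing unit

    def __post_init__(self) -> None:
        if self.dosing_basis not in ("flat", "per_kg", "oral_daily"):
            raise ParameterError(
                f"{self.drug}: unknown dosing basis {self.dosing_basis!r}"
            )
        for name in ("dose_amount", "administrations_per_cycle", "unit_size"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{self.drug}.{name} must be positive")
        if self.unit_cost < 0:
            raise ParameterError(f"{self.drug}.unit_cost must be non-negative")


@dataclass(frozen=True)
class RegimenPhase:
    components: tuple[DrugComponent, ...]
    iv_first: int
    iv_sequential: int
    cycles: int | None = None  # None = until leaving the line


@dataclass(frozen=True)
class RegimenSpec:
    name: str
    phases: tuple[RegimenPhase, ...]
    stop_rule: int | None = None  # optional max treatment duration, cycles

    def phase_at(self, cycle_in_line: int) -> RegimenPhase:
        offset = 0
        for phase in self.phases:
            if phase.cycles is None or cycle_in_line < offset + phase.cycles:
                return phase
            offset += phase.cycles
        return self.phases[-1]


@dataclass(frozen=True)
class TreatmentLineSpec:
    name: str
    pfs_model: SurvivalModel
    p_discontinue_ae: float
    p_death_ae: float
    regimen: RegimenSpec
    ae_management_cost: float
    utility: float

    def __post_init__(self) -> None:
        for attr in ("p_discontinue_ae", "p_death_ae"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{self.name}.{attr}={v} outside [0, 1]")
        if self.p_discontinue_ae + self.p_death_ae > 1.0:
            raise ParameterError(
                f"{self.name}: p_discontinue_ae + p_death_ae exceeds 1"
            )
        if not 0.0 <= self.utility <= 1.0:
            raise ParameterError(f"{self.name}.utility={self.utility} outside [0, 1]")
        if self.ae_management_cost < 0:
            raise ParameterError(f"{self.name}.ae_management_cost must be >= 0")


@dataclass(frozen=True)
class BscSpec:
    os_model: SurvivalModel
    cost_per_cycle: float
    utility: float

    def __post_init__(self) -> None:
        if self.cost_per_cycle < 0:
            raise ParameterError("bsc.cost_per_cycle must be >= 0")
        if not 0.0 <= self.utility <= 1.0:
            raise ParameterError(f"bsc.utility={self.utility} outside [0, 1]")


@dataclass(frozen=True)
class StrategySpec:
    name: str
    lines: tuple[TreatmentLineSpec, TreatmentLineSpec, TreatmentLineSpec]
    bsc: BscSpec


@dataclass(frozen=True)
class ModelConfig:
    """Run-level settings: cycle, discounting, horizon, cohort size."""

    cycle_days: float = 42.0
    month_days: float = 30.4375
    discount_rate: float = 0.03
    start_age: float = 62.0
    max_age: float = 100.0
    weight_kg: float = 70.0
    wtp: float = 100_000.0
    ae_disutility: float = 0.157
    n_patients: int = 5000
    seed: int = 0
    time_horizon_years: float | None = None  # None = lifetime (to max_age)
    bsc_switch_fraction: float = 0.0  # scenario 2 switch probability
    apply_entry_disutility: bool = True
    # what AE discontinuation does: "advance" moves the patient to the next
    # line immediately; "stop_drug" ends drug exposure, cost and
    # treatment-related mortality but leaves the patient progression-free
    # on the line's PFS clock until progression
    discontinuation_mode: str = "advance"

    def __post_init__(self) -> None:
        if self.discontinuation_mode not in ("stop_drug", "advance"):
            raise ParameterError(
                "discontinuation_mode must be 'stop_drug' or 'advance'"
            )
        if self.cycle_days <= 0:
            raise ParameterError("cycle_days must be positive")
        if self.discount_rate < 0:
            raise ParameterError("discount_rate must be >= 0")
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        if not 0.0 <= self.bsc_switch_fraction <= 1.0:
            raise ParameterError("bsc_switch_fraction outside [0, 1]")

    @property
    def cycle_months(self) -> float:
        return self.cycle_days / self.month_days

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / 365.25

    @property
    def n_cycles(self) -> int:
        horizon_years = (
            self.max_age - self.start_age
            if self.time_horizon_years is None
            else min(self.time_horizon_years, self.max_age - self.start_age)
        )
        return max(1, int(math.floor(horizon_years / self.cycle_years)))


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------


def _require(raw: Mapping[str, Any], *path: str):
    node: Any = raw
    for key in path:
        if not isinstance(node, Mapping) or key not in node:
            raise ParameterError(f"missing parameter {'.'.join(path)!r}")
        node = node[key]
    return node


@dataclass(frozen=True)
class Registry:
    """The full input registry plus the background-mortality life table."""

    raw: dict[str, Any]
    life_table: LifeTable

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.raw, sort_keys=False, default_flow_style=False)
        )

    def with_overrides(self, overrides: Mapping[str, float]) -> "Registry":
        """Return a copy with dotted-path leaves replaced, e.g.
        ``{"drug_unit_cost.sunitinib.cost": 700.0}``."""
        raw = copy.deepcopy(self.raw)
        for dotted, value in overrides.items():
            parts = dotted.split(".")
            node = raw
            for key in parts[:-1]:
                if key not in node:
                    raise ParameterError(f"unknown parameter path {dotted!r}")
                node = node[key]
            if parts[-1] not in node:
                raise ParameterError(f"unknown parameter path {dotted!r}")
            node[parts[-1]] = value
        return Registry(raw=raw, life_table=self.life_table)

    # -- typed accessors ----------------------------------------------------
    def config(self, **kwargs) -> ModelConfig:
        c = _require(self.raw, "config")
        base = dict(
            cycle_days=float(c["cycle_days"]),
            month_days=float(c["month_days"]),
            discount_rate=float(c["discount_rate"]),
            start_age=float(_require(self.raw, "start_age", "value")),
            max_age=float(c["max_age"]),
            weight_kg=float(_require(self.raw, "weight", "value")),
            wtp=float(c["wtp"]),
            ae_disutility=float(_require(self.raw, "disutility_ae", "value")),
        )
        base.update(kwargs)
        return ModelConfig(**base)

    def survival_model(self, key: str) -> SurvivalModel:
        entry = _require(self.raw, "survival", key)
        family = entry.get("family")
        if family not in ("exponential", "weibull", "lognormal", "loglogistic"):
            raise ParameterError(f"survival.{key}: unknown family {family!r}")
        exp_as = _require(self.raw, "config").get(
            "exponential_parameter", "mean_months"
        )
        try:
            return SurvivalModel(
                family=family,
                shape=float(entry["shape"]),
                scale=float(entry["scale"]) if "scale" in entry else None,
                label=key,
                exp_as=exp_as,
            )
        except (KeyError, ValueError) as exc:
            raise ParameterError(f"survival.{key}: {exc}") from exc

    def regimen(
        self, key: str, *, unit_cost_multipliers: Mapping[str, float] | None = None
    ) -> RegimenSpec:
        entry = _require(self.raw, "regimens", key)
        phases = []
        for phase in entry["phases"]:
            comps = []
            for c in phase["components"]:
                drug = c["drug"]
                cost_entry = _require(self.raw, "drug_unit_cost", drug)
                unit_cost = float(cost_entry["cost"])
                if unit_cost_multipliers and drug in unit_cost_multipliers:
                    unit_cost *= unit_cost_multipliers[drug]
                basis = c["basis"]
                if basis == "oral_daily":
                    dose, admin = float(c["dose_mg"]), float(c["days"])
                elif basis == "flat":
                    dose, admin = float(c["dose_mg"]), float(c["administrations"])
                elif basis == "per_kg":
                    dose = float(c["dose_mg_per_kg"])
                    admin = float(c["administrations"])
                else:
                    raise ParameterError(
                        f"regimens.{key}: unknown dosing basis {basis!r}"
                    )
                comps.append(
                    DrugComponent(
                        drug=drug,
                        dosing_basis=basis,
                        dose_amount=dose,
                        administrations_per_cycle=admin,
                        unit_size=float(cost_entry["unit_mg"]),
                        unit_cost=unit_cost,
                    )
                )
            phases.append(
                RegimenPhase(
                    components=tuple(comps),
                    iv_first=int(phase.get("iv_first", 0)),
                    iv_sequential=int(phase.get("iv_sequential", 0)),
                    cycles=phase.get("cycles"),
                )
            )
        return RegimenSpec(name=key, phases=tuple(phases))

    def admin_fees(self) -> tuple[float, float]:
        return (
            float(_require(self.raw, "administration_cost", "iv_first", "cost")),
            float(_require(self.raw, "administration_cost", "iv_sequential", "cost")),
        )

    def treatment_line(
        self,
        drug_key: str,
        line_index: int,
        *,
        unit_cost_multipliers: Mapping[str, float] | None = None,
    ) -> TreatmentLineSpec:
        utility = float(
            _require(self.raw, "utilities", LINE_UTILITY_KEYS[line_index], "value")
        )
        return TreatmentLineSpec(
            name=drug_key,
            pfs_model=self.survival_model(drug_key),
            p_discontinue_ae=float(_require(self.raw, "prob_discontinue_ae", drug_key)),
            p_death_ae=float(_require(self.raw, "prob_death_ae", drug_key)),
            regimen=self.regimen(drug_key, unit_cost_multipliers=unit_cost_multipliers),
            ae_management_cost=float(
                _require(self.raw, "ae_management_cost", drug_key, "cost")
            ),
            utility=utility,
        )

    def bsc(self) -> BscSpec:
        return BscSpec(
            os_model=self.survival_model("bsc_os"),
            cost_per_cycle=float(_require(self.raw, "bsc_cost_per_cycle", "cost")),
            utility=float(_require(self.raw, "utilities", "bsc", "value")),
        )

    def strategies(self, **build_kwargs) -> dict[str, StrategySpec]:
        return build_strategies(self, **build_kwargs)


def _first_line_drugs(registry: Registry, strategy_name: str) -> set[str]:
    entry = _require(registry.raw, "regimens", strategy_name)
    return {c["drug"] for phase in entry["phases"] for c in phase["components"]}


def build_strategies(
    registry: Registry,
    *,
    second_line_substitution: str | None = None,
    first_line_nivolumab_price_multiplier: float = 1.0,
) -> dict[str, StrategySpec]:
    """Construct the six treatment-sequence strategies from the registry.

    ``second_line_substitution`` ("nivolumab" or "axitinib") replaces
    cabozantinib in second line, with the cross-rule that a strategy
    already containing the substitute in its first-line regimen receives
    the alternative drug instead.  The price multiplier applies only to
    nivolumab acquisition cost inside the nivolumab+cabozantinib
    first-line regimen (indication-specific pricing scenario).
    """
    if second_line_substitution not in (None, "nivolumab", "axitinib"):
        raise ParameterError(
            f"second_line_substitution must be nivolumab or axitinib, "
            f"got {second_line_substitution!r}"
        )
    sequences = _require(registry.raw, "sequences")
    bsc = registry.bsc()
    out: dict[str, StrategySpec] = {}
    for name in STRATEGY_NAMES:
        if name not in sequences:
            raise ParameterError(f"missing sequence for strategy {name!r}")
        seq = list(sequences[name])
        if len(seq) != 3:
            raise ParameterError(f"sequences.{name} must list exactly 3 lines")
        if second_line_substitution is not None and seq[1] == "cabozantinib":
            other = "axitinib" if second_line_substitution == "nivolumab" else "nivolumab"
            if second_line_substitution in _first_line_drugs(registry, name):
                seq[1] = other
            else:
                seq[1] = second_line_substitution
        lines = []
        for i, drug_key in enumerate(seq):
            mult = None
            if (
                i == 0
                and name == "nivolumab_cabozantinib"
                and first_line_nivolumab_price_multiplier != 1.0
            ):
                mult = {"nivolumab": first_line_nivolumab_price_multiplier}
            lines.append(
                registry.treatment_line(drug_key, i, unit_cost_multipliers=mult)
            )
        out[name] = StrategySpec(name=name, lines=tuple(lines), bsc=bsc)
    return out


def _data_path(filename: str) -> Path:
    return Path(resources.files("rccsim").joinpath("data", filename))  # type: ignore[arg-type]


def load_parameters(
    config_file: str | Path | None = None,
    life_table_file: str | Path | None = None,
) -> Registry:
    """Load the registry (defaults to the packaged fixtures) and validate it
    by constructing every strategy once."""
    cfg_path = Path(config_file) if config_file else _data_path("parameters.yaml")
    lt_path = (
        Path(life_table_file)
        if life_table_file
        else _data_path("life_table_us2017_synthetic.tsv")
    )
    raw = yaml.safe_load(cfg_path.read_text())
    if not isinstance(raw, dict):
        raise ParameterError(f"parameter file {cfg_path} did not parse to a mapping")
    registry = Registry(raw=raw, life_table=LifeTable.read_tsv(lt_path))
    registry.config()
    build_strategies(registry)  # surfaces missing/out-of-range entries eagerly
    return registry
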