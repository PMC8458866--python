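"""Patient-level microsimulation of the treatment sequences.

Each simulated patient moves through first-, second- and third-line
treatment and then best supportive care (BSC) on 42-day cycles.  Within
a cycle events are resolved in a fixed order: background death (life
table), adverse-event death, progression (conditional survival of the
line's PFS model), adverse-event discontinuation.  Progression and
discontinuation both advance the patient to the next line; leaving third
line, and dying in BSC via its overall-survival model, end the sequence.
Costs and quality-adjusted time are accrued at cycle start for the phase
occupied and discounted at the annual rate; events take effect at cycle
end (no half-cycle correction), so the cycle in which a patient dies is
charged in full.

Discontinuation semantics are switchable (``ModelConfig.discontinuation_mode``).
Under the default ``stop_drug`` mode a discontinuing patient stays in the
line's progression-free state — utility and the PFS clock continue — but
drug acquisition, administration cost and treatment-related mortality
stop; the next line begins at progression.  Under ``advance`` mode
discontinuation moves the patient to the next line immediately.

The printed adverse-event probabilities are cumulative over a whole
treatment line; they are converted to constant per-cycle hazards
calibrated so the cumulative incidence over the line's median PFS equals
the printed value.

``run_cohort`` is vectorised over patients but keeps one uniform stream
per patient, derived from (master seed, patient index), so results do
not depend on execution order or batch size.  ``cohort_expectation`` is
the deterministic oracle: it propagates the full probability mass over
(phase, time-in-phase) with the same per-cycle probabilities and no
random numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from . import costing
from .parameters import (
    LifeTable,
    ModelConfig,
    StrategySpec,
    annual_to_cycle_prob,
    load_parameters,
)
from .survival import SurvivalModel

__all__ = [
    "PHASE_NAMES",
    "StrategyOutcome",
    "PatientTrajectory",
    "CompiledStrategy",
    "compile_strategy",
    "patient_uniforms",
    "simulate_patient",
    "run_cohort",
    "cohort_expectation",
]

PHASE_NAMES = ("line1", "line2", "line3", "bsc", "dead")
_N_CHANNELS = 5  # background death, AE death, progression/OS, discontinuation, BSC switch


@dataclass(frozen=True)
class StrategyOutcome:
    """Cohort means for one strategy; LY and QALY are discounted."""

    strategy: str
    mean_cost: float
    mean_ly: float
    mean_qaly: float
    mean_ly_undiscounted: float
    se_cost: float
    se_ly: float
    se_qaly: float
    n_patients: int
    seed: int | None


@dataclass(frozen=True)
class PatientTrajectory:
    """Per-cycle record of one simulated patient."""

    records: pd.DataFrame  # cycle, phase, cost, qaly, ly (cost/qaly discounted)
    total_cost: float
    total_qaly: float
    total_ly: float  # discounted
    total_ly_undiscounted: float

    def write_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def _per_cycle_hazard(p_cumulative: float, model: SurvivalModel, dt_months: float) -> float:
    """Constant per-cycle hazard whose cumulative incidence over the
    line's median PFS reproduces the printed cumulative probability."""
    if p_cumulative <= 0.0:
        return 0.0
    if p_cumulative >= 1.0:
        return 1.0
    median_cycles = max(model.median() / dt_months, 1.0)
    return -math.expm1(math.log1p(-p_cumulative) / median_cycles)


@dataclass(frozen=True)
class CompiledStrategy:
    """Per-cycle probability and cost tables for one strategy/config pair."""

    name: str
    n_cycles: int
    dt_years: float
    discount: np.ndarray       # (n_cycles,) discount factor at cycle start
    p_bg: np.ndarray           # (n_cycles,) background death per cycle
    event_prob: np.ndarray     # (4, n_cycles) progression (lines) / death (BSC) by time-in-phase
    h_death: np.ndarray        # (5,) per-cycle AE death hazard by phase
    h_disc: np.ndarray         # (5,) per-cycle AE discontinuation hazard by phase
    cost_table: np.ndarray     # (4, n_cycles) cycle cost by phase and time-in-phase
    entry_cost: np.ndarray     # (5,) one-off cost on phase entry
    utility: np.ndarray        # (5,)
    entry_disutility: np.ndarray  # (5,) utility decrement in the entry cycle
    bsc_switch_fraction: float
    disc_advances: bool        # True: discontinuation moves to the next line


def compile_strategy(
    strategy: StrategySpec,
    config: ModelConfig,
    life_table: LifeTable | None = None,
    iv_fees: tuple[float, float] | None = None,
) -> CompiledStrategy:
    if life_table is None:
        life_table = _default_life_table()
    iv_first, iv_seq = iv_fees if iv_fees is not None else (
        costing.IV_FIRST_FEE,
        costing.IV_SEQUENTIAL_FEE,
    )
    n_cycles = config.n_cycles
    dt_m, dt_y = config.cycle_months, config.cycle_years
    cycles = np.arange(n_cycles)
    discount = (1.0 + config.discount_rate) ** (-(cycles * dt_y))
    ages = config.start_age + cycles * dt_y
    p_bg = annual_to_cycle_prob(life_table.q_at(ages), config.cycle_days)

    event_prob = np.zeros((4, n_cycles))
    cost_table = np.zeros((4, n_cycles))
    h_death = np.zeros(5)
    h_disc = np.zeros(5)
    entry_cost = np.zeros(5)
    utility = np.zeros(5)
    entry_dis = np.zeros(5)

    t_grid = np.arange(n_cycles + 1) * dt_m
    for p, line in enumerate(strategy.lines):
        s = np.asarray(line.pfs_model.sf(t_grid))
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(s[:-1] > 0, 1.0 - s[1:] / np.where(s[:-1] > 0, s[:-1], 1.0), 1.0)
        event_prob[p] = np.clip(q, 0.0, 1.0)
        h_death[p] = _per_cycle_hazard(line.p_death_ae, line.pfs_model, dt_m)
        h_disc[p] = _per_cycle_hazard(line.p_discontinue_ae, line.pfs_model, dt_m)
        for k in range(n_cycles):
            if line.regimen.stop_rule is not None and k >= line.regimen.stop_rule:
                break
            bd = costing.line_cycle_cost(
                line, config.weight_kg, k, iv_first, iv_seq
            )
            cost_table[p, k] = bd.total
            # regimens are phase-constant after any induction block; stop
            # recomputing once the steady phase repeats
            if k >= 1 and cost_table[p, k] == cost_table[p, k - 1] and (
                line.regimen.phase_at(k) is line.regimen.phase_at(n_cycles)
                and line.regimen.stop_rule is None
            ):
                cost_table[p, k:] = cost_table[p, k]
                break
        entry_cost[p] = line.ae_management_cost
        utility[p] = line.utility
        if config.apply_entry_disutility:
            entry_dis[p] = config.ae_disutility * min(
                line.p_discontinue_ae + line.p_death_ae, 1.0
            )

    s = np.asarray(strategy.bsc.os_model.sf(t_grid))
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(s[:-1] > 0, 1.0 - s[1:] / np.where(s[:-1] > 0, s[:-1], 1.0), 1.0)
    event_prob[3] = np.clip(q, 0.0, 1.0)
    cost_table[3, :] = strategy.bsc.cost_per_cycle
    utility[3] = strategy.bsc.utility

    return CompiledStrategy(
        name=strategy.name,
        n_cycles=n_cycles,
        dt_years=dt_y,
        discount=discount,
        p_bg=np.asarray(p_bg),
        event_prob=event_prob,
        h_death=h_death,
        h_disc=h_disc,
        cost_table=cost_table,
        entry_cost=entry_cost,
        utility=utility,
        entry_disutility=entry_dis,
        bsc_switch_fraction=config.bsc_switch_fraction,
        disc_advances=config.discontinuation_mode == "advance",
    )


@lru_cache(maxsize=1)
def _default_life_table() -> LifeTable:
    return load_parameters().life_table


def patient_uniforms(
    seed, n_patients: int, n_cycles: int, start: int = 0, stop: int | None = None
) -> np.ndarray:
    """Uniform tensor (patients, cycles, channels); row i depends only on
    (seed, i), so any contiguous slice [start, stop) can be rebuilt."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_patients)
    stop = n_patients if stop is None else stop
    out = np.empty((stop - start, n_cycles, _N_CHANNELS))
    for i in range(start, stop):
        out[i - start] = np.random.default_rng(children[i]).random(
            (n_cycles, _N_CHANNELS)
        )
    return out


def _simulate_batch(cs: CompiledStrategy, uniforms: np.ndarray, record: bool = False):
    n = uniforms.shape[0]
    ncyc = cs.n_cycles
    phase = np.zeros(n, dtype=np.int64)
    tip = np.zeros(n, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    on_drug = np.ones(n, dtype=bool)
    cost = np.zeros(n)
    qaly = np.zeros(n)
    ly_d = np.zeros(n)
    ly_u = np.zeros(n)
    rows = [] if record else None

    kmax = ncyc - 1
    for c in range(ncyc):
        if not alive.any():
            break
        df = cs.discount[c]
        k = np.minimum(tip, kmax)
        cyc_cost = np.where(on_drug, cs.cost_table[np.minimum(phase, 3), k], 0.0)
        entry = tip == 0
        cyc_cost = cyc_cost + np.where(entry, cs.entry_cost[phase], 0.0)
        util = np.maximum(
            cs.utility[phase] - np.where(entry, cs.entry_disutility[phase], 0.0), 0.0
        )
        d_cost = np.where(alive, df * cyc_cost, 0.0)
        d_qaly = np.where(alive, df * cs.dt_years * util, 0.0)
        cost += d_cost
        qaly += d_qaly
        ly_d += np.where(alive, df * cs.dt_years, 0.0)
        ly_u += np.where(alive, cs.dt_years, 0.0)
        if record:
            for i in range(n):
                rows.append(
                    (
                        c,
                        PHASE_NAMES[phase[i]] if alive[i] else "dead",
                        d_cost[i],
                        d_qaly[i],
                        cs.dt_years if alive[i] else 0.0,
                    )
                )

        u = uniforms[:, c, :]
        die_bg = u[:, 0] < cs.p_bg[c]
        die_ae = ~die_bg & on_drug & (u[:, 1] < cs.h_death[phase])
        ev = ~die_bg & ~die_ae & (u[:, 2] < cs.event_prob[np.minimum(phase, 3), k])
        disc = (
            ~die_bg & ~die_ae & ~ev & on_drug & (u[:, 3] < cs.h_disc[phase])
        )
        in_bsc = phase == 3
        dead = alive & (die_bg | die_ae | (in_bsc & ev))
        if cs.disc_advances:
            advance = alive & ~in_bsc & ~dead & (ev | disc)
            stop = np.zeros(n, dtype=bool)
        else:
            advance = alive & ~in_bsc & ~dead & ev
            stop = alive & ~in_bsc & ~dead & disc
        switch = advance & (phase <= 1) & (u[:, 4] < cs.bsc_switch_fraction)

        tip = np.where(alive & ~advance & ~dead, tip + 1, 0)
        phase = np.where(advance, phase + 1, phase)
        phase = np.where(switch, 3, phase)
        phase = np.where(dead, 4, phase)
        on_drug = (on_drug & ~stop) | advance | switch
        alive = alive & ~dead

    totals = (cost, ly_d, qaly, ly_u)
    if record:
        frame = pd.DataFrame(
            rows, columns=["cycle", "phase", "cost", "qaly", "ly"]
        )
        return totals, frame
    return totals, None


def simulate_patient(
    strategy: StrategySpec,
    config: ModelConfig,
    rng: np.random.Generator,
    life_table: LifeTable | None = None,
    iv_fees: tuple[float, float] | None = None,
) -> PatientTrajectory:
    """Simulate a single patient from an externally supplied stream."""
    cs = compile_strategy(strategy, config, life_table, iv_fees)
    u = rng.random((1, cs.n_cycles, _N_CHANNELS))
    (cost, ly_d, qaly, ly_u), frame = _simulate_batch(cs, u, record=True)
    return PatientTrajectory(
        records=frame,
        total_cost=float(cost[0]),
        total_qaly=float(qaly[0]),
        total_ly=float(ly_d[0]),
        total_ly_undiscounted=float(ly_u[0]),
    )


def run_cohort(
    strategy: StrategySpec,
    config: ModelConfig,
    *,
    n_patients: int | None = None,
    seed=None,
    life_table: LifeTable | None = None,
    iv_fees: tuple[float, float] | None = None,
    batch_size: int = 20_000,
    compiled: CompiledStrategy | None = None,
) -> StrategyOutcome:
    """Means and Monte-Carlo standard errors over independent patients."""
    n = config.n_patients if n_patients is None else int(n_patients)
    master = config.seed if seed is None else seed
    cs = compiled if compiled is not None else compile_strategy(
        strategy, config, life_table, iv_fees
    )
    sums = np.zeros(4)
    sumsq = np.zeros(4)
    children = np.random.SeedSequence(master).spawn(n)
    for start in range(0, n, batch_size):
        stop = min(start + batch_size, n)
        u = np.empty((stop - start, cs.n_cycles, _N_CHANNELS))
        for i in range(start, stop):
            u[i - start] = np.random.default_rng(children[i]).random(
                (cs.n_cycles, _N_CHANNELS)
            )
        (cost, ly_d, qaly, ly_u), _ = _simulate_batch(cs, u)
        for j, arr in enumerate((cost, ly_d, qaly, ly_u)):
            sums[j] += arr.sum()
            sumsq[j] += (arr**2).sum()
    mean = sums / n
    if n > 1:
        var = np.maximum(sumsq / n - mean**2, 0.0) * n / (n - 1)
        se = np.sqrt(var / n)
    else:
        se = np.zeros(4)
    return StrategyOutcome(
        strategy=cs.name,
        mean_cost=float(mean[0]),
        mean_ly=float(mean[1]),
        mean_qaly=float(mean[2]),
        mean_ly_undiscounted=float(mean[3]),
        se_cost=float(se[0]),
        se_ly=float(se[1]),
        se_qaly=float(se[2]),
        n_patients=n,
        seed=master if np.isscalar(master) else None,
    )


def cohort_expectation(
    strategy: StrategySpec,
    config: ModelConfig,
    *,
    life_table: LifeTable | None = None,
    iv_fees: tuple[float, float] | None = None,
    compiled: CompiledStrategy | None = None,
    return_occupancy: bool = False,
):
    """Deterministic expectation of the per-patient outcome.

    Propagates the full probability mass over (phase, time-in-phase)
    using exactly the per-cycle probabilities of the microsimulation;
    no random numbers are involved.
    """
    cs = compiled if compiled is not None else compile_strategy(
        strategy, config, life_table, iv_fees
    )
    ncyc = cs.n_cycles
    kmax = ncyc - 1
    # probability mass over (phase, time-in-phase), lines split by
    # on-drug / off-drug (the latter only populated in stop_drug mode)
    mass_on = [np.zeros(ncyc + 1) for _ in range(4)]
    mass_off = [np.zeros(ncyc + 1) for _ in range(4)]
    mass_on[0][0] = 1.0
    dead = 0.0
    cost = qaly = ly_d = ly_u = 0.0
    occupancy = np.zeros((ncyc, 5)) if return_occupancy else None

    sw = cs.bsc_switch_fraction
    for c in range(ncyc):
        df = cs.discount[c]
        alive_mass = 0.0
        k = np.minimum(np.arange(c + 1), kmax)
        for p in range(4):
            m_on = mass_on[p][: c + 1]
            m_off = mass_off[p][: c + 1]
            tot = m_on.sum() + m_off.sum()
            if tot <= 0.0:
                continue
            alive_mass += tot
            cost += df * float(m_on @ cs.cost_table[p, k])
            cost += df * m_on[0] * cs.entry_cost[p]
            util = cs.utility[p] * tot - cs.entry_disutility[p] * m_on[0]
            qaly += df * cs.dt_years * max(util, 0.0)
            if return_occupancy:
                occupancy[c, p] = tot
        ly_d += df * cs.dt_years * alive_mass
        ly_u += cs.dt_years * alive_mass
        if return_occupancy:
            occupancy[c, 4] = dead

        pbg = cs.p_bg[c]
        inflow = np.zeros(4)
        new_dead = 0.0
        for p in range(4):
            m_on = mass_on[p][: c + 1]
            m_off = mass_off[p][: c + 1]
            if m_on.sum() + m_off.sum() <= 0.0:
                mass_on[p][: c + 2] = np.concatenate(([0.0], m_on))
                mass_off[p][: c + 2] = np.concatenate(([0.0], m_off))
                continue
            if p < 3:
                surv_on = (1.0 - pbg) * (1.0 - cs.h_death[p])
                ev = cs.event_prob[p, k]
                if cs.disc_advances:
                    exit_on = ev + (1.0 - ev) * cs.h_disc[p]
                    stay_on = m_on * surv_on * (1.0 - exit_on)
                    to_off = np.zeros_like(m_on)
                    moved = float((m_on * surv_on * exit_on).sum())
                else:
                    stay_on = m_on * surv_on * (1.0 - ev) * (1.0 - cs.h_disc[p])
                    to_off = m_on * surv_on * (1.0 - ev) * cs.h_disc[p]
                    moved = float((m_on * surv_on * ev).sum())
                stay_off = m_off * (1.0 - pbg) * (1.0 - ev)
                moved += float((m_off * (1.0 - pbg) * ev).sum())
                if p <= 1:
                    inflow[p + 1] += moved * (1.0 - sw)
                    inflow[3] += moved * sw
                else:
                    inflow[3] += moved
                new_dead += (
                    float(m_on.sum()) + float(m_off.sum())
                    - float(stay_on.sum()) - float(to_off.sum())
                    - float(stay_off.sum()) - moved
                )
                mass_on[p][: c + 2] = np.concatenate(([0.0], stay_on))
                mass_off[p][: c + 2] = np.concatenate(([0.0], stay_off + to_off))
            else:
                stay = m_on * (1.0 - pbg) * (1.0 - cs.event_prob[3, k])
                new_dead += float(m_on.sum()) - float(stay.sum())
                mass_on[p][: c + 2] = np.concatenate(([0.0], stay))
                mass_off[p][: c + 2] = np.concatenate(([0.0], m_off))
        for p in range(1, 4):
            mass_on[p][0] += inflow[p]
        dead += new_dead

    outcome = StrategyOutcome(
        strategy=cs.name,
        mean_cost=cost,
        mean_ly=ly_d,
        mean_qaly=qaly,
        mean_ly_undiscounted=ly_u,
        se_cost=0.0,
        se_ly=0.0,
        se_qaly=0.0,
        n_patients=0,
        seed=None,
    )
    if return_occupancy:
        return outcome, occupancy
    return outcome
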