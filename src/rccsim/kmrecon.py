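"""Pseudo individual-patient data from digitized Kaplan-Meier curves.

Published survival figures give only curve coordinates and a
numbers-at-risk table.  The iterative KM-inversion algorithm
implemented here recovers event and censoring times whose product-limit
estimate reproduces the digitized curve and whose implied numbers at
risk match the published risk table, interval by interval.  Censoring
times are spread uniformly within each risk-table interval and ties
place events before censorings, the standard KM convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .survival import PseudoIPD

__all__ = ["DigitizedKM", "ReconstructionError", "reconstruct_ipd", "km_estimate"]


class ReconstructionError(ValueError):
    """The digitized inputs admit no consistent reconstruction."""


@dataclass(frozen=True)
class DigitizedKM:
    """Digitized curve coordinates plus the numbers-at-risk table."""

    times: np.ndarray       # months, increasing, starts at 0
    survival: np.ndarray    # S at each time, non-increasing, S[0] <= 1
    risk_times: np.ndarray  # risk-table anchor times
    n_at_risk: np.ndarray   # counts at the anchors, non-increasing
    n_total: int
    events_total: int | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        surv = np.asarray(self.survival, dtype=float)
        rt = np.asarray(self.risk_times, dtype=float)
        nr = np.asarray(self.n_at_risk, dtype=int)
        if times.shape != surv.shape or times.ndim != 1:
            raise ReconstructionError("times and survival must be parallel 1-d arrays")
        if rt.shape != nr.shape or rt.ndim != 1 or rt.size < 2:
            raise ReconstructionError("need at least two risk-table entries")
        if np.any(np.diff(times) <= 0):
            raise ReconstructionError("digitized times must be strictly increasing")
        if np.any(np.diff(surv) > 1e-12):
            raise ReconstructionError("digitized survival must be non-increasing")
        if surv[0] > 1.0 + 1e-12 or np.any(surv < -1e-12):
            raise ReconstructionError("survival values must lie in [0, 1]")
        if np.any(np.diff(rt) <= 0) or np.any(np.diff(nr) > 0):
            raise ReconstructionError("risk table must have increasing times, non-increasing counts")
        if rt[0] < times[0] - 1e-9 or rt[-1] > times[-1] + 1e-9:
            raise ReconstructionError("risk-table times must lie within the curve span")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "survival", np.clip(surv, 0.0, 1.0))
        object.__setattr__(self, "risk_times", rt)
        object.__setattr__(self, "n_at_risk", nr)

    # -- tab-separated persistence (two files: curve and risk table) --------
    def write_tsv(self, curve_path: str | Path, risk_path: str | Path) -> None:
        pd.DataFrame({"time": self.times, "survival": self.survival}).to_csv(
            curve_path, sep="\t", index=False
        )
        risk = pd.DataFrame({"time": self.risk_times, "n_at_risk": self.n_at_risk})
        risk.attrs["n_total"] = self.n_total
        risk.to_csv(risk_path, sep="\t", index=False)

    @classmethod
    def read_tsv(
        cls,
        curve_path: str | Path,
        risk_path: str | Path,
        n_total: int | None = None,
        events_total: int | None = None,
    ) -> "DigitizedKM":
        curve = pd.read_csv(curve_path, sep="\t")
        risk = pd.read_csv(risk_path, sep="\t")
        return cls(
            times=curve["time"].to_numpy(),
            survival=curve["survival"].to_numpy(),
            risk_times=risk["time"].to_numpy(),
            n_at_risk=risk["n_at_risk"].to_numpy(),
            n_total=int(n_total if n_total is not None else risk["n_at_risk"].iloc[0]),
            events_total=events_total,
        )


def _interval_pass(
    s_vals: np.ndarray,
    t_vals: np.ndarray,
    n_start: int,
    s_prev: float,
    censor_times: np.ndarray,
    interval_end: float,
):
    """One deterministic sweep over the clicks of a risk interval.

    Returns implied n at interval end, the event counts per click, the
    running KM value, and censor counts assigned after each click.
    """
    cen = np.sort(np.asarray(censor_times, dtype=float))
    n = n_start
    s_run = s_prev
    d_counts = np.zeros(t_vals.size, dtype=int)
    # censors strictly before the first click leave the risk set first
    pos = int(np.searchsorted(cen, t_vals[0], side="left")) if t_vals.size else cen.size
    n -= pos
    for i in range(t_vals.size):
        if n > 0 and s_run > 0:
            d = int(round(n * (1.0 - s_vals[i] / s_run)))
            d = min(max(d, 0), n)
            s_run = s_run * (1.0 - d / n)
        else:
            d = 0
        d_counts[i] = d
        n -= d
        upper = t_vals[i + 1] if i + 1 < t_vals.size else np.inf
        nxt = int(np.searchsorted(cen, upper, side="left"))
        n -= nxt - pos
        pos = nxt
    n -= cen.size - pos  # every censor leaves the risk set exactly once
    return n, d_counts, s_run


def reconstruct_ipd(curve: DigitizedKM) -> PseudoIPD:
    """Invert a digitized KM curve plus risk table into pseudo-IPD.

    Within each risk interval the censored count is adjusted iteratively
    until the implied number at risk at the next anchor matches the
    published one; an interval whose risk counts cannot be met (negative
    implied censoring) raises :class:`ReconstructionError` naming it.
    """
    t, s = curve.times, curve.survival
    rt, nr = curve.risk_times, curve.n_at_risk
    n_intervals = rt.size
    events: list[float] = []
    censors: list[float] = []

    s_prev = 1.0
    n_cur = int(nr[0])
    for j in range(n_intervals):
        start = rt[j]
        end = rt[j + 1] if j + 1 < n_intervals else t[-1]
        sel = (t > start - 1e-12) & (t <= end + 1e-12)
        if j == 0:
            sel |= np.isclose(t, start)
        t_j, s_j = t[sel], s[sel]
        # skip the t=0, S=1 anchor click, it carries no information
        keep = ~((t_j <= 1e-12) & (s_j >= 1.0 - 1e-12))
        t_j, s_j = t_j[keep], s_j[keep]

        if j + 1 < n_intervals:
            target = int(nr[j + 1])
            c_guess = 0
            best = None
            for _ in range(40):
                cen = _spread(start, end, c_guess)
                n_end, d_counts, s_run = _interval_pass(
                    s_j, t_j, n_cur, s_prev, cen, end
                )
                delta = n_end - target
                if best is None or abs(delta) < abs(best[0]):
                    best = (delta, c_guess, cen, d_counts, s_run)
                if delta == 0:
                    break
                c_guess += delta
                if c_guess < 0:
                    break
            delta, c_guess, cen, d_counts, s_run = best
            # a small residual can arise from integer rounding on coarse
            # digitization grids; a large negative one means the inputs are
            # genuinely inconsistent
            if delta < -max(2, round(0.02 * nr[0])):
                raise ReconstructionError(
                    f"risk interval [{start}, {end}) implies negative censoring"
                )
        else:
            # terminal interval: events from the clicks, remainder censored
            # at the end of digitized follow-up
            cen = np.array([])
            n_end, d_counts, s_run = _interval_pass(s_j, t_j, n_cur, s_prev, cen, end)

        for i, ti in enumerate(t_j):
            events.extend([float(ti)] * int(d_counts[i]))
        censors.extend(float(c) for c in cen)
        s_prev = s_run
        n_cur = n_end

    if n_cur > 0:  # still at risk at the end of follow-up
        censors.extend([float(t[-1])] * int(n_cur))

    if curve.events_total is not None:
        events, censors = _rescale_events(events, censors, curve.events_total, t[-1])

    time = np.concatenate([np.asarray(events), np.asarray(censors)])
    event = np.concatenate(
        [np.ones(len(events), dtype=int), np.zeros(len(censors), dtype=int)]
    )
    order = np.lexsort((1 - event, time))  # ties: events before censorings
    return PseudoIPD(time[order], event[order])


def _spread(start: float, end: float, count: int) -> np.ndarray:
    """`count` censoring times spread uniformly over (start, end)."""
    if count <= 0:
        return np.array([])
    return start + (np.arange(1, count + 1) / (count + 1)) * (end - start)


def _rescale_events(events, censors, events_total, t_max):
    """Optional final step: nudge the totals to a published event count by
    relabelling the latest censorings as events (or vice versa)."""
    events, censors = sorted(events), sorted(censors)
    diff = events_total - len(events)
    while diff > 0 and censors:
        events.append(censors.pop())
        diff -= 1
    while diff < 0 and events:
        censors.append(events.pop())
        diff += 1
    return events, censors


def km_estimate(
    ipd: PseudoIPD, anchor_times: np.ndarray | None = None
) -> DigitizedKM:
    """Product-limit estimate of pseudo-IPD, shaped like a digitized curve."""
    if len(ipd) == 0:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.time, ipd.event)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    if times[0] != 0.0:
        times = np.concatenate([[0.0], times])
        surv = np.concatenate([[1.0], surv])
    if anchor_times is None:
        t_max = float(ipd.time.max())
        anchor_times = np.array([0.0, t_max]) if t_max > 0 else np.array([0.0, 1.0])
    anchor_times = np.asarray(anchor_times, dtype=float)
    n_at_risk = np.array([(ipd.time >= a - 1e-12).sum() for a in anchor_times])
    return DigitizedKM(
        times=times,
        survival=surv,
        risk_times=anchor_times,
        n_at_risk=n_at_risk,
        n_total=len(ipd),
        events_total=ipd.n_events,
    )
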