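"""Parametric time-to-event laws for progression-free and overall survival.

Four families are supported: exponential, Weibull, log-logistic and
lognormal, the standard set used when extrapolating digitized trial
survival curves beyond follow-up.  All times are in months.

Parameterizations
-----------------
Weibull       ``S(t) = exp(-(t/scale)^shape)``
log-logistic  ``S(t) = 1 / (1 + (t/scale)^shape)``
lognormal     ``S(t) = 1 - Phi((ln t - mu)/sigma)`` with
              ``mu = ln(scale)``, ``sigma = 1/shape``
exponential   a single parameter; by default it is the mean survival
              time in months, ``S(t) = exp(-t/mean)``.  Registries that
              print a bare "shape" for an exponential fit are ambiguous,
              so the interpretation is switchable (``exp_as``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FAMILIES",
    "SurvivalModel",
    "PseudoIPD",
    "FitResult",
    "survival_at",
    "cycle_transition_prob",
    "sample_time",
    "fit_mle",
    "select_best",
]

#: lexical order doubles as the AIC tie-break order after parameter count
FAMILIES = ("exponential", "loglogistic", "lognormal", "weibull")

_EXP_INTERPRETATIONS = ("mean_months", "rate_per_month", "rate_per_year")


@dataclass(frozen=True)
class SurvivalModel:
    """A parametric survival law ``S(t)`` on t >= 0 (months)."""

    family: str
    shape: float
    scale: float | None = None
    label: str = ""
    exp_as: str = "mean_months"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown survival family {self.family!r}")
        if not self.shape > 0:
            raise ValueError(f"shape must be > 0, got {self.shape}")
        if self.family == "exponential":
            if self.exp_as not in _EXP_INTERPRETATIONS:
                raise ValueError(
                    f"exp_as must be one of {_EXP_INTERPRETATIONS}, got {self.exp_as!r}"
                )
        elif self.scale is None or not self.scale > 0:
            raise ValueError(
                f"{self.family} requires scale > 0, got {self.scale}"
            )

    # -- derived parameters -------------------------------------------------
    @property
    def n_params(self) -> int:
        return 1 if self.family == "exponential" else 2

    @property
    def exp_mean(self) -> float:
        """Mean of the exponential law in months under the active interpretation."""
        if self.family != "exponential":
            raise ValueError("exp_mean only defined for exponential models")
        if self.exp_as == "mean_months":
            return self.shape
        if self.exp_as == "rate_per_month":
            return 1.0 / self.shape
        return 12.0 / self.shape  # rate per year

    # -- evaluation ---------------------------------------------------------
    def sf(self, t):
        """Survival function S(t); accepts scalars or arrays, t >= 0."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("negative time")
        if self.family == "exponential":
            out = np.exp(-t / self.exp_mean)
        elif self.family == "weibull":
            out = np.exp(-((t / self.scale) ** self.shape))
        elif self.family == "loglogistic":
            out = 1.0 / (1.0 + (t / self.scale) ** self.shape)
        else:  # lognormal
            sigma = 1.0 / self.shape
            with np.errstate(divide="ignore"):
                z = (np.log(np.maximum(t, np.finfo(float).tiny)) - math.log(self.scale)) / sigma
            out = stats.norm.sf(z)
            out = np.where(t <= 0, 1.0, out)
        return out if out.ndim else float(out)

    def isf(self, u):
        """Inverse survival: the time t with S(t) = u, u in (0, 1)."""
        u = np.asarray(u, dtype=float)
        if np.any((u <= 0) | (u >= 1)):
            raise ValueError("u must lie strictly inside (0, 1)")
        if self.family == "exponential":
            out = -self.exp_mean * np.log(u)
        elif self.family == "weibull":
            out = self.scale * (-np.log(u)) ** (1.0 / self.shape)
        elif self.family == "loglogistic":
            out = self.scale * ((1.0 - u) / u) ** (1.0 / self.shape)
        else:
            sigma = 1.0 / self.shape
            out = np.exp(math.log(self.scale) + sigma * stats.norm.isf(u))
        return out if out.ndim else float(out)

    def median(self) -> float:
        if self.family == "exponential":
            return self.exp_mean * math.log(2.0)
        if self.family == "weibull":
            return self.scale * math.log(2.0) ** (1.0 / self.shape)
        # log-logistic and lognormal medians both equal the scale
        return self.scale

    def logpdf(self, t):
        t = np.maximum(np.asarray(t, dtype=float), 1e-300)
        if self.family == "exponential":
            m = self.exp_mean
            return -np.log(m) - t / m
        if self.family == "weibull":
            p, b = self.shape, self.scale
            return (
                math.log(p) - math.log(b)
                + (p - 1.0) * (np.log(t) - math.log(b))
                - (t / b) ** p
            )
        if self.family == "loglogistic":
            p, b = self.shape, self.scale
            x = (t / b) ** p
            return (
                math.log(p) - math.log(b)
                + (p - 1.0) * (np.log(t) - math.log(b))
                - 2.0 * np.log1p(x)
            )
        sigma = 1.0 / self.shape
        return stats.lognorm.logpdf(t, s=sigma, scale=self.scale)

    def logsf(self, t):
        t = np.asarray(t, dtype=float)
        if self.family == "exponential":
            return -t / self.exp_mean
        if self.family == "weibull":
            return -((t / self.scale) ** self.shape)
        if self.family == "loglogistic":
            return -np.log1p((t / self.scale) ** self.shape)
        sigma = 1.0 / self.shape
        return stats.lognorm.logsf(np.maximum(t, 1e-300), s=sigma, scale=self.scale)


def survival_at(model: SurvivalModel, t) -> float:
    """S(t) for a model; thin functional wrapper over :meth:`SurvivalModel.sf`."""
    return model.sf(t)


def cycle_transition_prob(model: SurvivalModel, t, dt) -> float:
    """Conditional probability of the event inside (t, t+dt] given survival to t.

    Returns ``1 - S(t+dt)/S(t)``; when S(t) has already vanished the
    transition is certain.
    """
    t = np.asarray(t, dtype=float)
    if np.any(np.asarray(dt) <= 0):
        raise ValueError("dt must be positive")
    s0 = np.asarray(model.sf(t), dtype=float)
    s1 = np.asarray(model.sf(t + dt), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(s0 > 0, 1.0 - s1 / np.where(s0 > 0, s0, 1.0), 1.0)
    p = np.clip(p, 0.0, 1.0)
    return p if p.ndim else float(p)


def sample_time(model: SurvivalModel, u):
    """Inverse-CDF draw: the time t with S(t) = u for uniform u in (0, 1)."""
    return model.isf(u)


# ---------------------------------------------------------------------------
# pseudo individual patient data and censored maximum likelihood
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PseudoIPD:
    """Event/censoring records: ``time`` in months, ``event`` 1=event 0=censored."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=int)
        if time.shape != event.shape or time.ndim != 1:
            raise ValueError("time and event must be 1-d arrays of equal length")
        if np.any(time < 0):
            raise ValueError("times must be non-negative")
        if not np.all(np.isin(event, (0, 1))):
            raise ValueError("event indicators must be 0 or 1")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)

    def __len__(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "event": self.event})

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PseudoIPD":
        df = pd.read_csv(path, sep="\t")
        return cls(df["time"].to_numpy(), df["event"].to_numpy())


@dataclass(frozen=True)
class FitResult:
    model: SurvivalModel
    log_likelihood: float
    aic: float
    n: int
    n_events: int
    converged: bool = True


class FitError(RuntimeError):
    """Raised when maximum-likelihood estimation fails to converge."""


def _nll_factory(family: str, time: np.ndarray, event: np.ndarray):
    """Negative censored log-likelihood over log-transformed parameters."""
    ev = event.astype(bool)
    t_ev, t_ce = time[ev], time[~ev]

    def nll(logpar: np.ndarray) -> float:
        par = np.exp(logpar)
        if family == "exponential":
            model = SurvivalModel("exponential", par[0])
        else:
            model = SurvivalModel(family, par[0], par[1])
        ll = model.logpdf(t_ev).sum()
        if t_ce.size:
            ll += model.logsf(t_ce).sum()
        return -float(ll) if np.isfinite(ll) else 1e12

    return nll


def _starts(family: str, time: np.ndarray, event: np.ndarray) -> list[np.ndarray]:
    """Three deterministic initial points in log-parameter space."""
    t_ev = time[event.astype(bool)]
    med = float(np.median(t_ev)) if t_ev.size else float(np.median(time))
    med = max(med, 1e-3)
    if family == "exponential":
        mean = max(float(np.mean(t_ev)) if t_ev.size else med, 1e-3)
        return [np.log([mean]), np.log([0.5 * mean]), np.log([2.0 * mean])]
    if family == "lognormal":
        logt = np.log(np.maximum(t_ev if t_ev.size else time, 1e-3))
        sigma = max(float(np.std(logt)), 0.2)
        scale = math.exp(float(np.mean(logt)))
        return [
            np.log([1.0 / sigma, scale]),
            np.log([0.5 / sigma, scale]),
            np.log([2.0 / sigma, scale]),
        ]
    return [np.log([1.0, med]), np.log([0.7, med]), np.log([2.0, med])]


def fit_mle(ipd: PseudoIPD, family: str) -> FitResult:
    """Censored maximum-likelihood fit of one parametric family.

    Maximizes ``sum_events log f(t) + sum_censored log S(t)`` over
    log-transformed parameters (which enforces positivity), from three
    deterministic starting points, keeping the best optimum.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown survival family {family!r}")
    k = 1 if family == "exponential" else 2
    if ipd.n_events < k:
        raise FitError(f"{family} fit needs at least {k} event(s), got {ipd.n_events}")
    time = np.maximum(ipd.time, 1e-6)
    nll = _nll_factory(family, time, ipd.event)

    best = None
    for x0 in _starts(family, time, ipd.event):
        res = optimize.minimize(
            nll, x0, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError(f"maximum-likelihood fit failed for family {family!r}")
    par = np.exp(best.x)
    model = (
        SurvivalModel("exponential", par[0])
        if family == "exponential"
        else SurvivalModel(family, par[0], par[1])
    )
    ll = -float(best.fun)
    return FitResult(
        model=model,
        log_likelihood=ll,
        aic=2.0 * k - 2.0 * ll,
        n=len(ipd),
        n_events=ipd.n_events,
        converged=bool(best.success),
    )


def select_best(
    ipd: PseudoIPD, families: Sequence[str] = FAMILIES
) -> FitResult:
    """Fit every requested family and return the minimum-AIC result.

    Ties break toward fewer parameters, then lexical family order.
    """
    results: list[FitResult] = []
    errors: list[str] = []
    for fam in families:
        try:
            results.append(fit_mle(ipd, fam))
        except FitError as exc:  # pragma: no cover - degenerate inputs
            errors.append(str(exc))
    if not results:
        raise FitError("all parametric fits failed: " + "; ".join(errors))
    return min(
        results, key=lambda r: (r.aic, r.model.n_params, r.model.family)
    )
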