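"""The optimal-resource model core, advanced by daily iteration.

Per step t (daily by default) the model evaluates the forcing, redraws the
types' optima, and applies the balance equation

    Z_i(t+1) = Z_i(t) + mu_i(t) Z_i(t) - mu_loss(t) Z_i(t)

with

    r_pro   = C1 * SI * max(0, 1 - sum(Z)/K)            (resource allocation)
    mu_i    = C2 * (r_pro / R_i)
              * exp(-(SI - SI_i_opt)^2 / (2 alpha_i^2))
              * exp(-(SST - SST_i_opt)^2 / (2 beta_i^2))  (Gaussian response)
    Kc      = K * exp(-(SI - hSI_opt)^2 / (2 gamma^2))
              * exp(-(SST - hSST_opt)^2 / (2 w^2))        (sustainable density)
    mu_loss = min(1, C3 * max(0, sum(Z) - Kc) / sum(Z))   (excess loss)

Solar insolation is the limiting resource (self-shading makes r_pro decline
with standing stock); temperature is a condition entering only the Gaussian
factors.  Loss is non-selective: the same mu_loss applies to every type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .errors import NumericalError, ParameterError
from .forcing import AnomalySchedule, SeasonalForcing, apply_anomaly
from .traits import (
    HostEnvelope,
    SymbiontTrait,
    TraitDraw,
    TraitSampler,
    default_host,
    default_trait_table,
)

__all__ = [
    "ModelParams",
    "ModelState",
    "StepRates",
    "SiteForcing",
    "Trajectory",
    "resource_allocation",
    "growth_rate",
    "env_carrying_capacity",
    "loss_rate",
    "step",
    "simulate",
]


@dataclass(frozen=True)
class SiteForcing:
    """The two seasonal drivers for one site, plus an optional SST anomaly."""

    si: SeasonalForcing
    sst: SeasonalForcing
    anomaly: Optional[AnomalySchedule] = None

    def drivers_at(self, t: float) -> Tuple[float, float]:
        return float(self.si.evaluate(t)), apply_anomaly(self.sst, self.anomaly, t)


@dataclass(frozen=True)
class ModelParams:
    """Constants, trait table and host envelope for one run."""

    c1: float = 0.01
    c2: float = 3.0  # calibration default; see docs/methods.md
    c3: float = 1.0
    traits: Tuple[SymbiontTrait, ...] = field(
        default_factory=lambda: tuple(default_trait_table())
    )
    host: HostEnvelope = field(default_factory=default_host)
    step_days: float = 1.0
    horizon_days: float = 3600.0

    def __post_init__(self) -> None:
        for name in ("c1", "c2", "c3"):
            v = getattr(self, name)
            if not (v > 0.0 and math.isfinite(v)):
                raise ParameterError(f"{name} must be > 0, got {v}")
        if not (self.step_days > 0.0):
            raise ParameterError(f"step_days must be > 0, got {self.step_days}")
        if self.horizon_days < 0.0:
            raise ParameterError("horizon_days must be >= 0")
        n = self.horizon_days / self.step_days
        if abs(n - round(n)) > 1e-9:
            raise ParameterError(
                "horizon_days must be a whole number of steps "
                f"(horizon {self.horizon_days}, step {self.step_days})"
            )
        if len(self.traits) == 0:
            raise ParameterError("at least one symbiont type is required")
        labels = [tr.label for tr in self.traits]
        if len(set(labels)) != len(labels):
            raise ParameterError(f"trait labels must be unique, got {labels}")

    @property
    def n_steps(self) -> int:
        return int(round(self.horizon_days / self.step_days))

    @property
    def labels(self) -> Tuple[str, ...]:
        return tuple(tr.label for tr in self.traits)


@dataclass
class ModelState:
    """Model state at day ``t``."""

    t: float
    densities: np.ndarray  # cells cm-2, one per type
    current_draw: Optional[TraitDraw] = None

    @property
    def total_density(self) -> float:
        return float(self.densities.sum())


@dataclass(frozen=True)
class StepRates:
    """Rates realised in one step, recorded for audit."""

    r_pro: float  # kW m-2 d-1
    kc: float  # cells cm-2
    growth: np.ndarray  # mu_i, dimensionless, per type
    loss: float  # mu_loss, dimensionless, shared by all types


def resource_allocation(si: float, total_z: float, p: ModelParams) -> float:
    """Insolation available for proliferation after density limitation.

    Non-negative, equal to ``C1 * si`` for an empty host and 0 at or above
    the maximum capacity K.
    """
    if si < 0.0:
        raise ParameterError(f"si must be >= 0, got {si}")
    if total_z < 0.0:
        raise ParameterError(f"total_z must be >= 0, got {total_z}")
    k = p.host.max_capacity
    return p.c1 * si * max(0.0, 1.0 - total_z / k)


def growth_rate(
    draw_i: Tuple[float, float],
    trait_i: SymbiontTrait,
    si: float,
    sst: float,
    r_pro: float,
    p: ModelParams,
) -> float:
    """Specific growth rate mu_i of one type given its drawn optima.

    Maximised exactly at the drawn optima, where it equals
    ``C2 * r_pro / R_i``.
    """
    if r_pro < 0.0:
        raise ParameterError(f"r_pro must be >= 0, got {r_pro}")
    if not (trait_i.si_width > 0.0 and trait_i.sst_width > 0.0):
        raise ParameterError(f"{trait_i.label}: niche widths must be > 0")
    si_opt, sst_opt = draw_i
    g_si = math.exp(-((si - si_opt) ** 2) / (2.0 * trait_i.si_width**2))
    g_sst = math.exp(-((sst - sst_opt) ** 2) / (2.0 * trait_i.sst_width**2))
    return p.c2 * (r_pro / trait_i.resource_requirement) * g_si * g_sst


def env_carrying_capacity(si: float, sst: float, host: HostEnvelope) -> float:
    """Environmentally dependent sustainable density Kc.

    ``0 < Kc <= K`` with equality iff both drivers sit at the host optima.
    """
    if not (host.si_width > 0.0 and host.sst_width > 0.0):
        raise ParameterError("host widths must be > 0")
    f_si = math.exp(-((si - host.si_opt) ** 2) / (2.0 * host.si_width**2))
    f_sst = math.exp(-((sst - host.sst_opt) ** 2) / (2.0 * host.sst_width**2))
    return host.max_capacity * f_si * f_sst


def loss_rate(total_z: float, kc: float, p: ModelParams) -> float:
    """Non-selective loss rate mu_loss in [0, 1].

    Proportional (via C3) to the relative excess of the standing stock over
    Kc; 0 when there is no excess (or no stock), capped at 1 because at most
    the whole population can be shed in one step.
    """
    if kc <= 0.0:
        raise ParameterError(f"kc must be > 0, got {kc}")
    if total_z < 0.0:
        raise ParameterError(f"total_z must be >= 0, got {total_z}")
    if total_z == 0.0:
        return 0.0
    return min(1.0, p.c3 * max(0.0, total_z - kc) / total_z)


def _rates_for(
    t: float,
    densities: np.ndarray,
    draw_si: np.ndarray,
    draw_sst: np.ndarray,
    site: SiteForcing,
    p: ModelParams,
    si_w2: np.ndarray,
    sst_w2: np.ndarray,
    r_req: np.ndarray,
) -> Tuple[float, float, float, float, np.ndarray, float]:
    """Vectorised per-step rates; returns (si, sst, r_pro, kc, mu, loss)."""
    si, sst = site.drivers_at(t)
    total = float(densities.sum())
    r_pro = resource_allocation(si, total, p)
    kc = env_carrying_capacity(si, sst, p.host)
    mu = (
        p.c2
        * (r_pro / r_req)
        * np.exp(-((si - draw_si) ** 2) / si_w2)
        * np.exp(-((sst - draw_sst) ** 2) / sst_w2)
    )
    loss = loss_rate(total, kc, p)
    return si, sst, r_pro, kc, mu, loss


def _width_arrays(p: ModelParams) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    si_w2 = np.array([2.0 * tr.si_width**2 for tr in p.traits])
    sst_w2 = np.array([2.0 * tr.sst_width**2 for tr in p.traits])
    r_req = np.array([tr.resource_requirement for tr in p.traits])
    return si_w2, sst_w2, r_req


def step(
    state: ModelState,
    site: SiteForcing,
    p: ModelParams,
    sampler: TraitSampler,
) -> Tuple[ModelState, StepRates]:
    """Advance the state by one step, returning the rates used."""
    si_w2, sst_w2, r_req = _width_arrays(p)
    draw = sampler.sample()
    si, sst, r_pro, kc, mu, loss = _rates_for(
        state.t, state.densities, draw.si_opt, draw.sst_opt,
        site, p, si_w2, sst_w2, r_req,
    )
    new_densities = state.densities * (1.0 + mu - loss)
    if not np.all(np.isfinite(new_densities)):
        raise NumericalError(f"non-finite density at day {state.t}")
    new_state = ModelState(
        t=state.t + p.step_days, densities=new_densities, current_draw=draw
    )
    return new_state, StepRates(r_pro=r_pro, kc=kc, growth=mu, loss=loss)


@dataclass
class Trajectory:
    """Time-indexed record of one run.

    Row ``k`` holds the state at day ``day[k]`` together with the forcing
    and rates evaluated *at that day*, i.e. the quantities that produce the
    transition to row ``k + 1``:
    ``Z[k+1] = Z[k] * (1 + mu[k] - mu_loss[k])``.
    """

    labels: Tuple[str, ...]
    day: np.ndarray  # (n+1,)
    si: np.ndarray
    sst: np.ndarray
    kc: np.ndarray
    r_pro: np.ndarray
    densities: np.ndarray  # (n+1, n_types)
    growth: np.ndarray  # (n+1, n_types)
    loss: np.ndarray  # (n+1,)
    seed: Optional[int] = None

    @property
    def total_density(self) -> np.ndarray:
        return self.densities.sum(axis=1)

    @property
    def horizon_days(self) -> float:
        return float(self.day[-1])

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "day": self.day,
            "si": self.si,
            "sst": self.sst,
            "kc": self.kc,
            "r_pro": self.r_pro,
        }
        for j, lab in enumerate(self.labels):
            cols[f"z_{lab}"] = self.densities[:, j]
        for j, lab in enumerate(self.labels):
            cols[f"mu_{lab}"] = self.growth[:, j]
        cols["mu_loss"] = self.loss
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate(p: ModelParams, site: SiteForcing, seed: int) -> Trajectory:
    """Run the model for ``p.horizon_days`` and record every step.

    Bit-reproducible for a fixed ``seed``; with all draw SDs zero the output
    is seed-independent.
    """
    n = p.n_steps
    m = len(p.traits)
    si_w2, sst_w2, r_req = _width_arrays(p)
    sampler = TraitSampler(p.traits, seed)
    draw_si, draw_sst = sampler.sample_block(n + 1)

    day = np.arange(n + 1, dtype=float) * p.step_days
    si_arr = np.empty(n + 1)
    sst_arr = np.empty(n + 1)
    kc_arr = np.empty(n + 1)
    r_arr = np.empty(n + 1)
    loss_arr = np.empty(n + 1)
    dens = np.empty((n + 1, m))
    mu_arr = np.empty((n + 1, m))

    z = np.array([tr.initial_density for tr in p.traits], dtype=float)
    for k in range(n + 1):
        t = day[k]
        si, sst, r_pro, kc, mu, loss = _rates_for(
            t, z, draw_si[k], draw_sst[k], site, p, si_w2, sst_w2, r_req
        )
        si_arr[k] = si
        sst_arr[k] = sst
        kc_arr[k] = kc
        r_arr[k] = r_pro
        loss_arr[k] = loss
        dens[k] = z
        mu_arr[k] = mu
        if k < n:
            z = z * (1.0 + mu - loss)
            if not np.all(np.isfinite(z)):
                raise NumericalError(f"non-finite density at step {k + 1}")

    return Trajectory(
        labels=p.labels,
        day=day,
        si=si_arr,
        sst=sst_arr,
        kc=kc_arr,
        r_pro=r_arr,
        densities=dens,
        growth=mu_arr,
        loss=loss_arr,
        seed=int(seed),
    )
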