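"""Experiment layer: two sites x baseline/warming, seeded ensembles, and
the summary statistics behind the qualitative predictions (dominance,
seasonal peak timing, rarity below detectability, shuffling).

Site coefficients are calibration defaults emulating the two study
localities: a thermally homogeneous site (Lee Stocking Island-like, small
SST amplitude) and a seasonally variable site (Key Largo-like, large SST
amplitude).  Insolation peaks in June (day ~166), temperature lags it and
peaks at the start of September (day ~245).
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import timebase
from .dynamics import ModelParams, SiteForcing, Trajectory, simulate
from .errors import ConfigError, ParameterError
from .forcing import AnomalySchedule, SeasonalForcing, phase_for_peak

__all__ = [
    "ScenarioSpec",
    "RunSummary",
    "ShuffleReport",
    "SITE_BUILDERS",
    "site_forcing",
    "run_scenario",
    "summarize",
    "compare_scenarios",
    "group_share",
    "replicate_seeds",
    "DETECTABILITY_THRESHOLD",
]

#: Relative-abundance level below which field methods of the era could not
#: detect a symbiont type (~5%).
DETECTABILITY_THRESHOLD = 0.05

_SI_PEAK_DAY = 166.0
_SST_PEAK_DAY = 245.0


def _lee_stocking() -> Tuple[SeasonalForcing, SeasonalForcing]:
    si = SeasonalForcing(5.8, 1.0, phase_for_peak(_SI_PEAK_DAY))
    sst = SeasonalForcing(27.2, 2.3, phase_for_peak(_SST_PEAK_DAY))
    return si, sst


def _key_largo() -> Tuple[SeasonalForcing, SeasonalForcing]:
    si = SeasonalForcing(5.2, 1.6, phase_for_peak(_SI_PEAK_DAY))
    sst = SeasonalForcing(26.5, 3.5, phase_for_peak(_SST_PEAK_DAY))
    return si, sst


SITE_BUILDERS = {
    "lee_stocking": _lee_stocking,
    "key_largo": _key_largo,
}


def site_forcing(
    site: str,
    warming: Optional[AnomalySchedule] = None,
    custom: Optional[Tuple[SeasonalForcing, SeasonalForcing]] = None,
) -> SiteForcing:
    """Resolve a site name (or a custom (SI, SST) pair) to a SiteForcing."""
    if site == "custom":
        if custom is None:
            raise ConfigError("site 'custom' requires explicit SI/SST forcings")
        si, sst = custom
    else:
        try:
            si, sst = SITE_BUILDERS[site]()
        except KeyError:
            raise ConfigError(
                f"unknown site {site!r}; choose from "
                f"{sorted(SITE_BUILDERS)} or 'custom'"
            ) from None
    return SiteForcing(si=si, sst=sst, anomaly=warming)


@dataclass(frozen=True)
class ScenarioSpec:
    """An ensemble request: site, optional warming overlay, replication."""

    site: str = "lee_stocking"
    warming: Optional[AnomalySchedule] = None
    n_replicates: int = 1
    master_seed: int = 0
    custom_forcing: Optional[Tuple[SeasonalForcing, SeasonalForcing]] = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ConfigError(
                f"n_replicates must be >= 1, got {self.n_replicates}"
            )
        if self.site != "custom" and self.site not in SITE_BUILDERS:
            raise ConfigError(f"unknown site {self.site!r}")

    def forcing(self) -> SiteForcing:
        return site_forcing(self.site, self.warming, self.custom_forcing)


@dataclass(frozen=True)
class RunSummary:
    """Summary statistics of one trajectory.

    Final-year statistics are computed over the last 360 recorded days
    (rows with ``horizon - 360 <= day < horizon``); dominance rank orders
    types by final-year mean density, ties broken by trait order.
    """

    labels: Tuple[str, ...]
    final_year_mean_density: Tuple[float, ...]
    relative_abundance: Tuple[float, ...]
    dominance_rank: Tuple[str, ...]  # best first
    annual_peak_months: Tuple[int, ...]
    min_density: Tuple[float, ...]

    def rank_of(self, label: str) -> int:
        """1-based dominance rank of a type."""
        return self.dominance_rank.index(label) + 1

    def share(self, label: str) -> float:
        return self.relative_abundance[self.labels.index(label)]

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "final_year_mean_density": list(self.final_year_mean_density),
            "relative_abundance": list(self.relative_abundance),
            "dominance_rank": list(self.dominance_rank),
            "annual_peak_months": list(self.annual_peak_months),
            "min_density": list(self.min_density),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunSummary":
        return cls(
            labels=tuple(d["labels"]),
            final_year_mean_density=tuple(d["final_year_mean_density"]),
            relative_abundance=tuple(d["relative_abundance"]),
            dominance_rank=tuple(d["dominance_rank"]),
            annual_peak_months=tuple(d["annual_peak_months"]),
            min_density=tuple(d["min_density"]),
        )


def summarize(traj: Trajectory) -> RunSummary:
    """Compute the RunSummary of a trajectory."""
    if traj.day.shape[0] == 0:
        raise ParameterError("cannot summarize an empty trajectory")
    dens = traj.densities
    day = traj.day
    horizon = traj.horizon_days

    if horizon >= timebase.DAYS_PER_YEAR:
        mask = (day >= horizon - timebase.DAYS_PER_YEAR) & (day < horizon)
    else:  # short run: use everything
        mask = np.ones_like(day, dtype=bool)
    fy_mean = dens[mask].mean(axis=0)
    total = float(fy_mean.sum())
    if total > 0.0:
        rel = fy_mean / total
    else:
        rel = np.zeros_like(fy_mean)

    order = sorted(range(len(traj.labels)), key=lambda i: (-fy_mean[i], i))
    rank = tuple(traj.labels[i] for i in order)

    peaks: List[int] = []
    n_years = int(horizon // timebase.DAYS_PER_YEAR)
    tot = dens.sum(axis=1)
    for y in range(n_years):
        sel = (day >= y * timebase.DAYS_PER_YEAR) & (
            day < (y + 1) * timebase.DAYS_PER_YEAR
        )
        idx = np.flatnonzero(sel)
        k = idx[np.argmax(tot[idx])]
        peaks.append(timebase.month_of_day(day[k]))

    return RunSummary(
        labels=traj.labels,
        final_year_mean_density=tuple(float(v) for v in fy_mean),
        relative_abundance=tuple(float(v) for v in rel),
        dominance_rank=rank,
        annual_peak_months=tuple(peaks),
        min_density=tuple(float(v) for v in dens.min(axis=0)),
    )


def replicate_seeds(master_seed: int, n: int) -> List[int]:
    """Deterministic per-replicate seeds derived from one master seed."""
    rng = np.random.default_rng(int(master_seed))
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_scenario(
    spec: ScenarioSpec, p: ModelParams
) -> List[Tuple[Trajectory, RunSummary]]:
    """Run the ensemble described by ``spec``; bit-reproducible for a fixed
    master seed."""
    site = spec.forcing()
    out = []
    for seed in replicate_seeds(spec.master_seed, spec.n_replicates):
        traj = simulate(p, site, seed)
        out.append((traj, summarize(traj)))
    return out


def group_share(summaries: Sequence[RunSummary], labels: Sequence[str]) -> np.ndarray:
    """Per-replicate summed final-year relative abundance of a label group
    (e.g. the specialists)."""
    return np.array(
        [sum(s.share(lab) for lab in labels) for s in summaries]
    )


@dataclass(frozen=True)
class ShuffleReport:
    """Baseline-vs-warming comparison of two equally sized ensembles."""

    labels: Tuple[str, ...]
    threshold: float
    median_share_baseline: Dict[str, float]
    median_share_warmed: Dict[str, float]
    share_change: Dict[str, float]
    median_rank_baseline: Dict[str, float]
    median_rank_warmed: Dict[str, float]
    rank_change: Dict[str, float]
    emergence: Dict[str, bool]

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "threshold": self.threshold,
            "median_share_baseline": self.median_share_baseline,
            "median_share_warmed": self.median_share_warmed,
            "share_change": self.share_change,
            "median_rank_baseline": self.median_rank_baseline,
            "median_rank_warmed": self.median_rank_warmed,
            "rank_change": self.rank_change,
            "emergence": self.emergence,
        }


def compare_scenarios(
    baseline: Sequence[RunSummary],
    warmed: Sequence[RunSummary],
    threshold: float = DETECTABILITY_THRESHOLD,
) -> ShuffleReport:
    """Per-type change in median relative abundance and rank, with an
    "emergence" flag when the warmed median crosses the detectability
    threshold from below."""
    if len(baseline) != len(warmed) or len(baseline) == 0:
        raise ConfigError("ensembles must be non-empty and equally sized")
    labels = baseline[0].labels
    for s in list(baseline) + list(warmed):
        if s.labels != labels:
            raise ConfigError("ensembles carry mismatched type sets")
    if not (0.0 <= threshold <= 1.0):
        raise ConfigError("threshold must be in [0, 1]")

    msb, msw, msc = {}, {}, {}
    mrb, mrw, mrc = {}, {}, {}
    emergence = {}
    for lab in labels:
        b = statistics.median(s.share(lab) for s in baseline)
        w = statistics.median(s.share(lab) for s in warmed)
        msb[lab], msw[lab], msc[lab] = b, w, w - b
        rb = statistics.median(s.rank_of(lab) for s in baseline)
        rw = statistics.median(s.rank_of(lab) for s in warmed)
        mrb[lab], mrw[lab], mrc[lab] = rb, rw, rw - rb
        emergence[lab] = bool(b < threshold <= w)
    return ShuffleReport(
        labels=labels,
        threshold=float(threshold),
        median_share_baseline=msb,
        median_share_warmed=msw,
        share_change=msc,
        median_rank_baseline=mrb,
        median_rank_warmed=mrw,
        rank_change=mrc,
        emergence=emergence,
    )


def summaries_to_frame(summaries: Sequence[RunSummary]) -> pd.DataFrame:
    """Tidy table: one row per (replicate, type)."""
    rows = []
    for r, s in enumerate(summaries):
        for lab in s.labels:
            i = s.labels.index(lab)
            rows.append(
                {
                    "replicate": r,
                    "type": lab,
                    "final_mean": s.final_year_mean_density[i],
                    "rel_abund": s.relative_abundance[i],
                    "rank": s.rank_of(lab),
                    "min_density": s.min_density[i],
                }
            )
    return pd.DataFrame(rows)


def save_summaries(summaries: Sequence[RunSummary], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([s.to_dict() for s in summaries], fh, indent=1)
        fh.write("\n")


def load_summaries(path) -> List[RunSummary]:
    with open(path, "r", encoding="utf-8") as fh:
        return [RunSummary.from_dict(d) for d in json.load(fh)]
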