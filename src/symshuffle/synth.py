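"""Synthetic monthly climatology fixtures.

Stands in for the satellite-derived 10-year monthly means the model is
normally calibrated against: each driver is sampled from a sinusoid at
mid-month days with optional Gaussian noise.  Deterministic under a fixed
seed, so fixtures are generated at test time instead of being shipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import timebase
from .errors import ParameterError
from .forcing import SeasonalForcing

__all__ = ["DriverSpec", "generate_synthetic_climatology", "monthly_series"]

CLIMATOLOGY_COLUMNS = ("month", "sst_c", "si_kw_m2_d")


@dataclass(frozen=True)
class DriverSpec:
    """Generating sinusoid for one driver of a synthetic climatology."""

    mean: float
    amplitude: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0.0:
            raise ParameterError(f"amplitude must be >= 0, got {self.amplitude}")

    def forcing(self) -> SeasonalForcing:
        return SeasonalForcing(self.mean, self.amplitude, self.phase)


def monthly_series(
    spec: DriverSpec, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """12 mid-month samples of the sinusoid plus N(0, noise_sd) noise."""
    if noise_sd < 0.0:
        raise ParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    t = np.array(
        [timebase.month_midpoint(m) for m in range(1, timebase.MONTHS_PER_YEAR + 1)]
    )
    clean = spec.forcing().evaluate(t)
    if noise_sd == 0.0:
        return clean
    return clean + rng.normal(0.0, noise_sd, size=clean.shape)


def generate_synthetic_climatology(
    sst: DriverSpec,
    si: DriverSpec,
    noise_sd: float = 0.0,
    seed: int = 0,
    path=None,
) -> pd.DataFrame:
    """Build a 12-row climatology table (and optionally write it as CSV
    with header ``month,sst_c,si_kw_m2_d``)."""
    rng = np.random.default_rng(int(seed))
    df = pd.DataFrame(
        {
            "month": np.arange(1, timebase.MONTHS_PER_YEAR + 1),
            "sst_c": monthly_series(sst, noise_sd, rng),
            "si_kw_m2_d": monthly_series(si, noise_sd, rng),
        }
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df


def load_climatology(path) -> pd.DataFrame:
    """Read a climatology CSV, validating the expected header."""
    df = pd.read_csv(path)
    missing = [c for c in CLIMATOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(
            f"climatology file {path} is missing columns {missing}"
        )
    return df
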