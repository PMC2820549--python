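"""Symbiont and host niche envelopes, and the per-step draws of optima.

Each *Symbiodinium* type is described by a mean optimum and a width (SD) for
each of the two drivers, solar insolation (SI) and sea-surface temperature
(SST).  Wide envelopes are generalists, narrow envelopes specialists.  At
every iteration step the realised optima are redrawn from normal
distributions centred on the means with the same SDs, so a type's niche is a
stochastic cloud rather than a fixed point; the widths used inside the
Gaussian growth response stay fixed.

The four default types and the host envelope follow the published
parameterisation: optima (SI/SST) 5.5/28, 5.5/26.5, 4.5/28 and 4.5/26.5;
SI SDs 0.4, 0.8, 0.4, 0.8; SST SDs 0.4, 1, 0.4, 1; host optima 5.5 and 27
with tolerance widths 2.0 and 3.0; equal resource requirements R_i = 1 and
initial densities of 1.0e6 cells cm-2.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np

from .errors import ParameterError

__all__ = [
    "SymbiontTrait",
    "HostEnvelope",
    "TraitDraw",
    "TraitSampler",
    "default_trait_table",
    "default_host",
    "sample_optima",
    "SPECIALIST_LABELS",
    "GENERALIST_LABELS",
]

#: Default maximum carrying capacity K (cells cm-2): same order as the
#: ~1e6 cells that fit in 1 cm2 of tissue, times the four resident types.
DEFAULT_MAX_CAPACITY = 5.0e6

SPECIALIST_LABELS = ("type1", "type3")
GENERALIST_LABELS = ("type2", "type4")


@dataclass(frozen=True)
class SymbiontTrait:
    """Niche envelope and bookkeeping for one symbiont type.

    ``si_width``/``sst_width`` are the Gaussian niche SDs (alpha_i, beta_i;
    strictly positive).  ``si_draw_sd``/``sst_draw_sd`` are the SDs of the
    per-step optimum draws; they default to the niche widths (the published
    conditions list a single SD per driver per type) but may be set to 0 to
    obtain a fully deterministic run.
    """

    label: str
    si_opt_mean: float  # kW m-2 d-1
    sst_opt_mean: float  # degC
    si_width: float  # alpha_i, kW m-2 d-1
    sst_width: float  # beta_i, degC
    resource_requirement: float = 1.0  # R_i
    initial_density: float = 1.0e6  # cells cm-2
    si_draw_sd: Optional[float] = None
    sst_draw_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.label:
            raise ParameterError("trait label must be non-empty")
        if not (self.si_width > 0.0):
            raise ParameterError(
                f"{self.label}: si_width must be > 0, got {self.si_width}"
            )
        if not (self.sst_width > 0.0):
            raise ParameterError(
                f"{self.label}: sst_width must be > 0, got {self.sst_width}"
            )
        if not (self.resource_requirement > 0.0):
            raise ParameterError(
                f"{self.label}: resource_requirement must be > 0, "
                f"got {self.resource_requirement}"
            )
        if self.initial_density < 0.0:
            raise ParameterError(
                f"{self.label}: initial_density must be >= 0, "
                f"got {self.initial_density}"
            )
        for name in ("si_draw_sd", "sst_draw_sd"):
            sd = getattr(self, name)
            if sd is not None and sd < 0.0:
                raise ParameterError(f"{self.label}: {name} must be >= 0, got {sd}")
        for name in ("si_opt_mean", "sst_opt_mean"):
            if not math.isfinite(getattr(self, name)):
                raise ParameterError(f"{self.label}: {name} must be finite")

    @property
    def effective_si_draw_sd(self) -> float:
        return self.si_width if self.si_draw_sd is None else self.si_draw_sd

    @property
    def effective_sst_draw_sd(self) -> float:
        return self.sst_width if self.sst_draw_sd is None else self.sst_draw_sd

    def with_fixed_optima(self) -> "SymbiontTrait":
        """Copy with zero draw SDs (optima pinned at their means)."""
        return replace(self, si_draw_sd=0.0, sst_draw_sd=0.0)


@dataclass(frozen=True)
class HostEnvelope:
    """Host coral's environmental optimality envelope and capacity."""

    si_opt: float = 5.5  # hSI_opt, kW m-2 d-1
    sst_opt: float = 27.0  # hSST_opt, degC
    si_width: float = 2.0  # gamma, kW m-2 d-1
    sst_width: float = 3.0  # degC
    max_capacity: float = DEFAULT_MAX_CAPACITY  # K, cells cm-2

    def __post_init__(self) -> None:
        if not (self.si_width > 0.0 and self.sst_width > 0.0):
            raise ParameterError("host widths must be > 0")
        if not (self.max_capacity > 0.0):
            raise ParameterError(
                f"max_capacity must be > 0, got {self.max_capacity}"
            )


def default_trait_table() -> List[SymbiontTrait]:
    """The four published symbiont types.

    type1: high-SI / high-SST specialist; type2: high-SI / low-SST
    generalist; type3: low-SI / high-SST specialist; type4: low-SI /
    low-SST generalist.
    """
    return [
        SymbiontTrait("type1", 5.5, 28.0, 0.4, 0.4),
        SymbiontTrait("type2", 5.5, 26.5, 0.8, 1.0),
        SymbiontTrait("type3", 4.5, 28.0, 0.4, 0.4),
        SymbiontTrait("type4", 4.5, 26.5, 0.8, 1.0),
    ]


def default_host() -> HostEnvelope:
    return HostEnvelope()


@dataclass(frozen=True)
class TraitDraw:
    """Optima realised for one iteration step (one pair per type)."""

    labels: tuple
    si_opt: np.ndarray
    sst_opt: np.ndarray

    def __post_init__(self) -> None:
        if not (
            len(self.labels) == self.si_opt.shape[0] == self.sst_opt.shape[0]
        ):
            raise ParameterError("draw arrays must have one entry per type")


def _label_stream_key(label: str) -> int:
    # Stable per-label key so permuting the trait table permutes the
    # draw streams with it.
    return zlib.crc32(label.encode("utf-8"))


class TraitSampler:
    """Per-type substreams of optimum draws from one master seed.

    Each type's stream is keyed on its label, not its position, so adding
    or reordering types never perturbs the randomness of the others.  Each
    step consumes one (SI, SST) normal pair per type, in that order.
    """

    def __init__(self, traits: Sequence[SymbiontTrait], seed: int) -> None:
        self.traits = tuple(traits)
        self.seed = int(seed)
        self._rngs = [
            np.random.default_rng(
                np.random.SeedSequence(
                    entropy=self.seed, spawn_key=(_label_stream_key(tr.label),)
                )
            )
            for tr in self.traits
        ]

    def sample(self) -> TraitDraw:
        """Draw the optima for one iteration step."""
        si = np.empty(len(self.traits))
        sst = np.empty(len(self.traits))
        for i, (tr, rng) in enumerate(zip(self.traits, self._rngs)):
            # standard pair scaled by hand so stepwise and block sampling
            # consume the streams identically
            pair = rng.normal(size=2)
            si[i] = tr.si_opt_mean + tr.effective_si_draw_sd * pair[0]
            sst[i] = tr.sst_opt_mean + tr.effective_sst_draw_sd * pair[1]
        return TraitDraw(
            labels=tuple(tr.label for tr in self.traits), si_opt=si, sst_opt=sst
        )

    def sample_block(self, n_steps: int) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``n_steps`` steps at once; returns ``(si, sst)`` arrays of
        shape ``(n_steps, n_types)``.

        The values are identical to ``n_steps`` successive :meth:`sample`
        calls (each type's stream yields its (SI, SST) pairs in the same
        order either way).
        """
        m = len(self.traits)
        si = np.empty((n_steps, m))
        sst = np.empty((n_steps, m))
        for i, (tr, rng) in enumerate(zip(self.traits, self._rngs)):
            pairs = rng.normal(size=(n_steps, 2))
            si[:, i] = tr.si_opt_mean + tr.effective_si_draw_sd * pairs[:, 0]
            sst[:, i] = tr.sst_opt_mean + tr.effective_sst_draw_sd * pairs[:, 1]
        return si, sst


def sample_optima(traits: Sequence[SymbiontTrait], sampler: TraitSampler) -> TraitDraw:
    """Draw one step's optima using ``sampler`` (must wrap the same traits)."""
    if tuple(tr.label for tr in traits) != tuple(
        tr.label for tr in sampler.traits
    ):
        raise ParameterError("sampler was built for a different trait table")
    return sampler.sample()
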