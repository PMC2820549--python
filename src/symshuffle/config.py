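"""TOML run configuration: validation, defaults, round-tripping.

An empty file yields the full published parameterisation (four default
types, host envelope 5.5/27 with widths 2/3, C1 = 0.01, 360-day calendar,
10-year horizon, Lee Stocking Island forcing).  Unknown keys are rejected
and every applied default is logged at INFO level.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from pathlib import Path
from typing import List, Literal, Optional, Tuple

from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .dynamics import ModelParams
from .errors import ConfigError
from .forcing import DEFAULT_WARMING, AnomalySchedule, SeasonalForcing
from .scenarios import SITE_BUILDERS, ScenarioSpec
from .traits import HostEnvelope, SymbiontTrait, default_trait_table

logger = logging.getLogger("symshuffle")

__all__ = ["RunConfig", "load_config", "loads_config", "dumps_toml", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class ModelCfg(_Strict):
    c1: float = Field(0.01, gt=0)
    c2: float = Field(3.0, gt=0)
    c3: float = Field(1.0, gt=0)
    step_days: float = Field(1.0, gt=0)
    horizon_days: float = Field(3600.0, ge=0)


class HostCfg(_Strict):
    si_opt: float = 5.5
    sst_opt: float = 27.0
    si_width: float = Field(2.0, gt=0)
    sst_width: float = Field(3.0, gt=0)
    max_capacity: float = Field(5.0e6, gt=0)


class TraitCfg(_Strict):
    label: str
    si_opt: float
    sst_opt: float
    si_sd: float = Field(gt=0)
    sst_sd: float = Field(gt=0)
    r_i: float = Field(1.0, gt=0)
    z0: float = Field(1.0e6, ge=0)


class CoeffCfg(_Strict):
    mean: float
    amplitude: float = Field(ge=0)
    phase: float = 0.0
    period_days: float = Field(360.0, gt=0)


class ForcingCfg(_Strict):
    site: str = "lee_stocking"
    si: Optional[CoeffCfg] = None
    sst: Optional[CoeffCfg] = None

    @field_validator("site")
    @classmethod
    def _known_site(cls, v: str) -> str:
        if v != "custom" and v not in SITE_BUILDERS:
            raise ValueError(
                f"unknown site {v!r}; choose from {sorted(SITE_BUILDERS)} or 'custom'"
            )
        return v


class AnomalyEntryCfg(_Strict):
    month: int = Field(ge=1, le=12)
    delta: float


class ScenarioCfg(_Strict):
    warming: bool = False
    anomaly: Optional[List[AnomalyEntryCfg]] = None
    application_mode: Literal["every_year", "random_years"] = "every_year"
    probability: float = Field(1.0, ge=0, le=1)
    n_replicates: int = Field(1, ge=1)


class RunCfg(_Strict):
    seed: int = 0
    out_dir: str = "runs"
    log_level: str = "INFO"


class RunConfig(_Strict):
    """Fully validated run configuration."""

    model: ModelCfg = ModelCfg()
    host: HostCfg = HostCfg()
    traits: Optional[List[TraitCfg]] = None  # None -> default table
    forcing: ForcingCfg = ForcingCfg()
    scenario: ScenarioCfg = ScenarioCfg()
    run: RunCfg = RunCfg()

    # ---- builders -------------------------------------------------

    def trait_table(self) -> List[SymbiontTrait]:
        if self.traits is None:
            return default_trait_table()
        return [
            SymbiontTrait(
                label=t.label,
                si_opt_mean=t.si_opt,
                sst_opt_mean=t.sst_opt,
                si_width=t.si_sd,
                sst_width=t.sst_sd,
                resource_requirement=t.r_i,
                initial_density=t.z0,
            )
            for t in self.traits
        ]

    def host_envelope(self) -> HostEnvelope:
        h = self.host
        return HostEnvelope(
            si_opt=h.si_opt,
            sst_opt=h.sst_opt,
            si_width=h.si_width,
            sst_width=h.sst_width,
            max_capacity=h.max_capacity,
        )

    def model_params(self) -> ModelParams:
        m = self.model
        return ModelParams(
            c1=m.c1,
            c2=m.c2,
            c3=m.c3,
            traits=tuple(self.trait_table()),
            host=self.host_envelope(),
            step_days=m.step_days,
            horizon_days=m.horizon_days,
        )

    def anomaly_schedule(self) -> Optional[AnomalySchedule]:
        sc = self.scenario
        if not sc.warming and sc.anomaly is None:
            return None
        if sc.anomaly is not None:
            entries = tuple((e.month, e.delta) for e in sc.anomaly)
        else:
            entries = DEFAULT_WARMING.entries
        return AnomalySchedule(
            entries=entries,
            application_mode=sc.application_mode,
            probability=sc.probability,
            seed=self.run.seed,
        )

    def custom_forcing(self) -> Optional[Tuple[SeasonalForcing, SeasonalForcing]]:
        f = self.forcing
        if f.site != "custom":
            return None
        if f.si is None or f.sst is None:
            raise ConfigError(
                "forcing.site = 'custom' requires [forcing.si] and [forcing.sst]"
            )
        mk = lambda c: SeasonalForcing(c.mean, c.amplitude, c.phase, c.period_days)
        return mk(f.si), mk(f.sst)

    def scenario_spec(self, warming: Optional[bool] = None) -> ScenarioSpec:
        sched = self.anomaly_schedule()
        if warming is False:
            sched = None
        elif warming is True and sched is None:
            sched = DEFAULT_WARMING
        return ScenarioSpec(
            site=self.forcing.site,
            warming=sched,
            n_replicates=self.scenario.n_replicates,
            master_seed=self.run.seed,
            custom_forcing=self.custom_forcing(),
        )


def _log_defaults(data: dict) -> None:
    for section, model in (
        ("model", ModelCfg),
        ("host", HostCfg),
        ("forcing", ForcingCfg),
        ("scenario", ScenarioCfg),
        ("run", RunCfg),
    ):
        present = data.get(section, {})
        for name, f in model.model_fields.items():
            if name not in present:
                logger.info(
                    "config: using default %s.%s = %r", section, name,
                    f.get_default(),
                )
            else:
                logger.info(
                    "config: override %s.%s = %r", section, name, present[name]
                )
    if "traits" not in data:
        logger.info("config: using the default four-type trait table")


def loads_config(text: str) -> RunConfig:
    """Parse and validate a TOML configuration string."""
    try:
        data = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"invalid TOML: {exc}") from exc
    try:
        cfg = RunConfig.model_validate(data)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration: {locs}") from exc
    _log_defaults(data)
    # surface trait/host domain errors (e.g. duplicate labels) early
    cfg.model_params()
    cfg.scenario_spec()
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a TOML configuration file."""
    p = Path(path)
    if not p.is_file():
        raise ConfigError(f"config file not found: {p}")
    return loads_config(p.read_text(encoding="utf-8"))


def _toml_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, float) and v == int(v) and abs(v) < 1e15:
        return f"{v:.1f}"
    return repr(v)


def dumps_toml(cfg: RunConfig) -> str:
    """Serialise a RunConfig to TOML such that it round-trips exactly."""
    lines: List[str] = []

    def table(name: str, obj: BaseModel, skip=()) -> None:
        lines.append(f"[{name}]")
        for k, v in obj.model_dump().items():
            if k in skip or v is None:
                continue
            lines.append(f"{k} = {_toml_scalar(v)}")
        lines.append("")

    table("model", cfg.model)
    table("host", cfg.host)
    if cfg.traits is not None:
        for t in cfg.traits:
            lines.append("[[traits]]")
            for k, v in t.model_dump().items():
                lines.append(f"{k} = {_toml_scalar(v)}")
            lines.append("")
    table("forcing", cfg.forcing, skip=("si", "sst"))
    if cfg.forcing.si is not None:
        table("forcing.si", cfg.forcing.si)
    if cfg.forcing.sst is not None:
        table("forcing.sst", cfg.forcing.sst)
    table("scenario", cfg.scenario, skip=("anomaly",))
    if cfg.scenario.anomaly is not None:
        for e in cfg.scenario.anomaly:
            lines.append("[[scenario.anomaly]]")
            for k, v in e.model_dump().items():
                lines.append(f"{k} = {_toml_scalar(v)}")
            lines.append("")
    table("run", cfg.run)
    return "\n".join(lines).rstrip() + "\n"


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of the fully resolved configuration (for metadata)."""
    payload = json.dumps(cfg.model_dump(), sort_keys=True)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]
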