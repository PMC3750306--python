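"""Run configuration: defaults, YAML/JSON loading, validation, round-trip."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .parameters import (
    PARAMETER_ALIASES,
    InputPoint,
    KineticParameters,
    PoolConfiguration,
    POOL_PRESETS,
)

__all__ = ["SolverSettings", "RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Malformed or out-of-range run configuration."""


@dataclass(frozen=True)
class SolverSettings:
    """Integrator contract for the stiff full system."""

    rtol: float = 1e-8
    atol: float = 1e-3
    method: str = "BDF"

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ConfigError("solver tolerances must be positive")


_PARAM_KEYS = {f.name for f in dataclasses.fields(KineticParameters)}
_POOL_KEYS = {"Bad_tot": "bad_tot", "BclxL_tot": "bclxl_tot", "Scaffold_tot": "scaffold_tot",
              "bad_tot": "bad_tot", "bclxl_tot": "bclxl_tot", "scaffold_tot": "scaffold_tot"}
_INPUT_KEYS = {"p53_killer": "p53_killer", "Akt_u": "akt_u", "akt_u": "akt_u"}
_OTHER_KEYS = {"preset", "solver", "seed"}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved run configuration.

    ``pools`` stays None until a preset or explicit totals are supplied;
    operations that need pools refuse to guess.
    """

    params: KineticParameters = field(default_factory=KineticParameters)
    pools: PoolConfiguration | None = None
    preset: str | None = None
    inputs: InputPoint | None = None
    solver: SolverSettings = field(default_factory=SolverSettings)
    seed: int | None = None
    overridden: tuple[str, ...] = ()

    def require_pools(self) -> PoolConfiguration:
        if self.pools is None:
            raise ConfigError(
                "no pool configuration: choose a preset (OR, AND, AND_STAR) "
                "or give explicit Bad_tot/BclxL_tot totals"
            )
        return self.pools

    def to_dict(self) -> dict:
        d: dict = dict(self.params.as_dict())
        if self.pools is not None:
            d.update(
                Bad_tot=self.pools.bad_tot,
                BclxL_tot=self.pools.bclxl_tot,
                Scaffold_tot=self.pools.scaffold_tot,
            )
        if self.preset is not None:
            d["preset"] = self.preset
        if self.inputs is not None:
            d["p53_killer"] = self.inputs.p53_killer
            d["akt_u"] = self.inputs.akt_u
        d["solver"] = dataclasses.asdict(self.solver)
        if self.seed is not None:
            d["seed"] = self.seed
        return d


def _from_mapping(doc: dict) -> RunConfig:
    param_over: dict[str, float] = {}
    pool_over: dict[str, float] = {}
    input_over: dict[str, float] = {}
    preset = None
    solver = SolverSettings()
    seed = None
    overridden: list[str] = []

    for key, value in doc.items():
        canon = PARAMETER_ALIASES.get(key, key)
        if canon in _PARAM_KEYS:
            param_over[canon] = float(value)
        elif key in _POOL_KEYS:
            pool_over[_POOL_KEYS[key]] = float(value)
        elif key in _INPUT_KEYS:
            input_over[_INPUT_KEYS[key]] = float(value)
        elif key == "preset":
            preset = str(value)
            if preset not in POOL_PRESETS:
                raise ConfigError(
                    f"unknown preset {preset!r}; choose from {sorted(POOL_PRESETS)}"
                )
        elif key == "solver":
            if not isinstance(value, dict):
                raise ConfigError("'solver' must be a mapping of rtol/atol/method")
            unknown = set(value) - {"rtol", "atol", "method"}
            if unknown:
                raise ConfigError(f"unknown solver key(s): {sorted(unknown)}")
            solver = SolverSettings(**value)
        elif key == "seed":
            seed = int(value)
        else:
            raise ConfigError(f"unknown configuration key {key!r}")
        if key not in ("solver", "seed"):
            overridden.append(key)

    try:
        params = KineticParameters(**param_over)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    pools: PoolConfiguration | None = None
    if preset is not None:
        pools = POOL_PRESETS[preset]
        if pool_over:
            pools = pools.replace(**pool_over)
    elif pool_over:
        if "bad_tot" not in pool_over or "bclxl_tot" not in pool_over:
            raise ConfigError(
                "explicit pools need both Bad_tot and BclxL_tot (Scaffold_tot optional)"
            )
        pools = PoolConfiguration(**pool_over)

    inputs: InputPoint | None = None
    if input_over:
        inputs = InputPoint(
            p53_killer=input_over.get("p53_killer", 0.0),
            akt_u=input_over.get("akt_u", 0.0),
        )
        if inputs.akt_u > params.akt_tot:
            raise ConfigError(
                f"akt_u={inputs.akt_u} exceeds the total Akt pool {params.akt_tot}"
            )

    return RunConfig(
        params=params,
        pools=pools,
        preset=preset,
        inputs=inputs,
        solver=solver,
        seed=seed,
        overridden=tuple(overridden),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration.

    Keys are the printed parameter symbols (s1..a2, Akt_tot, p53killer_max)
    plus Bad_tot/BclxL_tot/Scaffold_tot, preset, p53_killer/Akt_u, solver,
    and seed; absent keys take the published defaults.  Unknown keys are
    rejected by name.
    """
    path = Path(path)
    text = path.read_text()
    try:
        doc = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path} must contain a mapping at top level")
    return _from_mapping(doc)
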