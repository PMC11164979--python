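"""Run configuration: loading, validation and defaults.

A run is configured by a single YAML document (or an in-memory
:class:`RunConfig`).  Every referenced weighting scheme and price scenario
must be defined; validation failures name the offending key.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from ._errors import ConfigurationError
from .economic import DEFAULT_RISK_AVERSION, price_scenarios
from .synthetic import CVModel, SimulationParams
from .weighting import STAKEHOLDERS

KNOWN_SCHEMES = tuple(STAKEHOLDERS) + ("equal_function", "equal_service")


@dataclass
class RunConfig:
    """Configuration of an end-to-end pipeline run."""

    seed: int = 0
    n_mainplots: int = 10
    years: list[int] = field(default_factory=lambda: list(range(2016, 2021)))
    #: per-function year subsets for aggregation (empty: use all years)
    year_sets: dict[str, list[int]] = field(default_factory=dict)
    schemes: list[str] = field(default_factory=lambda: list(KNOWN_SCHEMES))
    scenarios: list[str] = field(default_factory=lambda: list(price_scenarios()))
    nitrogen_variant: str = "literal"
    cv_ddof: int = 1
    flat_soil_health: bool = False
    risk_aversion: float = DEFAULT_RISK_AVERSION
    #: price (EUR/dt) used to monetize simulated yield biomass
    yield_price: float = 9.0
    #: optional overrides forwarded to SimulationParams
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_mainplots < 2 or self.n_mainplots % 2:
            raise ConfigurationError("n_mainplots: must be even and >= 2")
        unknown = set(self.schemes) - set(KNOWN_SCHEMES)
        if unknown:
            raise ConfigurationError(
                f"schemes: unknown scheme(s) {sorted(unknown)}; known: {KNOWN_SCHEMES}"
            )
        unknown = set(self.scenarios) - set(price_scenarios())
        if unknown:
            raise ConfigurationError(
                f"scenarios: unknown scenario(s) {sorted(unknown)}"
            )
        if self.nitrogen_variant not in ("literal", "balance"):
            raise ConfigurationError("nitrogen_variant: must be 'literal' or 'balance'")
        if self.cv_ddof not in (0, 1):
            raise ConfigurationError("cv_ddof: must be 0 or 1")
        if self.risk_aversion < 0:
            raise ConfigurationError("risk_aversion: must be nonnegative")
        if self.yield_price < 0:
            raise ConfigurationError("yield_price: must be nonnegative")

    def simulation_params(self) -> SimulationParams:
        """Materialize generator parameters, applying any overrides."""
        overrides = dict(self.simulation)
        cv = overrides.pop("cv_model", None)
        kwargs = dict(years=list(self.years), seed=self.seed)
        if cv is not None:
            kwargs["cv_model"] = CVModel(**cv)
        for key in (
            "baselines",
            "units",
            "climate_effects",
            "management_effects",
            "noise_sd",
            "b_means",
            "h_means",
            "trait_sd",
            "trait_coupling",
        ):
            if key in overrides:
                kwargs[key] = overrides.pop(key)
        if overrides:
            raise ConfigurationError(
                f"simulation: unknown key(s) {sorted(overrides)}"
            )
        return SimulationParams(**kwargs)

    def as_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable digest of the configuration, recorded in all outputs."""
        blob = yaml.safe_dump(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.as_dict(), sort_keys=True))
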