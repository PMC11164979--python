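"""Weighting schemes and ecological multifunctionality.

Ecological multifunctionality (egEMF) is the weighted average of the
normalized ecosystem-function levels, with weights derived either from
stakeholder service preferences, from an equal-function rule, or from an
equal-service rule that distributes each service's share among its
constituent functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, DomainError, MissingDataError
from .functions import CANONICAL_FUNCTIONS

log = logging.getLogger(__name__)

SERVICES: tuple[str, ...] = (
    "food_production",
    "climate_regulation",
    "water_quality",
    "soil_health",
    "biodiversity_conservation",
    "landscape_aesthetics",
)

#: Which service each canonical function approximates.
FUNCTION_SERVICE: dict[str, str] = {
    "yield": "food_production",
    "toc_flux": "climate_regulation",
    "n_surplus": "water_quality",
    "microbial_biomass": "soil_health",
    "cellulase": "soil_health",
    "nag": "soil_health",
    "acid_phosphatase": "soil_health",
    "bg_decomposition": "soil_health",
    "ag_decomposition_microbes": "soil_health",
    "ag_decomposition_microbes_fauna": "soil_health",
    "nematode_diversity": "biodiversity_conservation",
    "mesofauna_diversity": "biodiversity_conservation",
    "macrofauna_diversity": "biodiversity_conservation",
    "flower_abundance": "landscape_aesthetics",
}

#: Hierarchical within-service shares for soil health: microbial biomass is
#: one of three equal components; each enzyme and each decomposition measure
#: is one third of its component.
HIERARCHICAL_SOIL_HEALTH_SHARES: dict[str, float] = {
    "microbial_biomass": 1.0 / 3.0,
    "cellulase": 1.0 / 9.0,
    "nag": 1.0 / 9.0,
    "acid_phosphatase": 1.0 / 9.0,
    "bg_decomposition": 1.0 / 9.0,
    "ag_decomposition_microbes": 1.0 / 9.0,
    "ag_decomposition_microbes_fauna": 1.0 / 9.0,
}


def default_service_map(flat_soil_health: bool = False) -> "ServiceMap":
    """Build the default function-to-service map.

    ``flat_soil_health=True`` swaps the hierarchical soil-health shares for
    an equal 1/7 per function.
    """
    shares: dict[str, float] = {}
    for service in SERVICES:
        members = [fn for fn, s in FUNCTION_SERVICE.items() if s == service]
        if service == "soil_health" and not flat_soil_health:
            for fn in members:
                shares[fn] = HIERARCHICAL_SOIL_HEALTH_SHARES[fn]
        else:
            for fn in members:
                shares[fn] = 1.0 / len(members)
    return ServiceMap(function_service=dict(FUNCTION_SERVICE), within_shares=shares)


@dataclass(frozen=True)
class ServiceMap:
    """Maps each function to a service, with within-service shares."""

    function_service: dict[str, str]
    within_shares: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.function_service) != set(CANONICAL_FUNCTIONS):
            raise ConfigurationError(
                "service map must cover exactly the canonical functions"
            )
        for service in set(self.function_service.values()):
            total = sum(
                self.within_shares[fn]
                for fn, s in self.function_service.items()
                if s == service
            )
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"within-service shares for {service!r} sum to {total}, not 1"
                )

    def functions_of(self, service: str) -> list[str]:
        return [fn for fn, s in self.function_service.items() if s == service]


@dataclass(frozen=True)
class WeightingScheme:
    """A named weight vector over ecosystem functions, summing to 1."""

    name: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.weights) - set(CANONICAL_FUNCTIONS)
        if unknown:
            raise ConfigurationError(f"unknown functions in scheme: {sorted(unknown)}")
        if any(w < 0 for w in self.weights.values()):
            raise ConfigurationError("scheme weights must be nonnegative")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"scheme {self.name!r} weights sum to {total}, not 1"
            )

    def subset(self, functions: Sequence[str], name: str | None = None) -> "WeightingScheme":
        """Restrict to a function subset and renormalize to sum 1."""
        kept = {fn: self.weights[fn] for fn in functions if fn in self.weights}
        total = sum(kept.values())
        if total <= 0:
            raise ConfigurationError(
                "subset carries zero total weight; cannot renormalize"
            )
        return WeightingScheme(
            name=name or f"{self.name}_subset",
            weights={fn: w / total for fn, w in kept.items()},
        )


#: Final stakeholder service-preference vectors (percent).  The farmers
#: vector is as published (it sums to 102 and is renormalized on use); the
#: other three groups are illustrative defaults qualitatively matching the
#: described preference patterns and are fully configurable.
PRINTED_PREFERENCES: dict[str, dict[str, float]] = {
    "farmers": {
        "food_production": 38.0,
        "biodiversity_conservation": 18.0,
        "soil_health": 18.0,
        "landscape_aesthetics": 14.0,
        "climate_regulation": 7.0,
        "water_quality": 7.0,
    },
    "local_residents": {
        "food_production": 30.0,
        "landscape_aesthetics": 28.0,
        "biodiversity_conservation": 12.0,
        "soil_health": 12.0,
        "climate_regulation": 9.0,
        "water_quality": 9.0,
    },
    "conservation_agencies": {
        "food_production": 8.0,
        "landscape_aesthetics": 8.0,
        "biodiversity_conservation": 24.0,
        "soil_health": 24.0,
        "climate_regulation": 18.0,
        "water_quality": 18.0,
    },
    "tourism": {
        "food_production": 14.0,
        "landscape_aesthetics": 40.0,
        "biodiversity_conservation": 13.0,
        "soil_health": 13.0,
        "climate_regulation": 10.0,
        "water_quality": 10.0,
    },
}

STAKEHOLDERS: tuple[str, ...] = tuple(PRINTED_PREFERENCES)


def transfer_preferences(original: Mapping[str, float]) -> dict[str, float]:
    """Transfer survey service preferences onto this study's six services.

    Steps: (1) food production is the mean of crop food production and
    livestock production (or taken directly if already combined); (2) the
    supporting-class weight ("biodiversity" in the source) is halved and
    allocated to both biodiversity conservation and soil health; (3) the
    regulating-class weight ("carbon storage") is likewise split between
    climate regulation and water quality; (4) the result is renormalized to
    sum to 100.

    Note: this procedure does *not* reproduce the published worked example
    (44/29/16/11 -> 38/18/18/14/7/7); it yields 44/14.5/14.5/16/5.5/5.5.
    The published final vectors are available as
    :data:`PRINTED_PREFERENCES` fixtures instead.
    """
    src = dict(original)
    if any(v < 0 for v in src.values()):
        raise DomainError("source preferences must be nonnegative")
    if "food_production" in src:
        food = src["food_production"]
    elif "food_crops" in src and "livestock" in src:
        food = 0.5 * (src["food_crops"] + src["livestock"])
    else:
        raise ConfigurationError(
            "source must provide 'food_production' or both 'food_crops' and 'livestock'"
        )
    for key in ("biodiversity", "landscape_aesthetics", "carbon_storage"):
        if key not in src:
            raise ConfigurationError(f"source preference {key!r} missing")
    out = {
        "food_production": food,
        "biodiversity_conservation": 0.5 * src["biodiversity"],
        "soil_health": 0.5 * src["biodiversity"],
        "landscape_aesthetics": src["landscape_aesthetics"],
        "climate_regulation": 0.5 * src["carbon_storage"],
        "water_quality": 0.5 * src["carbon_storage"],
    }
    total = sum(out.values())
    if total <= 0:
        raise ConfigurationError("source preferences sum to zero")
    log.info("preference transfer intermediate vector: %s (total %.3f)", out, total)
    return {svc: 100.0 * w / total for svc, w in out.items()}


def build_weighting_scheme(
    kind: str,
    prefs: Mapping[str, float] | None = None,
    service_map: ServiceMap | None = None,
    name: str | None = None,
) -> WeightingScheme:
    """Build a function-level weighting scheme.

    ``kind`` is one of ``equal_function`` (every function 1/14),
    ``equal_service`` (every service 1/6 distributed by within-service
    shares) or ``stakeholder`` (service preferences, renormalized to 1,
    distributed by within-service shares; requires ``prefs``).
    """
    service_map = service_map or default_service_map()
    if kind == "equal_function":
        n = len(CANONICAL_FUNCTIONS)
        return WeightingScheme(
            name=name or "equal_function",
            weights={fn: 1.0 / n for fn in CANONICAL_FUNCTIONS},
        )
    if kind == "equal_service":
        prefs = {svc: 1.0 for svc in SERVICES}
        name = name or "equal_service"
    elif kind == "stakeholder":
        if prefs is None:
            raise ConfigurationError("stakeholder scheme requires service preferences")
        name = name or "stakeholder"
    else:
        raise ConfigurationError(f"unknown scheme kind {kind!r}")
    missing = set(SERVICES) - set(prefs)
    if missing:
        raise ConfigurationError(f"preferences missing services: {sorted(missing)}")
    total = sum(prefs[svc] for svc in SERVICES)
    if total <= 0:
        raise ConfigurationError("preferences do not sum to a positive total")
    if abs(total - 100.0) > 1e-9 and kind == "stakeholder":
        log.info("renormalizing preference vector summing to %.4g", total)
    weights = {
        fn: (prefs[service_map.function_service[fn]] / total)
        * service_map.within_shares[fn]
        for fn in CANONICAL_FUNCTIONS
    }
    return WeightingScheme(name=name, weights=weights)


def stakeholder_schemes(
    service_map: ServiceMap | None = None,
    preferences: Mapping[str, Mapping[str, float]] | None = None,
) -> dict[str, WeightingScheme]:
    """The four stakeholder schemes plus the two equal-weight schemes."""
    preferences = preferences or PRINTED_PREFERENCES
    schemes = {
        group: build_weighting_scheme(
            "stakeholder", prefs=prefs, service_map=service_map, name=group
        )
        for group, prefs in preferences.items()
    }
    schemes["equal_function"] = build_weighting_scheme("equal_function")
    schemes["equal_service"] = build_weighting_scheme(
        "equal_service", service_map=service_map
    )
    return schemes


def ecological_emf(normalized: pd.DataFrame, scheme: WeightingScheme) -> pd.Series:
    """Weighted average of normalized function levels, per plot.

    ``normalized`` is a per-plot table (rows: plots, columns: functions)
    with values in [0, 1]; the dis-service nitrogen surplus must already be
    direction-inverted by the normalization stage.  Returns a Series named
    after the scheme, with values in [0, 1].
    """
    missing = [fn for fn in scheme.weights if fn not in normalized.columns]
    if missing:
        raise MissingDataError(
            f"normalized table lacks functions required by scheme "
            f"{scheme.name!r}: {missing}"
        )
    cols = list(scheme.weights)
    block = normalized[cols].to_numpy(dtype=float)
    if np.isnan(block).any():
        raise MissingDataError("normalized table contains missing values")
    if ((block < -1e-12) | (block > 1 + 1e-12)).any():
        raise DomainError("normalized function levels must lie in [0, 1]")
    alpha = np.array([scheme.weights[fn] for fn in cols])
    return pd.Series(block @ alpha, index=normalized.index, name=scheme.name)
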