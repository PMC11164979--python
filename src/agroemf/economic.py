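"""Monetary valuation of ecosystem services.

Economic multifunctionality (enEMF) sums the per-hectare monetary values of
food production, climate regulation (soil carbon flux at a CO2 accounting
price), water quality (nitrogen surplus at a social cost), and the natural
insurance values of soil biodiversity and soil health.

The insurance valuation works in three steps: (1) the risk premium a
risk-averse farmer would pay to stabilize a lognormally distributed annual
yield, RP = mean * (1 - (1 + CV^2)^(-r/2)); (2) a quadratic response
surface RP(b, h) = x1 + x2 b + x3 b^2 + x4 h + x5 h^2 + x6 b h fitted over
plots; (3) insurance values as risk-premium differences on that surface:
I_B = RP(0, h) - RP(b, h), I_H = RP(b, 0) - RP(b, h),
I_HB = RP(0, 0) - RP(b, h).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np

from ._errors import (
    CollinearityError,
    ConfigurationError,
    DomainError,
    InsufficientDataError,
    MissingDataError,
)
from .constants import DEFAULT_SOIL, SoilConstants

log = logging.getLogger(__name__)

#: Relative risk aversion of a slightly risk-averse farmer.
DEFAULT_RISK_AVERSION = 0.28

#: Placeholder producer prices (EUR / dt); the authoritative per-crop price
#: table is supplementary material and not reproduced here.  These defaults
#: exist so the pipeline is runnable and are clearly non-authoritative.
DEFAULT_PRODUCER_PRICES: dict[str, float] = {
    "wheat_grain": 18.0,
    "wheat_straw": 5.0,
    "barley_grain": 16.0,
    "barley_straw": 5.0,
    "rape_grain": 38.0,
    "legume_biomass": 14.0,
    "grass_biomass": 9.0,
    "biomass": 9.0,
}


@dataclass(frozen=True)
class PriceSet:
    """Accounting prices for one valuation scenario."""

    name: str = "default"
    producer_prices: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PRODUCER_PRICES)
    )
    co2_price: float = 195.0  # EUR / t CO2 (social cost)
    n_price: float = 7.30  # EUR / kg N surplus (leaching into surface water)
    crop_price_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.co2_price < 0 or self.n_price < 0 or self.crop_price_multiplier < 0:
            raise ConfigurationError("accounting prices must be nonnegative")
        if any(p < 0 for p in self.producer_prices.values()):
            raise ConfigurationError("producer prices must be nonnegative")


def price_scenarios() -> dict[str, PriceSet]:
    """The default scenario and the four sensitivity variants."""
    return {
        "default": PriceSet(name="default"),
        "co2_280": PriceSet(name="co2_280", co2_price=280.0),
        "co2_90": PriceSet(name="co2_90", co2_price=90.0),
        "n_1.9": PriceSet(name="n_1.9", n_price=1.9),
        "crop_+40%": PriceSet(name="crop_+40%", crop_price_multiplier=1.4),
    }


def food_production_value(masses: Mapping[str, float], prices: PriceSet) -> float:
    """Market value of harvested biomass (EUR / ha).

    ``masses`` maps product name (e.g. grain and straw separately for
    crops, summed cuts for grassland) to dt/ha.  Every product must be
    priced; the scenario's crop price multiplier applies to all products.
    """
    total = 0.0
    for product, mass in masses.items():
        if mass < 0:
            raise DomainError(f"negative mass for product {product!r}")
        if product not in prices.producer_prices:
            raise ConfigurationError(f"no producer price for product {product!r}")
        total += mass * prices.producer_prices[product]
    return total * prices.crop_price_multiplier


def climate_regulation_value(
    c_flux: float, prices: PriceSet, constants: SoilConstants = DEFAULT_SOIL
) -> float:
    """Value of the net soil carbon flux (EUR / ha / yr).

    ``c_flux`` is in t C/ha/yr and may be negative (carbon loss is a cost).
    """
    return c_flux * constants.c_to_co2 * prices.co2_price


def water_quality_value(n_surplus: float, prices: PriceSet) -> float:
    """(Non-positive) social cost of the nitrogen surplus (EUR / ha / yr).

    A positive surplus is costed at the scenario's social price per kg N;
    a zero or negative surplus yields zero (no credit for a deficit).
    """
    return -max(n_surplus, 0.0) * prices.n_price


@dataclass(frozen=True)
class YieldSeries:
    """Summary of a plot's annual monetary yields."""

    mean: float
    cv: float
    n_years: int

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise DomainError("coefficient of variation cannot be negative")


def yield_cv(series: Sequence[float], ddof: int = 1) -> YieldSeries:
    """Mean and coefficient of variation of an annual yield series.

    Uses the sample (n-1) standard deviation by default; pass ``ddof=0``
    for the population variant.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 2:
        raise InsufficientDataError(
            f"need at least 2 years for a CV, got {y.size}"
        )
    if not np.isfinite(y).all():
        raise DomainError("non-finite yield values")
    mean = float(y.mean())
    if mean <= 0:
        raise DomainError("mean yield must be positive for a CV")
    return YieldSeries(mean=mean, cv=float(y.std(ddof=ddof) / mean), n_years=y.size)


def risk_premium(mean_y: float, cv: float, r: float = DEFAULT_RISK_AVERSION) -> float:
    """Risk premium of a lognormal yield under constant relative risk aversion.

    RP = mean * (1 - (1 + CV^2)^(-r/2)); the second term is the certainty
    equivalent.  RP is zero at CV = 0 or r = 0 and below the mean for r > 0.
    """
    if mean_y < 0:
        raise DomainError("mean yield cannot be negative")
    if cv < 0:
        raise DomainError("coefficient of variation cannot be negative")
    if r < 0:
        raise DomainError("risk aversion cannot be negative")
    return mean_y * (1.0 - (1.0 + cv * cv) ** (-r / 2.0))


def _surface_design(b: np.ndarray, h: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(b), b, b * b, h, h * h, b * h])


@dataclass(frozen=True)
class RPSurface:
    """Fitted quadratic risk-premium response surface RP(b, h)."""

    coefficients: tuple[float, float, float, float, float, float]
    r_squared: float = float("nan")
    residual_sd: float = float("nan")
    b_range: tuple[float, float] = (0.0, 1.0)
    h_range: tuple[float, float] = (0.0, 1.0)

    def rp(self, b: float, h: float) -> float:
        x1, x2, x3, x4, x5, x6 = self.coefficients
        return x1 + x2 * b + x3 * b * b + x4 * h + x5 * h * h + x6 * b * h

    def _check_range(self, b: float, h: float) -> None:
        if not (self.b_range[0] <= b <= self.b_range[1]) or not (
            self.h_range[0] <= h <= self.h_range[1]
        ):
            warnings.warn(
                f"evaluating RP surface outside the fitted range at (b={b}, h={h})",
                stacklevel=3,
            )

    def insurance(self, b: float, h: float) -> "InsuranceValues":
        """Insurance values at a (b, h) point, on the fitted surface."""
        self._check_range(b, h)
        rp_bh = self.rp(b, h)
        return InsuranceValues(
            i_b=self.rp(0.0, h) - rp_bh,
            i_h=self.rp(b, 0.0) - rp_bh,
            i_hb=self.rp(0.0, 0.0) - rp_bh,
        )


@dataclass(frozen=True)
class InsuranceValues:
    """Natural insurance values (EUR / ha) at one (b, h) point."""

    i_b: float
    i_h: float
    i_hb: float


def fit_rp_surface(
    b: Sequence[float], h: Sequence[float], rp: Sequence[float]
) -> RPSurface:
    """Least-squares fit of the quadratic RP(b, h) response surface.

    Requires at least 6 observations and a full-rank design (e.g. all-equal
    b values make the quadratic unidentifiable and raise
    :class:`CollinearityError`).
    """
    b = np.asarray(b, dtype=float)
    h = np.asarray(h, dtype=float)
    y = np.asarray(rp, dtype=float)
    if not (b.size == h.size == y.size):
        raise ConfigurationError("b, h and rp must have equal length")
    if b.size < 6:
        raise InsufficientDataError(
            f"need at least 6 observations to fit 6 coefficients, got {b.size}"
        )
    X = _surface_design(b, h)
    rank = np.linalg.matrix_rank(X)
    if rank < 6:
        raise CollinearityError(
            f"design matrix rank {rank} < 6; surface coefficients not identifiable"
        )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    resid = y - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(y.size - 6, 1)
    return RPSurface(
        coefficients=tuple(float(c) for c in coef),
        r_squared=r2,
        residual_sd=float(np.sqrt(ss_res / dof)),
        b_range=(float(b.min()), float(b.max())),
        h_range=(float(h.min()), float(h.max())),
    )


def insurance_values(surface: RPSurface, b: float, h: float) -> InsuranceValues:
    """Insurance values I_B, I_H, I_HB at (b, h) on a fitted surface."""
    return surface.insurance(b, h)


@dataclass(frozen=True)
class EconomicResult:
    """Per-plot monetary service values and their totals (EUR / ha / yr)."""

    food_production: float
    climate_regulation: float
    water_quality: float
    biodiversity_insurance: float
    soil_health_insurance: float
    joint_insurance: float = float("nan")

    @property
    def enemf(self) -> float:
        """Economic multifunctionality: sum of all five service values."""
        return (
            self.food_production
            + self.climate_regulation
            + self.water_quality
            + self.biodiversity_insurance
            + self.soil_health_insurance
        )

    @property
    def farmer_value(self) -> float:
        """Value accruing to the farmer: food plus the two insurance services."""
        return (
            self.food_production
            + self.biodiversity_insurance
            + self.soil_health_insurance
        )


def economic_totals(components: Mapping[str, float]) -> EconomicResult:
    """Assemble an :class:`EconomicResult` from named component values.

    Required keys: ``food_production, climate_regulation, water_quality,
    biodiversity_insurance, soil_health_insurance``.  The optional
    ``joint_insurance`` (I_HB) is carried for transparency but not summed,
    since enEMF books the two insurance services separately.
    """
    required = (
        "food_production",
        "climate_regulation",
        "water_quality",
        "biodiversity_insurance",
        "soil_health_insurance",
    )
    missing = [k for k in required if k not in components]
    if missing:
        raise MissingDataError(f"missing economic components: {missing}")
    return EconomicResult(
        food_production=float(components["food_production"]),
        climate_regulation=float(components["climate_regulation"]),
        water_quality=float(components["water_quality"]),
        biodiversity_insurance=float(components["biodiversity_insurance"]),
        soil_health_insurance=float(components["soil_health_insurance"]),
        joint_insurance=float(components.get("joint_insurance", float("nan"))),
    )
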