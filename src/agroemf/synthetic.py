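"""Synthetic split-plot designs, function panels and classifier fixtures.

The generator emulates the statistical structure the downstream analysis
assumes: a balanced split-plot layout (climate on mainplots, land-use type
on subplots), multiplicative climate and management effects per function,
lognormally distributed annual yields whose coefficient of variation is a
function of latent plot traits (soil biodiversity *b* and soil health *h*
on the [0, 1] scale), truncated-Gaussian noise on all other functions, and
raster images with exact known flower-color pixel fractions.

No attempt is made to simulate realistic agronomy; the defaults are
illustrative and exist so that every downstream stage has testable ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import stats as sps

from ._errors import ConfigurationError, DomainError, FixtureError, InvalidDesignError
from .flowers import classify_pixel
from .functions import BIODIVERSITY_FUNCTIONS, CANONICAL_FUNCTIONS

LAND_USE_TYPES: tuple[str, ...] = ("EM", "EP", "IM", "OF", "CF")
CLIMATES: tuple[str, ...] = ("ambient", "future")

MANAGEMENT: dict[str, str] = {
    "EM": "sustainable",
    "EP": "sustainable",
    "OF": "sustainable",
    "IM": "intensive",
    "CF": "intensive",
}
COVER: dict[str, str] = {
    "EM": "grassland",
    "EP": "grassland",
    "IM": "grassland",
    "OF": "cropland",
    "CF": "cropland",
}

#: Per-function baseline means under ambient climate / sustainable management.
DEFAULT_BASELINES: dict[str, float] = {
    "yield": 80.0,
    "toc_flux": 0.8,
    "n_surplus": 15.0,
    "microbial_biomass": 300.0,
    "cellulase": 120.0,
    "nag": 80.0,
    "acid_phosphatase": 150.0,
    "bg_decomposition": 0.45,
    "ag_decomposition_microbes": 0.35,
    "ag_decomposition_microbes_fauna": 0.55,
    "nematode_diversity": 2.0,
    "mesofauna_diversity": 1.6,
    "macrofauna_diversity": 1.4,
    "flower_abundance": 3.0,
}

DEFAULT_UNITS: dict[str, str] = {
    "yield": "dt/ha",
    "toc_flux": "t C/ha/yr",
    "n_surplus": "kg N/ha",
    "microbial_biomass": "ug C/g dry soil",
    "cellulase": "nmol/h/g dry soil",
    "nag": "nmol/h/g dry soil",
    "acid_phosphatase": "nmol/h/g dry soil",
    "bg_decomposition": "fraction",
    "ag_decomposition_microbes": "fraction",
    "ag_decomposition_microbes_fauna": "fraction",
    "nematode_diversity": "shannon H",
    "mesofauna_diversity": "shannon H",
    "macrofauna_diversity": "shannon H",
    "flower_abundance": "percent",
}

#: Multiplicative effect of the future-climate treatment (unlisted: 1.0).
DEFAULT_CLIMATE_EFFECTS: dict[str, float] = {
    "yield": 0.85,
    "flower_abundance": 0.6,
    "ag_decomposition_microbes": 0.85,
    "ag_decomposition_microbes_fauna": 0.85,
    "n_surplus": 1.2,
}

#: Multiplicative effect of intensive management (unlisted: 1.0).
DEFAULT_MANAGEMENT_EFFECTS: dict[str, float] = {
    "yield": 1.15,
    "n_surplus": 4.0,
    "flower_abundance": 0.3,
    "nematode_diversity": 0.75,
    "mesofauna_diversity": 0.75,
    "macrofauna_diversity": 0.75,
    "microbial_biomass": 0.85,
    "cellulase": 0.85,
    "nag": 0.85,
    "acid_phosphatase": 0.85,
    "bg_decomposition": 0.85,
}


@dataclass(frozen=True)
class CVModel:
    """Linear model for the yield coefficient of variation.

    CV(b, h) = intercept + b_slope * b + h_slope * h, with b, h in [0, 1].
    Must be nonnegative over the whole unit square (checked at the corners,
    sufficient for a linear form).
    """

    intercept: float = 0.30
    b_slope: float = -0.15
    h_slope: float = -0.05

    def __post_init__(self) -> None:
        corners = [
            self.intercept + self.b_slope * b + self.h_slope * h
            for b in (0.0, 1.0)
            for h in (0.0, 1.0)
        ]
        if min(corners) < 0:
            raise ConfigurationError(
                "CV model goes negative on the (b, h) unit square; "
                f"corner values {corners}"
            )

    def cv(self, b: float, h: float) -> float:
        return self.intercept + self.b_slope * b + self.h_slope * h


@dataclass
class SimulationParams:
    """Everything the panel generator needs besides the design table."""

    years: Sequence[int] = tuple(range(2016, 2021))
    baselines: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    units: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_UNITS))
    climate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLIMATE_EFFECTS)
    )
    management_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MANAGEMENT_EFFECTS)
    )
    cv_model: CVModel = field(default_factory=CVModel)
    #: absolute Gaussian noise sd per non-yield function; ``None`` defaults to
    #: 5% of each baseline, an explicit dict is used as given (missing: 0.0)
    noise_sd: dict[str, float] | None = None
    #: latent trait means per management regime
    b_means: dict[str, float] = field(
        default_factory=lambda: {"sustainable": 0.70, "intensive": 0.35}
    )
    h_means: dict[str, float] = field(
        default_factory=lambda: {"sustainable": 0.65, "intensive": 0.40}
    )
    trait_sd: float = 0.08
    #: couple diversity / soil-health function means to the latent traits
    trait_coupling: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.baselines) - set(CANONICAL_FUNCTIONS)
        if unknown:
            raise ConfigurationError(f"unknown function names in baselines: {sorted(unknown)}")
        for extra in (self.climate_effects, self.management_effects, self.noise_sd or {}):
            unknown = set(extra) - set(CANONICAL_FUNCTIONS)
            if unknown:
                raise ConfigurationError(
                    f"unknown function names in effect/noise maps: {sorted(unknown)}"
                )
        if any(m <= 0 for m in self.baselines.values()):
            raise ConfigurationError("all baseline means must be positive")
        if self.noise_sd is None:
            self.noise_sd = {
                fn: 0.05 * mean for fn, mean in self.baselines.items() if fn != "yield"
            }
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ConfigurationError("noise_sd must be nonnegative")
        if len(self.years) == 0:
            raise ConfigurationError("at least one simulation year is required")
        if self.trait_sd < 0:
            raise ConfigurationError("trait_sd must be nonnegative")


def generate_design(n_mainplots: int, seed: int = 0) -> pd.DataFrame:
    """Generate a balanced split-plot design table.

    Climates are assigned half/half to mainplots and the land-use order is
    randomized within each mainplot, both under ``seed``.  Returns one row
    per plot with plot_id, mainplot_id, climate, lut, management and cover.
    """
    if n_mainplots < 2 or n_mainplots % 2 != 0:
        raise InvalidDesignError(
            f"n_mainplots must be even and >= 2, got {n_mainplots}"
        )
    rng = np.random.default_rng(seed)
    climates = np.array(
        ["ambient"] * (n_mainplots // 2) + ["future"] * (n_mainplots // 2)
    )
    rng.shuffle(climates)
    rows = []
    for i in range(n_mainplots):
        mainplot = f"M{i + 1:02d}"
        for lut in rng.permutation(LAND_USE_TYPES):
            rows.append(
                {
                    "plot_id": f"{mainplot}-{lut}",
                    "mainplot_id": mainplot,
                    "climate": climates[i],
                    "lut": lut,
                    "management": MANAGEMENT[lut],
                    "cover": COVER[lut],
                }
            )
    return pd.DataFrame(rows)


def validate_design(design: pd.DataFrame) -> None:
    """Check split-plot design invariants; raise :class:`InvalidDesignError`."""
    required = {"plot_id", "mainplot_id", "climate", "lut"}
    missing = required - set(design.columns)
    if missing:
        raise InvalidDesignError(f"design lacks columns: {sorted(missing)}")
    per_mainplot = design.groupby("mainplot_id")["lut"].apply(
        lambda s: sorted(s) == sorted(LAND_USE_TYPES)
    )
    if not per_mainplot.all():
        bad = per_mainplot[~per_mainplot].index.tolist()
        raise InvalidDesignError(
            f"mainplot(s) missing or duplicating land-use types: {bad}"
        )
    nclim = design.groupby("mainplot_id")["climate"].nunique()
    if (nclim != 1).any():
        raise InvalidDesignError("climate varies within a mainplot")
    counts = design.groupby("mainplot_id").size()
    if counts.nunique() != 1:
        raise InvalidDesignError("mainplots have unequal plot counts")


def assign_traits(design: pd.DataFrame, params: SimulationParams) -> pd.DataFrame:
    """Latent (b, h) traits per plot, deterministic given the params seed.

    Trait draws use a dedicated random substream so that the traits are
    reproducible independently of panel noise.
    """
    rng = np.random.default_rng([params.seed, 1])
    rows = []
    for _, plot in design.iterrows():
        mgmt = plot.get("management", MANAGEMENT[plot["lut"]])
        b = float(np.clip(rng.normal(params.b_means[mgmt], params.trait_sd), 0.0, 1.0))
        h = float(np.clip(rng.normal(params.h_means[mgmt], params.trait_sd), 0.0, 1.0))
        rows.append({"plot_id": plot["plot_id"], "b": b, "h": h})
    return pd.DataFrame(rows).set_index("plot_id")


def _trait_multiplier(fn: str, b: float, h: float, params: SimulationParams) -> float:
    """Monotone trait coupling: diversity scales with b, soil health with h.

    The multiplier is 1 at trait level 0.5 so that baselines stay centered.
    """
    if not params.trait_coupling:
        return 1.0
    if fn in BIODIVERSITY_FUNCTIONS:
        return 0.5 + b
    if fn in (
        "microbial_biomass",
        "cellulase",
        "nag",
        "acid_phosphatase",
        "bg_decomposition",
        "ag_decomposition_microbes",
        "ag_decomposition_microbes_fauna",
    ):
        return 0.5 + h
    return 1.0


def generate_function_panel(
    design: pd.DataFrame, params: SimulationParams
) -> pd.DataFrame:
    """Simulate a long-format function panel for a design.

    Annual yields are lognormal with plot-level CV from ``params.cv_model``
    evaluated at the plot's latent traits; every other function gets
    zero-truncated Gaussian noise.  Effects are multiplicative.  The result
    is bit-identical for identical params (seed included).
    """
    validate_design(design)
    traits = assign_traits(design, params)
    rng = np.random.default_rng([params.seed, 2])
    years = [int(y) for y in params.years]
    records: list[dict] = []
    for _, plot in design.iterrows():
        pid = plot["plot_id"]
        mgmt = plot.get("management", MANAGEMENT[plot["lut"]])
        b, h = traits.at[pid, "b"], traits.at[pid, "h"]
        for fn, baseline in params.baselines.items():
            target = baseline
            if plot["climate"] == "future":
                target *= params.climate_effects.get(fn, 1.0)
            if mgmt == "intensive":
                target *= params.management_effects.get(fn, 1.0)
            target *= _trait_multiplier(fn, b, h, params)
            if fn == "yield":
                cv = params.cv_model.cv(b, h)
                if cv > 0:
                    sigma2 = np.log1p(cv * cv)
                    mu = np.log(target) - sigma2 / 2.0
                    values = rng.lognormal(mu, np.sqrt(sigma2), size=len(years))
                else:
                    values = np.full(len(years), target)
            else:
                sd = params.noise_sd.get(fn, 0.0)
                if sd > 0:
                    a = (0.0 - target) / sd  # truncate at zero
                    values = sps.truncnorm.rvs(
                        a, np.inf, loc=target, scale=sd, size=len(years), random_state=rng
                    )
                else:
                    values = np.full(len(years), target)
            for year, value in zip(years, values):
                records.append(
                    {
                        "plot_id": pid,
                        "mainplot_id": plot["mainplot_id"],
                        "climate": plot["climate"],
                        "lut": plot["lut"],
                        "year": year,
                        "function": fn,
                        "value": float(value),
                        "unit": params.units.get(fn, ""),
                    }
                )
    return pd.DataFrame.from_records(records)


#: Canonical representative color per flower class (violet has none: the
#: literal violet rule is unsatisfiable, see :mod:`agroemf.flowers`).
CANONICAL_COLORS: dict[str, tuple[int, int, int]] = {
    "red": (255, 0, 0),
    "orange": (255, 150, 100),
    "blue": (0, 0, 255),
    "white": (255, 255, 255),
    "yellow": (255, 255, 0),
}

DEFAULT_BACKGROUND: tuple[int, int, int] = (0, 255, 0)


def generate_plot_image(
    width: int,
    height: int,
    color_fractions: Mapping[str, float] | None = None,
    background: tuple[int, int, int] = DEFAULT_BACKGROUND,
    seed: int = 0,
) -> Image.Image:
    """Build an RGB image with exact known flower-pixel fractions.

    Each requested class gets exactly ``round(fraction * width * height)``
    pixels of its canonical color at positions randomized under ``seed``;
    the remainder is background.  The background must not match any flower
    rule, or the fixture's ground truth would be corrupted.
    """
    if width <= 0 or height <= 0:
        raise DomainError("image dimensions must be positive")
    fractions = dict(color_fractions or {})
    unknown = set(fractions) - set(CANONICAL_COLORS)
    if "violet" in unknown:
        raise FixtureError(
            "no color can satisfy the literal violet rule; "
            "a violet fixture cannot be constructed"
        )
    if unknown:
        raise FixtureError(f"unknown flower classes requested: {sorted(unknown)}")
    if any(f < 0 for f in fractions.values()):
        raise FixtureError("color fractions must be nonnegative")
    if sum(fractions.values()) > 1.0 + 1e-12:
        raise FixtureError("color fractions sum to more than 1")
    if classify_pixel(*background) is not None:
        raise FixtureError(
            f"background color {background} matches the "
            f"{classify_pixel(*background)!r} flower rule"
        )
    total = width * height
    counts = {cls: round(frac * total) for cls, frac in fractions.items()}
    if sum(counts.values()) > total:
        raise FixtureError("rounded pixel counts exceed the image size")
    rng = np.random.default_rng(seed)
    order = rng.permutation(total)
    arr = np.empty((total, 3), dtype=np.uint8)
    arr[:] = background
    start = 0
    for cls in sorted(counts):
        n = counts[cls]
        arr[order[start : start + n]] = CANONICAL_COLORS[cls]
        start += n
    return Image.fromarray(arr.reshape(height, width, 3), mode="RGB")
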