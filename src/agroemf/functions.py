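"""Ingestion and aggregation of ecosystem-function panels.

The long-format *function panel* (one row per plot x year x function) is the
interchange format between all pipeline stages.  This module aggregates it
to per-plot means, normalizes functions to the unit interval against the
observed range, and computes the derived functions and composites: Shannon
diversity, soil multidiversity, soil health, bait-lamina consumption,
litterbag mass loss, microbial biomass from the respiratory response,
nitrogen surplus, and soil carbon stocks/fluxes.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import (
    ConfigurationError,
    DegenerateRangeError,
    DomainError,
    EmptyCommunityError,
    MassGainError,
    MissingDataError,
)
from .constants import DEFAULT_SOIL, SoilConstants

#: The 14 canonical ecosystem-function names accepted in panels.
CANONICAL_FUNCTIONS: tuple[str, ...] = (
    "yield",
    "toc_flux",
    "n_surplus",
    "microbial_biomass",
    "cellulase",
    "nag",
    "acid_phosphatase",
    "bg_decomposition",
    "ag_decomposition_microbes",
    "ag_decomposition_microbes_fauna",
    "nematode_diversity",
    "mesofauna_diversity",
    "macrofauna_diversity",
    "flower_abundance",
)

#: Functions whose larger values indicate *worse* outcomes (dis-services).
DECREASING_FUNCTIONS: tuple[str, ...] = ("n_surplus",)

#: The three soil-biodiversity functions (excluded from the 11-function index).
BIODIVERSITY_FUNCTIONS: tuple[str, ...] = (
    "nematode_diversity",
    "mesofauna_diversity",
    "macrofauna_diversity",
)

ENZYME_FUNCTIONS: tuple[str, ...] = ("cellulase", "nag", "acid_phosphatase")
DECOMPOSITION_FUNCTIONS: tuple[str, ...] = (
    "bg_decomposition",
    "ag_decomposition_microbes",
    "ag_decomposition_microbes_fauna",
)


def validate_panel(panel: pd.DataFrame) -> None:
    """Check a long-format panel for canonical names and finite values."""
    required = {"plot_id", "year", "function", "value"}
    missing = required - set(panel.columns)
    if missing:
        raise ConfigurationError(f"panel lacks required columns: {sorted(missing)}")
    unknown = set(panel["function"]) - set(CANONICAL_FUNCTIONS)
    if unknown:
        raise ConfigurationError(
            f"unknown function names in panel: {sorted(unknown)}; "
            f"accepted names are {list(CANONICAL_FUNCTIONS)}"
        )
    values = pd.to_numeric(panel["value"], errors="coerce")
    if not np.isfinite(values.to_numpy(dtype=float)).all():
        raise DomainError("panel contains non-finite or non-numeric values")
    if "unit" in panel.columns:
        nunits = panel.groupby("function")["unit"].nunique()
        bad = nunits[nunits > 1]
        if len(bad):
            raise ConfigurationError(
                f"inconsistent units within function(s): {list(bad.index)}"
            )


def aggregate_panel(
    panel: pd.DataFrame,
    years: Mapping[str, Iterable[int]] | None = None,
) -> pd.DataFrame:
    """Mean value over (optionally per-function) year sets, per plot.

    Parameters
    ----------
    panel:
        Long table with columns ``plot_id, year, function, value``.
    years:
        Optional mapping ``function -> iterable of years`` restricting the
        years averaged for that function.  Functions not listed use all
        available years.

    Returns
    -------
    Wide table indexed by ``plot_id`` with one column per function.
    """
    validate_panel(panel)
    years = dict(years or {})
    unknown = set(years) - set(CANONICAL_FUNCTIONS)
    if unknown:
        raise ConfigurationError(f"year sets given for unknown functions: {sorted(unknown)}")

    parts = []
    for fn, sub in panel.groupby("function", sort=False):
        if fn in years:
            keep = set(int(y) for y in years[fn])
            sub = sub[sub["year"].astype(int).isin(keep)]
        parts.append(sub)
    selected = pd.concat(parts, ignore_index=True)

    wide = selected.pivot_table(
        index="plot_id", columns="function", values="value", aggfunc="mean"
    )
    # every plot in the panel must keep every function it is asked for
    all_plots = panel["plot_id"].unique()
    all_fns = panel["function"].unique()
    wide = wide.reindex(index=all_plots, columns=all_fns)
    if wide.isna().any().any():
        holes = [
            (plot, fn)
            for plot in wide.index
            for fn in wide.columns
            if pd.isna(wide.at[plot, fn])
        ]
        raise MissingDataError(
            "no values in the requested years for plot/function pairs: "
            + ", ".join(f"{p}:{f}" for p, f in holes[:10])
        )
    wide.columns.name = None
    wide.index.name = "plot_id"
    return wide


def minmax_normalize(values, direction: str = "increasing") -> np.ndarray:
    """Scale values to [0, 1] against the observed min and max.

    ``direction="increasing"`` maps the minimum to 0 and the maximum to 1;
    ``direction="decreasing"`` reflects the scale so that the *best* (lowest)
    value maps to 1.  A degenerate range (all values equal) raises rather
    than silently emitting constants.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DomainError("min-max normalization needs at least two values")
    if not np.isfinite(x).all():
        raise DomainError("non-finite values in normalization input")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateRangeError(
            f"all {x.size} values identical ({lo}); normalization undefined"
        )
    if direction == "increasing":
        return (x - lo) / (hi - lo)
    if direction == "decreasing":
        return (hi - x) / (hi - lo)
    raise ConfigurationError(f"unknown direction {direction!r}")


def normalize_table(
    means: pd.DataFrame,
    directions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Min-max normalize every function column of a per-plot mean table.

    The default direction is increasing for every function except the
    dis-service ``n_surplus``, which is direction-inverted so that a low
    surplus scores high.
    """
    directions = dict(directions or {})
    out = {}
    for fn in means.columns:
        direction = directions.get(
            fn, "decreasing" if fn in DECREASING_FUNCTIONS else "increasing"
        )
        try:
            out[fn] = minmax_normalize(means[fn].to_numpy(), direction)
        except DegenerateRangeError as exc:
            raise DegenerateRangeError(f"function {fn!r}: {exc}") from exc
    return pd.DataFrame(out, index=means.index)


def shannon_index(counts: Sequence[float]) -> float:
    """Shannon diversity H = -sum p ln p over taxa with positive counts."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise DomainError("negative taxon counts")
    total = c.sum()
    if total == 0:
        raise EmptyCommunityError("all taxon counts are zero")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def soil_multidiversity(
    h_by_group: Mapping[str, float],
    max_by_group: Mapping[str, float],
) -> float:
    """Mean over organism groups of Shannon index / group maximum.

    Normalizing each group by its own observed maximum weights groups with
    different taxon richness equally; the result lies in [0, 1].
    """
    if not h_by_group:
        raise MissingDataError("no organism groups supplied")
    missing = set(h_by_group) - set(max_by_group)
    if missing:
        raise ConfigurationError(f"no maximum supplied for groups: {sorted(missing)}")
    ratios = []
    for group, h in h_by_group.items():
        hmax = max_by_group[group]
        if hmax <= 0:
            raise DomainError(f"group {group!r}: maximum must be positive")
        if h < 0:
            raise DomainError(f"group {group!r}: negative diversity")
        if h > hmax:
            raise DomainError(
                f"group {group!r}: diversity {h} exceeds group maximum {hmax}"
            )
        ratios.append(h / hmax)
    return float(np.mean(ratios))


def composite_mean(components: Sequence[float]) -> float:
    """Arithmetic mean of already-normalized components in [0, 1]."""
    x = np.asarray(components, dtype=float)
    if x.size == 0:
        raise MissingDataError("no components supplied")
    if ((x < 0) | (x > 1)).any():
        raise DomainError("composite components must lie in [0, 1]")
    return float(x.mean())


def soil_health(
    microbial_biomass: float,
    enzymes: Sequence[float],
    decomposition: Sequence[float],
) -> float:
    """Hierarchical soil-health composite.

    The three components — normalized microbial biomass, the enzymatic
    composite (mean of the three enzyme activities) and the decomposition
    composite (mean of the three decomposition measures) — enter with equal
    weight; the sub-components are averaged bottom-up first.
    """
    return composite_mean(
        [microbial_biomass, composite_mean(enzymes), composite_mean(decomposition)]
    )


_BAIT_SCORES = {"empty": 1.0, "partly": 0.5, "filled": 0.0}


def bait_lamina_consumption(hole_states: Sequence[str]) -> float:
    """Mean feeding score over bait-lamina holes (empty=1, partly=0.5, filled=0)."""
    if len(hole_states) == 0:
        raise MissingDataError("no bait-lamina holes scored")
    try:
        scores = [_BAIT_SCORES[state] for state in hole_states]
    except KeyError as exc:
        raise DomainError(
            f"unknown hole state {exc.args[0]!r}; expected empty/partly/filled"
        ) from exc
    return float(np.mean(scores))


def litterbag_mass_loss(initial_mass: float, final_mass: float) -> float:
    """Fractional mass loss (initial - final) / initial of a litterbag."""
    if initial_mass <= 0:
        raise DomainError("initial mass must be positive")
    if final_mass < 0:
        raise DomainError("final mass cannot be negative")
    if final_mass > initial_mass:
        raise MassGainError(
            f"final mass {final_mass} g exceeds initial mass {initial_mass} g"
        )
    return (initial_mass - final_mass) / initial_mass


def microbial_biomass_from_mirr(
    mirr: float, constants: SoilConstants = DEFAULT_SOIL
) -> float:
    """Microbial biomass (ug C / g dry soil) from the maximum initial
    respiratory response (ul O2 / g dry soil)."""
    if mirr < 0:
        raise DomainError("MIRR cannot be negative")
    return constants.mirr_factor * mirr


def nitrogen_surplus(
    nmin_x: float,
    n_input: float,
    n_deprivation: float,
    nmin_x1: float,
    variant: str = "literal",
) -> float:
    """Plot-level mineral nitrogen surplus (kg N / ha).

    ``variant="literal"`` follows the bookkeeping as stated — initial soil
    mineral N *plus* input *minus* harvest deprivation *plus* next-season
    soil mineral N.  ``variant="balance"`` is the mass-balance alternative
    that subtracts the next-season stock instead.  The two differ by exactly
    ``2 * nmin_x1``.
    """
    for name, v in (
        ("nmin_x", nmin_x),
        ("n_input", n_input),
        ("n_deprivation", n_deprivation),
        ("nmin_x1", nmin_x1),
    ):
        if v < 0:
            raise DomainError(f"{name} cannot be negative")
    if variant == "literal":
        return nmin_x + n_input - n_deprivation + nmin_x1
    if variant == "balance":
        return nmin_x + n_input - n_deprivation - nmin_x1
    raise ConfigurationError(f"unknown nitrogen-surplus variant {variant!r}")


def nmin_unit_convert(areal: float, constants: SoilConstants = DEFAULT_SOIL) -> float:
    """Convert areal mineral N (g N / m^2) to a concentration (mg N / kg dry soil).

    Assumes the nitrogen mixes into the top ``n_mixing_depth`` metres of soil
    at the configured bulk density: 1 m^2 holds depth x density kg of soil.
    """
    if areal < 0:
        raise DomainError("areal nitrogen cannot be negative")
    soil_mass = constants.n_mixing_depth * constants.bulk_density  # kg per m^2
    return areal * 1000.0 / soil_mass


def nmin_unit_invert(concentration: float, constants: SoilConstants = DEFAULT_SOIL) -> float:
    """Inverse of :func:`nmin_unit_convert` (mg/kg back to g/m^2)."""
    if concentration < 0:
        raise DomainError("concentration cannot be negative")
    soil_mass = constants.n_mixing_depth * constants.bulk_density
    return concentration * soil_mass / 1000.0


def carbon_stock(toc_percent: float, constants: SoilConstants = DEFAULT_SOIL) -> float:
    """Soil organic carbon stock (t C / ha) from a TOC percentage.

    The accounted soil mass per hectare is depth x bulk density x 10^4 m^2,
    i.e. 4050 t/ha at the defaults, of which ``toc_percent`` percent is carbon.
    """
    if toc_percent < 0:
        raise DomainError("TOC percentage cannot be negative")
    soil_t_per_ha = constants.c_accounting_depth * constants.bulk_density * 10000.0 / 1000.0
    return toc_percent / 100.0 * soil_t_per_ha


def carbon_stock_and_flux(
    toc_percent_by_year: Mapping[int, float],
    baseline_year: int,
    constants: SoilConstants = DEFAULT_SOIL,
) -> pd.DataFrame:
    """Per-year carbon stocks and mean annual fluxes versus the baseline year.

    Returns a frame indexed by year with columns ``stock`` (t C/ha) and
    ``flux`` (t C/ha/yr, NaN for the baseline year itself).  The flux at
    year x is (stock_x - stock_baseline) / (x - baseline).
    """
    years = {int(y): float(v) for y, v in toc_percent_by_year.items()}
    if baseline_year not in years:
        raise MissingDataError(f"baseline year {baseline_year} not in TOC series")
    if any(y < baseline_year for y in years):
        raise DomainError("TOC series contains years before the baseline year")
    base_stock = carbon_stock(years[baseline_year], constants)
    rows = []
    for year in sorted(years):
        stock = carbon_stock(years[year], constants)
        flux = np.nan if year == baseline_year else (stock - base_stock) / (year - baseline_year)
        rows.append({"year": year, "stock": stock, "flux": flux})
    return pd.DataFrame(rows).set_index("year")
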