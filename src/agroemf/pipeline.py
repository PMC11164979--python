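"""End-to-end orchestration: simulate -> functions -> EMF -> economics -> stats.

Each stage is a standalone function operating on plain DataFrames so the
CLI subcommands can run them individually on intermediate CSVs; the
:func:`run_pipeline` driver chains them, writes result CSVs, and records a
plain-text log with every constant used, the seed and the config hash.
"""

from __future__ import annotations

import datetime
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .constants import DEFAULT_SOIL
from .economic import (
    climate_regulation_value,
    fit_rp_surface,
    price_scenarios,
    risk_premium,
    water_quality_value,
    yield_cv,
)
from .functions import (
    BIODIVERSITY_FUNCTIONS,
    DECOMPOSITION_FUNCTIONS,
    ENZYME_FUNCTIONS,
    aggregate_panel,
    normalize_table,
)
from .stats import anova_with_posthoc, correlation_matrix, regress_biodiversity_emf
from .synthetic import assign_traits, generate_design, generate_function_panel
from .weighting import default_service_map, ecological_emf, stakeholder_schemes

log = logging.getLogger(__name__)


def simulate_stage(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Generate design, function panel and latent traits."""
    design = generate_design(config.n_mainplots, config.seed)
    params = config.simulation_params()
    panel = generate_function_panel(design, params)
    traits = assign_traits(design, params)
    return {"design": design, "panel": panel, "traits": traits}


def functions_stage(
    panel: pd.DataFrame, config: RunConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Aggregate the panel and derive normalized levels and composites."""
    config = config or RunConfig()
    means = aggregate_panel(panel, years=config.year_sets or None)
    normalized = normalize_table(means)

    # soil multidiversity: mean over groups of value / group maximum
    multidiv = (
        means[list(BIODIVERSITY_FUNCTIONS)] / means[list(BIODIVERSITY_FUNCTIONS)].max()
    ).mean(axis=1)
    # hierarchical soil health on normalized components
    soil_health = (
        normalized["microbial_biomass"]
        + normalized[list(ENZYME_FUNCTIONS)].mean(axis=1)
        + normalized[list(DECOMPOSITION_FUNCTIONS)].mean(axis=1)
    ) / 3.0
    # 11-function equal-weight multifunctionality (biodiversity excluded)
    non_bio = [c for c in normalized.columns if c not in BIODIVERSITY_FUNCTIONS]
    emf11 = normalized[non_bio].mean(axis=1)

    composites = pd.DataFrame(
        {"multidiversity": multidiv, "soil_health": soil_health, "emf11": emf11}
    )
    return {"means": means, "normalized": normalized, "composites": composites}


def emf_stage(normalized: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """Ecological multifunctionality per plot for every selected scheme."""
    config = config or RunConfig()
    service_map = default_service_map(flat_soil_health=config.flat_soil_health)
    schemes = stakeholder_schemes(service_map=service_map)
    out = {
        name: ecological_emf(normalized, schemes[name]) for name in config.schemes
    }
    frame = pd.DataFrame(out)
    frame.index.name = "plot_id"
    return frame


def econ_stage(
    panel: pd.DataFrame,
    means: pd.DataFrame,
    composites: pd.DataFrame,
    config: RunConfig | None = None,
) -> dict[str, object]:
    """Monetize services and compute enEMF per plot and price scenario.

    The risk-premium surface is fitted once on base-price monetary yields;
    insurance values scale linearly with the crop price multiplier, which
    is applied per scenario.
    """
    config = config or RunConfig()
    scenarios = price_scenarios()

    yields = panel[panel["function"] == "yield"]
    monetary = {
        pid: sub.sort_values("year")["value"].to_numpy() * config.yield_price
        for pid, sub in yields.groupby("plot_id")
    }
    plots = means.index.tolist()
    summaries = {pid: yield_cv(monetary[pid], ddof=config.cv_ddof) for pid in plots}
    rp = pd.Series(
        {
            pid: risk_premium(s.mean, s.cv, config.risk_aversion)
            for pid, s in summaries.items()
        }
    )
    b = composites["multidiversity"].reindex(plots)
    h = composites["soil_health"].reindex(plots)
    surface = fit_rp_surface(b.to_numpy(), h.to_numpy(), rp.reindex(plots).to_numpy())

    rows = []
    for scen_name in config.scenarios:
        prices = scenarios[scen_name]
        for pid in plots:
            ins = surface.insurance(float(b[pid]), float(h[pid]))
            mult = prices.crop_price_multiplier
            food = means.at[pid, "yield"] * config.yield_price * mult
            climate = climate_regulation_value(means.at[pid, "toc_flux"], prices)
            water = water_quality_value(means.at[pid, "n_surplus"], prices)
            i_b, i_h, i_hb = ins.i_b * mult, ins.i_h * mult, ins.i_hb * mult
            rows.append(
                {
                    "plot_id": pid,
                    "scenario": scen_name,
                    "food_production": food,
                    "climate_regulation": climate,
                    "water_quality": water,
                    "biodiversity_insurance": i_b,
                    "soil_health_insurance": i_h,
                    "joint_insurance": i_hb,
                    "risk_premium": rp[pid] * mult,
                    "enemf": food + climate + water + i_b + i_h,
                    "farmer_value": food + i_b + i_h,
                }
            )
    econ = pd.DataFrame(rows)
    return {"economic": econ, "surface": surface, "risk_premium": rp}


def stats_stage(
    design: pd.DataFrame,
    eg: pd.DataFrame,
    econ: pd.DataFrame,
    composites: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """ANOVA/post-hoc per response, biodiversity regression, correlations."""
    responses = {f"egEMF_{c}": eg[c] for c in eg.columns}
    base = econ[econ["scenario"] == econ["scenario"].iloc[0]].set_index("plot_id")
    responses["enEMF"] = base["enemf"]
    responses["farmer_value"] = base["farmer_value"]

    anova_rows, posthoc_rows = [], []
    for name, series in responses.items():
        table, posthoc = anova_with_posthoc(series, design)
        table = table.assign(response=name)
        posthoc = posthoc.assign(response=name, term=posthoc.attrs["term"])
        anova_rows.append(table)
        posthoc_rows.append(posthoc)
    anova = pd.concat(anova_rows, ignore_index=True)
    posthoc = pd.concat(posthoc_rows, ignore_index=True)

    climate_by_plot = design.set_index("plot_id")["climate"]
    fits = regress_biodiversity_emf(
        composites["emf11"], composites["multidiversity"], climate_by_plot
    )
    reg_rows = []
    for label, fit in fits.items():
        for term, row in fit.params.iterrows():
            reg_rows.append(
                {
                    "model": label,
                    "formula": fit.formula,
                    "term": term,
                    "coef": row["coef"],
                    "se": row["se"],
                    "t": row["t"],
                    "p": row["p"],
                    "r_squared": fit.r_squared,
                    "n": fit.n_obs,
                }
            )
    regression = pd.DataFrame(reg_rows)

    corr_vars = pd.DataFrame(responses)
    r, p = correlation_matrix(corr_vars)
    return {
        "anova": anova,
        "posthoc": posthoc,
        "regression": regression,
        "correlation_r": r,
        "correlation_p": p,
    }


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict[str, object]:
    """Run every stage; optionally write CSV outputs and a run log.

    Reruns with the same config are bit-identical for all deterministic
    stages.  Every output CSV carries the config hash and seed columns.
    """
    sim = simulate_stage(config)
    fx = functions_stage(sim["panel"], config)
    eg = emf_stage(fx["normalized"], config)
    econ = econ_stage(sim["panel"], fx["means"], fx["composites"], config)
    stats = stats_stage(sim["design"], eg, econ["economic"], fx["composites"])

    results: dict[str, object] = {**sim, **fx, "egemf": eg, **econ, **stats}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        chash = config.config_hash()
        tables = {
            "design": sim["design"],
            "panel": sim["panel"],
            "traits": sim["traits"].reset_index(),
            "means": fx["means"].reset_index(),
            "normalized": fx["normalized"].reset_index(),
            "composites": fx["composites"].reset_index(),
            "egemf": eg.reset_index(),
            "economic": econ["economic"],
            "anova": stats["anova"],
            "posthoc": stats["posthoc"],
            "regression": stats["regression"],
            "correlation_r": stats["correlation_r"].reset_index(),
            "correlation_p": stats["correlation_p"].reset_index(),
        }
        written = []
        try:
            for name, frame in tables.items():
                frame = frame.copy()
                frame["config_hash"] = chash
                frame["seed"] = config.seed
                path = outdir / f"{name}.csv"
                frame.to_csv(path, index=False)
                written.append(path)
        except Exception:
            for path in written:
                path.unlink(missing_ok=True)
            raise
        _write_log(outdir / "run.log", config, econ["surface"])
    return results


def _write_log(path: Path, config: RunConfig, surface) -> None:
    lines = [
        f"agroemf run {datetime.datetime.now().isoformat()}",
        f"seed: {config.seed}",
        f"config_hash: {config.config_hash()}",
        f"risk_aversion: {config.risk_aversion}",
        f"yield_price: {config.yield_price}",
        f"nitrogen_variant: {config.nitrogen_variant}",
        f"cv_ddof: {config.cv_ddof}",
        "soil constants: "
        + ", ".join(f"{k}={v}" for k, v in DEFAULT_SOIL.as_dict().items()),
        "price scenarios: "
        + "; ".join(
            f"{n}(co2={p.co2_price}, n={p.n_price}, crop_mult={p.crop_price_multiplier})"
            for n, p in price_scenarios().items()
            if n in config.scenarios
        ),
        "rp surface coefficients: "
        + ", ".join(f"x{i+1}={c:.6g}" for i, c in enumerate(surface.coefficients)),
        f"rp surface r_squared: {surface.r_squared:.4f}",
    ]
    path.write_text("\n".join(lines) + "\n")
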