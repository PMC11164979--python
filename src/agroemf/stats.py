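"""Inference for the balanced split-plot design.

Climate is applied to whole mainplots and land-use type to subplots within
them, so the two factors need separate error strata: climate is tested
against the among-mainplot mean square (denominator df = n_mainplots - 2),
while land-use type and the interaction are tested against the subplot
residual (denominator df = 4 * n_mainplots - 8 with five land-use types).
For the balanced, complete design these classical stratified F tests are
exactly equivalent to REML-based mixed-model F tests with Satterthwaite
degrees of freedom; unbalanced designs are rejected rather than
approximated.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from ._errors import (
    DomainError,
    InsufficientDataError,
    UnsupportedDesignError,
)
from .synthetic import LAND_USE_TYPES, validate_design


def _design_codes(design: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Integer codes (climate, mainplot, lut) per row plus mainplot count."""
    try:
        validate_design(design)
    except Exception as exc:
        raise UnsupportedDesignError(f"invalid design: {exc}") from exc
    climate = pd.Categorical(design["climate"]).codes
    mainplot = pd.Categorical(design["mainplot_id"]).codes
    lut = pd.Categorical(design["lut"], categories=LAND_USE_TYPES).codes
    n_mainplots = int(mainplot.max()) + 1
    if len(np.unique(climate)) != 2:
        raise UnsupportedDesignError("exactly two climate levels are required")
    per_climate = pd.crosstab(design["climate"], design["mainplot_id"]).astype(bool).sum(axis=1)
    if per_climate.nunique() != 1:
        raise UnsupportedDesignError("mainplots must split evenly across climates")
    return climate, mainplot, lut, n_mainplots


def splitplot_anova(response, design: pd.DataFrame) -> pd.DataFrame:
    """Classical split-plot ANOVA F tests for a balanced complete design.

    Parameters
    ----------
    response:
        Per-plot values aligned with the rows of ``design`` (array-like or
        a Series indexed by ``plot_id``).
    design:
        Design table from :func:`agroemf.synthetic.generate_design`.

    Returns
    -------
    DataFrame with one row per term (climate, lut, climate:lut) giving the
    stratum, numerator/denominator df, F and p.  If an error stratum has
    zero mean square the corresponding tests are reported as degenerate
    (F and p = NaN).
    """
    if isinstance(response, pd.Series):
        y = response.reindex(design["plot_id"]).to_numpy(dtype=float)
    else:
        y = np.asarray(response, dtype=float)
    if y.size != len(design):
        raise UnsupportedDesignError("response length does not match the design")
    if np.isnan(y).any():
        raise DomainError("response contains missing values")
    climate, mainplot, lut, m = _design_codes(design)
    k = len(LAND_USE_TYPES)

    grand = y.mean()
    # cell/marginal means via bincount
    clim_mean = np.bincount(climate, weights=y) / np.bincount(climate)
    mp_mean = np.bincount(mainplot, weights=y) / np.bincount(mainplot)
    lut_mean = np.bincount(lut, weights=y) / np.bincount(lut)
    cell_idx = climate * k + lut
    cell_mean = np.bincount(cell_idx, weights=y, minlength=2 * k) / np.bincount(
        cell_idx, minlength=2 * k
    )
    mp_climate = np.zeros(m, dtype=int)
    mp_climate[mainplot] = climate

    n_per_climate = np.bincount(climate)  # plots per climate = k * m/2
    ss_climate = float((n_per_climate * (clim_mean - grand) ** 2).sum())
    ss_mainplot = float(k * ((mp_mean - clim_mean[mp_climate]) ** 2).sum())
    ss_lut = float(m * ((lut_mean - grand) ** 2).sum())
    inter = cell_mean.reshape(2, k) - clim_mean[:, None] - lut_mean[None, :] + grand
    ss_inter = float((m / 2) * (inter**2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_resid = ss_total - ss_climate - ss_mainplot - ss_lut - ss_inter
    ss_resid = max(ss_resid, 0.0)

    df_climate, df_mainplot = 1, m - 2
    df_lut = df_inter = k - 1
    df_resid = m * (k - 1) - 2 * (k - 1)

    ms_mainplot = ss_mainplot / df_mainplot
    ms_resid = ss_resid / df_resid

    def _test(ss: float, df_num: int, ms_err: float, df_den: int) -> tuple[float, float]:
        if ms_err <= 0:
            return float("nan"), float("nan")
        f = (ss / df_num) / ms_err
        return f, float(sps.f.sf(f, df_num, df_den))

    f_c, p_c = _test(ss_climate, df_climate, ms_mainplot, df_mainplot)
    f_l, p_l = _test(ss_lut, df_lut, ms_resid, df_resid)
    f_i, p_i = _test(ss_inter, df_inter, ms_resid, df_resid)

    table = pd.DataFrame(
        [
            ("climate", "mainplot", df_climate, df_mainplot, f_c, p_c),
            ("lut", "subplot", df_lut, df_resid, f_l, p_l),
            ("climate:lut", "subplot", df_inter, df_resid, f_i, p_i),
        ],
        columns=["term", "stratum", "df_num", "df_den", "F", "p"],
    )
    table.attrs["ms_resid"] = ms_resid
    table.attrs["df_resid"] = df_resid
    table.attrs["ms_mainplot"] = ms_mainplot
    return table


def significance_stars(p: float) -> str:
    """Figure-caption style stars: *** / ** / * at 0.001 / 0.01 / 0.05."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def tukey_pairwise(
    means: dict[str, float], n_per_group: int, ms_error: float, df_error: int
) -> pd.DataFrame:
    """Tukey (studentized-range) adjusted pairwise comparisons of means.

    With two groups the adjusted p equals the two-sided pooled t-test p.
    """
    if len(means) < 2:
        raise DomainError("need at least two groups for pairwise comparisons")
    if ms_error <= 0 or df_error <= 0:
        raise DomainError("error mean square and df must be positive")
    if n_per_group < 1:
        raise DomainError("n_per_group must be at least 1")
    k = len(means)
    se = np.sqrt(ms_error / n_per_group)
    rows = []
    for a, bb in combinations(sorted(means), 2):
        diff = means[a] - means[bb]
        q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df_error))
        rows.append(
            {
                "group_a": a,
                "group_b": bb,
                "estimate": diff,
                "se": se,
                "q": q,
                "p_adj": min(p, 1.0),
                "stars": significance_stars(p),
            }
        )
    return pd.DataFrame(rows)


def tukey_posthoc(
    response, design: pd.DataFrame, term: str = "lut", alpha: float = 0.05
) -> pd.DataFrame:
    """Tukey post-hoc comparisons after the split-plot ANOVA.

    ``term`` is ``"lut"`` (marginal land-use means) or ``"lut:climate"``
    (cell means).  Estimated marginal means are plain cell means — exact for
    the balanced design — and the comparisons use the subplot residual mean
    square and its degrees of freedom, following the published analysis.

    Mirroring the published flow, :func:`anova_with_posthoc` drops to the
    marginal means whenever the interaction is non-significant.
    """
    table = splitplot_anova(response, design)
    ms_resid = table.attrs["ms_resid"]
    df_resid = table.attrs["df_resid"]
    if isinstance(response, pd.Series):
        y = response.reindex(design["plot_id"]).to_numpy(dtype=float)
    else:
        y = np.asarray(response, dtype=float)
    df = design.copy()
    df["_y"] = y
    if term == "lut":
        groups = df.groupby("lut")["_y"]
    elif term in ("lut:climate", "climate:lut"):
        groups = df.groupby(df["lut"] + ":" + df["climate"])["_y"]
    else:
        raise DomainError(f"unknown post-hoc term {term!r}")
    means = groups.mean().to_dict()
    n_per_group = int(groups.size().iloc[0])
    return tukey_pairwise(means, n_per_group, ms_resid, df_resid)


def anova_with_posthoc(
    response, design: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ANOVA plus the interaction-aware post-hoc flow.

    If the climate x land-use interaction is significant at ``alpha`` the
    post-hoc compares the ten cell means; otherwise the interaction is
    dropped and the five marginal land-use means are compared.
    """
    table = splitplot_anova(response, design)
    p_inter = table.loc[table["term"] == "climate:lut", "p"].iloc[0]
    term = "lut:climate" if (not np.isnan(p_inter) and p_inter < alpha) else "lut"
    posthoc = tukey_posthoc(response, design, term=term, alpha=alpha)
    posthoc.attrs["term"] = term
    return table, posthoc


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit summary for one model."""

    formula: str
    params: pd.DataFrame  # index: term; columns: coef, se, t, p
    r_squared: float
    n_obs: int

    def coef(self, term: str) -> float:
        return float(self.params.loc[term, "coef"])


def _ols_fit(y: np.ndarray, X: pd.DataFrame, formula: str) -> RegressionFit:
    model = sm.OLS(y, sm.add_constant(X, has_constant="add"))
    res = model.fit()
    params = pd.DataFrame(
        {"coef": res.params, "se": res.bse, "t": res.tvalues, "p": res.pvalues}
    )
    return RegressionFit(
        formula=formula, params=params, r_squared=float(res.rsquared), n_obs=int(res.nobs)
    )


def regress_biodiversity_emf(
    emf11: pd.Series, multidiv: pd.Series, climate: pd.Series
) -> dict[str, RegressionFit]:
    """Regress 11-function multifunctionality on soil multidiversity.

    Returns fits for the pooled model, per-climate models, and the
    interaction model ``emf11 ~ multidiv * climate`` whose interaction
    coefficient measures the climate-dependence of the slope.
    """
    df = pd.DataFrame({"emf11": emf11, "multidiv": multidiv, "climate": climate}).dropna()
    if len(df) < 4:
        raise InsufficientDataError("need at least 4 observations for the regression")
    if df["multidiv"].nunique() == 1:
        raise DomainError("constant predictor: regression is degenerate")
    fits: dict[str, RegressionFit] = {}
    fits["pooled"] = _ols_fit(
        df["emf11"].to_numpy(), df[["multidiv"]], "emf11 ~ multidiv"
    )
    for clim, sub in df.groupby("climate"):
        if sub["multidiv"].nunique() == 1 or len(sub) < 3:
            continue
        fits[str(clim)] = _ols_fit(
            sub["emf11"].to_numpy(), sub[["multidiv"]], f"emf11 ~ multidiv | {clim}"
        )
    levels = sorted(df["climate"].unique())
    if len(levels) == 2:
        ind = (df["climate"] == levels[1]).astype(float)
        X = pd.DataFrame(
            {
                "multidiv": df["multidiv"],
                "climate_ind": ind,
                "multidiv:climate": df["multidiv"] * ind,
            }
        )
        fits["interaction"] = _ols_fit(
            df["emf11"].to_numpy(), X, "emf11 ~ multidiv * climate"
        )
    return fits


def correlation_matrix(variables: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided p values.

    Returns (r, p) DataFrames.  Pairs with fewer than 3 complete
    observations or a zero-variance column are skipped (NaN) and listed in
    ``r.attrs["skipped"]``.
    """
    cols = list(variables.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    skipped: list[tuple[str, str]] = []
    for a, b in combinations(cols, 2):
        sub = variables[[a, b]].dropna()
        if len(sub) < 3 or sub[a].nunique() == 1 or sub[b].nunique() == 1:
            r.loc[a, b] = r.loc[b, a] = np.nan
            p.loc[a, b] = p.loc[b, a] = np.nan
            skipped.append((a, b))
            continue
        rr, pp = sps.pearsonr(sub[a], sub[b])
        r.loc[a, b] = r.loc[b, a] = rr
        p.loc[a, b] = p.loc[b, a] = pp
    r.attrs["skipped"] = skipped
    return r, p
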