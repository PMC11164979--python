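"""Tests for the split-plot ANOVA, Tukey post-hoc, regressions, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from agroemf._errors import DomainError, InsufficientDataError, UnsupportedDesignError
from agroemf.stats import (
    anova_with_posthoc,
    correlation_matrix,
    regress_biodiversity_emf,
    significance_stars,
    splitplot_anova,
    tukey_pairwise,
    tukey_posthoc,
)
from agroemf.synthetic import generate_design


def _simulate(design, rng, climate_effect=0.0, lut_effects=None, mainplot_sd=1.0, noise_sd=1.0):
    lut_effects = lut_effects or {}
    mp_effects = {
        mp: rng.normal(0, mainplot_sd) for mp in design["mainplot_id"].unique()
    }
    y = np.array(
        [
            (climate_effect if row.climate == "future" else 0.0)
            + lut_effects.get(row.lut, 0.0)
            + mp_effects[row.mainplot_id]
            + rng.normal(0, noise_sd)
            for row in design.itertuples()
        ]
    )
    return y


class TestSplitplotAnova:
    def test_degrees_of_freedom_10_mainplots(self, design10, rng):
        y = rng.normal(size=len(design10))
        table = splitplot_anova(y, design10).set_index("term")
        assert table.at["lut", "df_num"] == 4
        assert table.at["lut", "df_den"] == 32
        assert table.at["climate", "df_num"] == 1
        assert table.at["climate", "df_den"] == 8
        assert table.at["climate:lut", "df_num"] == 4
        assert table.at["climate:lut", "df_den"] == 32

    @pytest.mark.parametrize("m", [4, 6, 8, 12])
    def test_df_bookkeeping_general(self, m, rng):
        design = generate_design(m, seed=m)
        y = rng.normal(size=len(design))
        table = splitplot_anova(y, design).set_index("term")
        assert table.at["climate", "df_den"] == m - 2
        assert table.at["lut", "df_den"] == 4 * m - 8
        # all strata df sum to n_plots - 1
        total_df = 1 + (m - 2) + 4 + 4 + (4 * m - 8)
        assert total_df == 5 * m - 1

    def test_constant_response_degenerate(self, design10):
        table = splitplot_anova(np.full(50, 3.0), design10)
        assert table["F"].isna().all()

    def test_matches_model_comparison_oracle(self, design10, rng):
        """Independent oracle: sums of squares via nested OLS model comparison."""
        y = _simulate(design10, rng, climate_effect=1.0, lut_effects={"CF": 2.0})
        d = design10.reset_index(drop=True)
        n = len(d)

        def rss(cols):
            X = np.ones((n, 1))
            for col, levels in cols:
                dummies = pd.get_dummies(d[col] if isinstance(col, str) else col)
                X = np.column_stack([X, dummies.to_numpy(dtype=float)])
            resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            return float(resid @ resid)

        cell = d["climate"] + ":" + d["lut"]
        rss_0 = rss([])
        rss_c = rss([("climate", None)])
        rss_mp = rss([("mainplot_id", None)])
        rss_mp_lut = rss([("mainplot_id", None), ("lut", None)])
        rss_full = rss([("mainplot_id", None), ("lut", None), (cell, None)])

        m = 10
        ss_climate = rss_0 - rss_c
        ss_mainplot = rss_c - rss_mp
        ss_lut = rss_mp - rss_mp_lut
        ss_inter = rss_mp_lut - rss_full
        f_climate = (ss_climate / 1) / (ss_mainplot / (m - 2))
        f_lut = (ss_lut / 4) / (rss_full / (4 * m - 8))
        f_inter = (ss_inter / 4) / (rss_full / (4 * m - 8))

        table = splitplot_anova(y, design10).set_index("term")
        assert table.at["climate", "F"] == pytest.approx(f_climate, rel=1e-8)
        assert table.at["lut", "F"] == pytest.approx(f_lut, rel=1e-8)
        assert table.at["climate:lut", "F"] == pytest.approx(f_inter, rel=1e-8)

    def test_climate_f_equals_mainplot_mean_anova(self, design10, rng):
        # second oracle: the whole-plot test equals a one-way ANOVA on
        # mainplot means
        y = _simulate(design10, rng, climate_effect=2.0)
        d = design10.assign(y=y)
        mp = d.groupby(["mainplot_id", "climate"])["y"].mean().reset_index()
        groups = [g["y"].to_numpy() for _, g in mp.groupby("climate")]
        f_oracle, p_oracle = sps.f_oneway(*groups)
        table = splitplot_anova(y, design10).set_index("term")
        assert table.at["climate", "F"] == pytest.approx(f_oracle, rel=1e-9)
        assert table.at["climate", "p"] == pytest.approx(p_oracle, rel=1e-9)

    def test_series_response_aligned_by_plot_id(self, design10, rng):
        y = pd.Series(rng.normal(size=50), index=design10["plot_id"])
        shuffled = y.sample(frac=1.0, random_state=0)
        a = splitplot_anova(y, design10)
        b = splitplot_anova(shuffled, design10)
        assert np.allclose(a["F"], b["F"])

    def test_unbalanced_rejected(self, design10, rng):
        with pytest.raises(UnsupportedDesignError):
            splitplot_anova(rng.normal(size=49), design10.iloc[:49])

    def test_nan_response_rejected(self, design10):
        y = np.zeros(50)
        y[3] = np.nan
        with pytest.raises(DomainError):
            splitplot_anova(y, design10)


class TestTukey:
    def test_identical_means_give_p_one(self, design10, rng):
        y = pd.Series(rng.normal(size=50), index=design10["plot_id"])
        # center by land-use group: group means exactly identical
        y = y - y.groupby(design10.set_index("plot_id")["lut"]).transform("mean")
        out = tukey_posthoc(y, design10, term="lut")
        assert np.allclose(out["p_adj"], 1.0)

    def test_k2_reduces_to_t_test(self):
        means = {"a": 1.0, "b": 2.5}
        n, ms, df = 6, 1.3, 20
        out = tukey_pairwise(means, n, ms, df)
        t = abs(means["a"] - means["b"]) / np.sqrt(2 * ms / n)
        p_t = 2 * sps.t.sf(t, df)
        assert out["p_adj"].iloc[0] == pytest.approx(p_t, rel=1e-6)

    def test_adjusted_geq_unadjusted(self, rng):
        means = {f"g{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 5))}
        n, ms, df = 5, 1.0, 32
        out = tukey_pairwise(means, n, ms, df)
        for row in out.itertuples():
            t = abs(row.estimate) / np.sqrt(2 * ms / n)
            p_unadj = 2 * sps.t.sf(t, df)
            assert row.p_adj >= p_unadj - 1e-12

    def test_power_on_planted_effect(self, design10, rng):
        y = _simulate(
            design10, rng, lut_effects={"CF": 10.0}, mainplot_sd=0.2, noise_sd=0.5
        )
        out = tukey_posthoc(y, design10, term="lut")
        assert out["p_adj"].min() < 0.001

    def test_interaction_flow_switches_term(self, design10, rng):
        y_main = _simulate(design10, rng, lut_effects={"CF": 5.0}, noise_sd=0.5)
        _, posthoc = anova_with_posthoc(y_main, design10)
        assert posthoc.attrs["term"] == "lut"
        # plant a strong interaction: CF effect only under future climate
        inter = np.array(
            [
                10.0 if (row.lut == "CF" and row.climate == "future") else 0.0
                for row in design10.itertuples()
            ]
        )
        y_int = inter + _simulate(design10, rng, mainplot_sd=0.2, noise_sd=0.5)
        _, posthoc = anova_with_posthoc(y_int, design10)
        assert posthoc.attrs["term"] == "lut:climate"

    def test_single_group_rejected(self):
        with pytest.raises(DomainError):
            tukey_pairwise({"a": 1.0}, 5, 1.0, 10)

    def test_stars(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == ""


class TestRegression:
    def test_noiseless_linear_r2_one(self, design10):
        climate = design10.set_index("plot_id")["climate"]
        x = pd.Series(
            np.linspace(0, 1, 50), index=design10["plot_id"], name="multidiv"
        )
        y = 0.2 + 0.6 * x
        fits = regress_biodiversity_emf(y, x, climate)
        assert fits["pooled"].r_squared == pytest.approx(1.0)
        assert fits["pooled"].coef("multidiv") == pytest.approx(0.6)

    def test_null_r2_small_and_p_uniform(self, design10):
        climate = design10.set_index("plot_id")["climate"]
        pvals, r2s = [], []
        rng = np.random.default_rng(2024)
        for _ in range(200):
            x = pd.Series(rng.uniform(size=50), index=design10["plot_id"])
            y = pd.Series(rng.uniform(size=50), index=design10["plot_id"])
            fit = regress_biodiversity_emf(y, x, climate)["pooled"]
            pvals.append(fit.params.loc["multidiv", "p"])
            r2s.append(fit.r_squared)
        assert np.mean(r2s) < 0.1
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_interaction_recovers_slope_difference(self, design10):
        rng = np.random.default_rng(7)
        climate = design10.set_index("plot_id")["climate"]
        x = pd.Series(rng.uniform(size=50), index=design10["plot_id"])
        slopes = climate.map({"ambient": 0.2, "future": 0.8})
        y = slopes * x + rng.normal(0, 0.02, size=50)
        fit = regress_biodiversity_emf(y, x, climate)["interaction"]
        beta = fit.coef("multidiv:climate")
        se = float(fit.params.loc["multidiv:climate", "se"])
        assert abs(beta - 0.6) < 3 * se

    def test_constant_predictor_rejected(self, design10):
        climate = design10.set_index("plot_id")["climate"]
        x = pd.Series(0.5, index=design10["plot_id"])
        y = pd.Series(np.arange(50, dtype=float), index=design10["plot_id"])
        with pytest.raises(DomainError):
            regress_biodiversity_emf(y, x, climate)

    def test_too_few_observations(self):
        idx = ["a", "b", "c"]
        s = pd.Series([1.0, 2.0, 3.0], index=idx)
        with pytest.raises(InsufficientDataError):
            regress_biodiversity_emf(s, s, pd.Series(["x", "x", "y"], index=idx))


class TestCorrelationMatrix:
    def test_self_correlation(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=10)})
        r, p = correlation_matrix(df)
        assert r.at["a", "a"] == 1.0

    def test_anticorrelation(self, rng):
        x = rng.normal(size=20)
        r, _ = correlation_matrix(pd.DataFrame({"x": x, "neg": -x}))
        assert r.at["x", "neg"] == pytest.approx(-1.0)

    def test_hand_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 6.0])
        r, p = correlation_matrix(pd.DataFrame({"x": x, "y": y}))
        # brute-force covariance formula
        rx = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r.at["x", "y"] == pytest.approx(rx, rel=1e-12)

    def test_symmetry_and_p_range(self, rng):
        df = pd.DataFrame(rng.normal(size=(15, 4)), columns=list("abcd"))
        r, p = correlation_matrix(df)
        assert np.allclose(r, r.T)
        off_diag = p.to_numpy()[~np.eye(4, dtype=bool)]
        assert ((off_diag >= 0) & (off_diag <= 1)).all()

    def test_zero_variance_column_skipped(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=10), "const": np.ones(10)})
        r, p = correlation_matrix(df)
        assert np.isnan(r.at["a", "const"])
        assert ("a", "const") in r.attrs["skipped"]
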