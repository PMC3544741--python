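"""Design construction, OLS correctness against independent oracles, and the
interpretation of the interaction coefficients."""

import numpy as np
import pandas as pd
import pytest

from mlrdecon import deconvolution, presets, simulate
from mlrdecon.deconvolution import (
    CellTypeInteractionRegression,
    CollinearityError,
    DataError,
    UnderdeterminedError,
    build_design,
    fit_all,
    fit_gene,
    interaction_name,
    rank_by_gamma,
)

from conftest import normal_equations_fit


class TestBuildDesign:
    def test_column_count_and_order(self, small_cohort):
        comps, relapse = small_cohort
        design = build_design(comps, relapse, ("tumor", "stroma", "BPH"))
        assert design.shape == (40, 7)
        assert list(design.columns) == [
            "intercept", "tumor", "stroma", "BPH",
            "tumor:relapse", "stroma:relapse", "BPH:relapse",
        ]

    def test_interaction_is_elementwise_product(self, small_cohort):
        comps, relapse = small_cohort
        design = build_design(comps, relapse)
        for t in ("tumor", "stroma", "BPH"):
            np.testing.assert_allclose(
                design[interaction_name(t)], design[t] * relapse, atol=1e-15
            )

    def test_all_four_fractions_plus_intercept_collinear(self, small_cohort):
        comps, relapse = small_cohort
        with pytest.raises(CollinearityError):
            build_design(comps, relapse, ("tumor", "stroma", "BPH", "other"))

    def test_percent_scale_autodetected(self, small_cohort):
        comps, relapse = small_cohort
        design_pct = build_design(comps * 100.0, relapse)
        design = build_design(comps, relapse)
        pd.testing.assert_frame_equal(design_pct, design)


class TestFitGene:
    def test_noiseless_coefficients_recovered_exactly(self, study_cohort):
        comps, relapse = study_cohort
        model = presets.table2_models(noise_sd=0.0)["Egr3"]
        expr = simulate.simulate_expression(comps, relapse, [model])
        design = build_design(comps, relapse)
        fit = fit_gene(expr.loc["Egr3"], design)
        assert fit.params["intercept"] == pytest.approx(model.beta0, abs=1e-9)
        for t in ("tumor", "stroma", "BPH"):
            assert fit.beta(t) == pytest.approx(model.beta[t], abs=1e-9)
            assert fit.gamma(t) == pytest.approx(model.gamma[t], abs=1e-9)

    def test_matches_normal_equations_on_toy_system(self, rng):
        n = 6
        comps = pd.DataFrame(
            rng.dirichlet((2, 2, 2), size=n), columns=["tumor", "stroma", "BPH"]
        )
        relapse = pd.Series([0, 1, 0, 1, 1, 0])
        design = build_design(comps, relapse, ("tumor",))
        y = pd.Series(rng.normal(size=n), name="toy")
        fit = fit_gene(y, design)
        beta, se, t, p, df = normal_equations_fit(design.to_numpy(), y.to_numpy())
        np.testing.assert_allclose(fit.params, beta, rtol=1e-10)
        np.testing.assert_allclose(fit.bse, se, rtol=1e-10)
        np.testing.assert_allclose(fit.pvalues, p, rtol=1e-10)
        assert fit.df_resid == df

    def test_matches_statsmodels(self, small_cohort, rng):
        sm = pytest.importorskip("statsmodels.api")
        comps, relapse = small_cohort
        design = build_design(comps, relapse)
        y = rng.normal(size=len(design))
        fit = fit_gene(pd.Series(y, index=design.index), design)
        res = sm.OLS(y, design.to_numpy()).fit()
        np.testing.assert_allclose(fit.params, res.params, rtol=1e-9)
        np.testing.assert_allclose(fit.bse, res.bse, rtol=1e-9)
        np.testing.assert_allclose(fit.pvalues, res.pvalues, rtol=1e-9, atol=1e-12)

    def test_zero_interaction_columns_dropped_when_no_relapse(self, small_cohort):
        comps, _ = small_cohort
        relapse = pd.Series(0, index=comps.index)
        design = build_design(comps, relapse)
        y = pd.Series(np.arange(len(design), dtype=float), index=design.index)
        fit = fit_gene(y, design)
        for t in ("tumor", "stroma", "BPH"):
            assert np.isnan(fit.params[interaction_name(t)])
        assert fit.df_resid == len(design) - 4

    def test_pvalues_invariant_to_constant_shift(self, small_cohort, rng):
        comps, relapse = small_cohort
        design = build_design(comps, relapse)
        y = rng.normal(size=len(design))
        a = fit_gene(pd.Series(y, index=design.index), design)
        b = fit_gene(pd.Series(y + 17.3, index=design.index), design)
        np.testing.assert_allclose(
            a.pvalues.drop("intercept"), b.pvalues.drop("intercept"), rtol=1e-8
        )

    def test_underdetermined_and_nonfinite_rejected(self, small_cohort):
        comps, relapse = small_cohort
        design = build_design(comps, relapse)
        with pytest.raises(UnderdeterminedError):
            fit_gene(pd.Series(np.zeros(7), index=design.index[:7]), design.iloc[:7])
        bad = pd.Series(np.full(len(design), np.nan), index=design.index)
        with pytest.raises(DataError):
            fit_gene(bad, design)

    def test_gamma_equals_subset_beta_difference(self, study_cohort):
        """On noiseless data, gamma from the interaction model equals the
        difference of betas fit separately in relapse / non-relapse subsets."""
        comps, relapse = study_cohort
        model = presets.table2_models(noise_sd=0.0)["Egr3"]
        expr = simulate.simulate_expression(comps, relapse, [model])
        y = expr.loc["Egr3"]
        design = build_design(comps, relapse)
        full = fit_gene(y, design)
        for group in (0, 1):
            idx = relapse[relapse == group].index
            sub_design = build_design(
                comps.loc[idx], pd.Series(0, index=idx), ("tumor", "stroma", "BPH")
            )[["intercept", "tumor", "stroma", "BPH"]]
            sub = fit_gene(y.loc[idx], sub_design)
            for t in ("tumor", "stroma", "BPH"):
                expected = full.beta(t) + (full.gamma(t) if group else 0.0)
                assert sub.beta(t) == pytest.approx(expected, abs=1e-7)


class TestFitAll:
    def test_matches_fit_gene_per_row(self, small_cohort, rng):
        comps, relapse = small_cohort
        expr = pd.DataFrame(
            rng.normal(size=(5, len(comps))),
            index=[f"g{i}" for i in range(5)], columns=comps.index,
        )
        fits = fit_all(expr, comps, relapse)
        design = build_design(comps, relapse)
        for gid in expr.index:
            single = fit_gene(expr.loc[gid], design)
            assert fits.loc[gid, "gamma_tumor"] == pytest.approx(
                single.gamma("tumor"), rel=1e-10
            )
            assert fits.loc[gid, "p_tumor:relapse"] == pytest.approx(
                single.pvalues[interaction_name("tumor")], rel=1e-10
            )

    def test_hundred_gene_matrix_all_fit(self, small_cohort, rng):
        comps, relapse = small_cohort
        expr = pd.DataFrame(
            rng.normal(size=(100, len(comps))),
            index=[f"g{i:03d}" for i in range(100)], columns=comps.index,
        )
        fits = fit_all(expr, comps, relapse)
        assert len(fits) == 100
        assert fits["gamma_tumor"].notna().all()

    def test_constant_gene_has_zero_slopes(self, small_cohort):
        comps, relapse = small_cohort
        expr = pd.DataFrame(
            np.full((1, len(comps)), 3.5), index=["flat"], columns=comps.index
        )
        fits = fit_all(expr, comps, relapse)
        for t in ("tumor", "stroma", "BPH"):
            assert fits.loc["flat", f"beta_{t}"] == pytest.approx(0.0, abs=1e-9)
            assert fits.loc["flat", f"gamma_{t}"] == pytest.approx(0.0, abs=1e-9)

    def test_center_samples_shifts_only_intercept(self, small_cohort, rng):
        comps, relapse = small_cohort
        expr = pd.DataFrame(
            rng.normal(size=(6, len(comps))),
            index=[f"g{i}" for i in range(6)], columns=comps.index,
        )
        raw = fit_all(expr, comps, relapse, center_samples=False)
        centered = fit_all(expr, comps, relapse, center_samples=True)
        assert not np.allclose(raw["beta0"], centered["beta0"])


class TestRankByGamma:
    def _fits(self, gammas, ids=None):
        ids = ids or [f"g{i}" for i in range(len(gammas))]
        return pd.DataFrame({"gamma_tumor": gammas}, index=pd.Index(ids, name="gene_id"))

    def test_ascending_order(self):
        ranked = rank_by_gamma(self._fits([1.0, -2.0, 0.0]), "tumor")
        assert list(ranked.index) == ["g1", "g2", "g0"]
        assert list(ranked["rank"]) == [1, 2, 3]

    def test_ties_broken_lexicographically(self):
        ranked = rank_by_gamma(self._fits([0.5, 0.5], ids=["zz", "aa"]), "tumor")
        assert list(ranked.index) == ["aa", "zz"]

    def test_planted_extreme_gene_is_rank_one(self, study_cohort):
        comps, relapse = study_cohort
        models = [
            simulate.GeneModel(f"null{i:02d}", beta0=5.0, noise_sd=0.3)
            for i in range(50)
        ]
        models.append(
            simulate.GeneModel("hit", beta0=5.0, gamma={"tumor": -8.0}, noise_sd=0.3)
        )
        expr = simulate.simulate_expression(comps, relapse, models, seed=13)
        fits = fit_all(expr, comps, relapse)
        ranked = rank_by_gamma(fits, "tumor")
        assert ranked.index[0] == "hit"

    def test_unknown_cell_type_rejected(self):
        with pytest.raises(ValueError):
            rank_by_gamma(self._fits([0.0]), "bone")


class TestEstimatorInterface:
    def test_get_set_params_roundtrip(self):
        est = CellTypeInteractionRegression(center_samples=True)
        params = est.get_params()
        est2 = CellTypeInteractionRegression(**params)
        assert est2.get_params() == params

    def test_predict_reproduces_noiseless_data(self, small_cohort):
        comps, relapse = small_cohort
        model = simulate.GeneModel(
            "g", beta0=1.0, beta={"tumor": 2.0}, gamma={"stroma": -1.0}, noise_sd=0.0
        )
        expr = simulate.simulate_expression(comps, relapse, [model])
        X = comps.copy()
        X["relapse"] = relapse
        est = CellTypeInteractionRegression().fit(X, expr.T)
        np.testing.assert_allclose(est.predict(X)[:, 0], expr.loc["g"], atol=1e-10)
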