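"""Generator behavior: simplex compositions, the linear expression model,
correlated modules, planted promoters and synthetic IHC images."""

import numpy as np
import pandas as pd
import pytest

from mlrdecon import motif, simulate
from mlrdecon.simulate import (
    AlignmentError,
    CohortSpec,
    CorrelatedModuleSpec,
    DegenerateInputError,
    GeneModel,
    GlandSpec,
    LayoutError,
    ParameterError,
)


class TestCompositions:
    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_rows_on_simplex(self, seed):
        comps = simulate.generate_compositions(CohortSpec(n_samples=50, seed=seed))
        assert (comps.to_numpy() >= 0).all()
        np.testing.assert_allclose(comps.sum(axis=1), 1.0, atol=1e-12)

    def test_reproducible_for_fixed_seed(self):
        spec = CohortSpec(n_samples=20, seed=5)
        a = simulate.generate_compositions(spec)
        b = simulate.generate_compositions(spec)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_alpha_concentrates_mass(self):
        spec = CohortSpec(
            n_samples=25, dirichlet_alpha=(1e6, 1e-9, 1e-9, 1e-9), seed=0
        )
        comps = simulate.generate_compositions(spec)
        assert (comps["tumor"] > 0.999).all()

    def test_symmetric_alpha_means(self):
        spec = CohortSpec(n_samples=10_000, dirichlet_alpha=(2, 2, 2, 2), seed=3)
        comps = simulate.generate_compositions(spec)
        np.testing.assert_allclose(comps.mean(axis=0), 0.25, atol=0.01)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dirichlet_alpha": (1, 1, -1, 1)},
            {"dirichlet_alpha": (1, 1)},
            {"relapse_fraction": 1.5},
            {"n_samples": 0},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        base = {"n_samples": 10}
        base.update(kwargs)
        with pytest.raises(ParameterError):
            CohortSpec(**base)


class TestExpression:
    def _pure_tumor(self, rs):
        comps = pd.DataFrame(
            [[1.0, 0.0, 0.0, 0.0]], index=["S0"],
            columns=["tumor", "stroma", "BPH", "other"],
        )
        relapse = pd.Series([rs], index=["S0"], name="relapse")
        return comps, relapse

    def test_pure_tumor_nonrelapse_equals_beta(self):
        comps, relapse = self._pure_tumor(0)
        model = GeneModel("Egr3", beta0=0.0, beta={"tumor": 1.125}, noise_sd=0.0)
        expr = simulate.simulate_expression(comps, relapse, [model])
        assert expr.loc["Egr3", "S0"] == pytest.approx(1.125, abs=1e-12)

    def test_pure_tumor_relapse_adds_gamma(self):
        comps, relapse = self._pure_tumor(1)
        model = GeneModel(
            "Egr3", beta0=0.0, beta={"tumor": 1.125}, gamma={"tumor": -1.921},
            noise_sd=0.0,
        )
        expr = simulate.simulate_expression(comps, relapse, [model])
        assert expr.loc["Egr3", "S0"] == pytest.approx(-0.796, abs=1e-12)

    def test_all_zero_coefficients_give_zero_matrix(self, small_cohort):
        comps, relapse = small_cohort
        models = [GeneModel(f"g{i}", beta0=0.0, noise_sd=0.0) for i in range(3)]
        expr = simulate.simulate_expression(comps, relapse, models)
        assert (expr.to_numpy() == 0).all()

    def test_noiseless_matches_linear_predictor(self, small_cohort):
        comps, relapse = small_cohort
        model = GeneModel(
            "g", beta0=2.0, beta={"tumor": 1.5, "stroma": -0.5},
            gamma={"tumor": -2.0}, noise_sd=0.0,
        )
        expr = simulate.simulate_expression(comps, relapse, [model])
        expected = (
            2.0 + 1.5 * comps["tumor"] - 0.5 * comps["stroma"]
            - 2.0 * comps["tumor"] * relapse
        )
        np.testing.assert_allclose(expr.loc["g"], expected, atol=1e-12)

    def test_mismatched_samples_rejected(self, small_cohort):
        comps, relapse = small_cohort
        with pytest.raises(AlignmentError):
            simulate.simulate_expression(comps, relapse.iloc[:-3], [GeneModel("g", 0.0)])


class TestCorrelatedModule:
    def test_target_r_one_is_exact(self, small_cohort, rng):
        seed_profile = pd.Series(rng.normal(size=40), index=small_cohort[0].index)
        spec = CorrelatedModuleSpec(n_genes=5, target_R=1.0, seed=1)
        module = simulate.simulate_correlated_module(seed_profile, spec)
        for _, row in module.iterrows():
            r = np.corrcoef(row, seed_profile)[0, 1]
            assert r == pytest.approx(1.0, abs=1e-12)

    def test_realized_r_converges_to_target(self, rng):
        seed_profile = pd.Series(rng.normal(size=5000))
        spec = CorrelatedModuleSpec(n_genes=30, target_R=0.45, seed=2)
        module = simulate.simulate_correlated_module(seed_profile, spec)
        rs = [np.corrcoef(row, seed_profile)[0, 1] for _, row in module.iterrows()]
        assert np.mean(rs) == pytest.approx(0.45, abs=0.03)

    def test_noiseless_slope_recovered(self, rng):
        seed_profile = pd.Series(rng.normal(size=100))
        spec = CorrelatedModuleSpec(
            n_genes=4, slope_range=(0.5, 0.5), target_R=1.0, seed=3
        )
        module = simulate.simulate_correlated_module(seed_profile, spec)
        for _, row in module.iterrows():
            slope = np.polyfit(seed_profile, row, 1)[0]
            assert slope == pytest.approx(0.5, abs=1e-9)

    def test_constant_seed_rejected(self):
        const = pd.Series(np.ones(10))
        with pytest.raises(DegenerateInputError):
            simulate.simulate_correlated_module(
                const, CorrelatedModuleSpec(n_genes=2, seed=0)
            )


class TestPromoters:
    matrix = motif.build_ere_matrix()

    def test_full_site_fraction_plants_perfect_sites(self):
        recs = simulate.generate_promoters(20, 80, self.matrix, 1.0, seed=4)
        for rec in recs:
            sims = [m.similarity for m in motif.scan_sequence(str(rec.seq), self.matrix)]
            assert max(sims) == pytest.approx(1.0)

    def test_zero_site_fraction_scans_clean(self):
        recs = simulate.generate_promoters(30, 120, self.matrix, 0.0, seed=5)
        frac, _ = motif.fraction_with_site(recs, self.matrix, threshold=0.80)
        assert frac == 0.0

    def test_background_fraction_recovered_by_scan(self):
        recs = simulate.generate_promoters(1000, 200, self.matrix, 0.627, seed=6)
        frac, _ = motif.fraction_with_site(recs, self.matrix, threshold=0.80)
        assert frac == pytest.approx(0.627, abs=0.035)

    def test_length_below_width_rejected(self):
        with pytest.raises(ParameterError):
            simulate.generate_promoters(1, 5, self.matrix, 0.5, seed=0)


class TestIHCImage:
    def test_gland_and_stroma_land_in_expected_bands(self):
        glands = [GlandSpec(center=(40, 40), radius=15, intensity=90)]
        img, masks = simulate.generate_ihc_image(100, 100, glands, stroma_intensity=230)
        gland_px = img[masks["gland"]]
        stroma_px = img[masks["stroma"]]
        assert (gland_px <= 100).all()   # all strong
        assert (stroma_px > 220).all()   # all negative

    def test_lumen_pixels_above_weak_threshold(self):
        glands = [GlandSpec(center=(50, 50), radius=20, intensity=90, lumen=True)]
        img, masks = simulate.generate_ihc_image(100, 100, glands)
        assert masks["lumen"].any()
        assert (img[masks["lumen"]] > 220).all()

    def test_overlapping_glands_rejected(self):
        glands = [
            GlandSpec(center=(30, 30), radius=15, intensity=90),
            GlandSpec(center=(35, 35), radius=15, intensity=120),
        ]
        with pytest.raises(LayoutError):
            simulate.generate_ihc_image(100, 100, glands)

    def test_reproducible_for_fixed_seed(self):
        glands = [GlandSpec(center=(30, 30), radius=10, intensity=150)]
        a, _ = simulate.generate_ihc_image(64, 64, glands, seed=9)
        b, _ = simulate.generate_ihc_image(64, 64, glands, seed=9)
        np.testing.assert_array_equal(a, b)
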