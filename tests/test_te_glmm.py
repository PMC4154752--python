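import numpy as np
import pytest
import statsmodels.api as sm

from repeatproof.feature_eval import FeatureAssessment
from repeatproof.te_glmm import (
    SeparationError,
    build_design,
    fit_glmm,
    marginal_loglik,
    marginal_loglik_quadrature,
    predict_curves,
    simulate_glmm_data,
)


class TestBuildDesign:
    def _assessments(self, genome, perfect_ids):
        return [
            FeatureAssessment(
                feature_id=t.feature_id, feature_type="TE", contained=True,
                contig_id="c", identity=1.0, length_ratio=1.0,
                perfect=t.feature_id in perfect_ids,
            )
            for t in genome.tes
        ]

    def test_high_copies_counts_family_members_below_threshold(self, small_genome):
        assessments = self._assessments(
            small_genome, {t.feature_id for t in small_genome.tes[:5]}
        )
        data = build_design(assessments, small_genome.tes, small_genome)
        # recompute independently from the annotations
        div = {t.feature_id: t.divergence for t in small_genome.tes}
        fam = {t.feature_id: t.family for t in small_genome.tes}
        expected = {}
        for f in set(fam.values()):
            expected[f] = sum(
                1 for t in small_genome.tes if t.family == f and t.divergence < 0.01
            )
        idx = data.columns.index("high_copies")
        raw = data.X[:, idx] * data.sds["high_copies"] + data.means["high_copies"]
        fams_by_row = [data.family_labels[i] for i in data.family_index]
        for r, f in zip(raw, fams_by_row):
            assert round(r) == expected[f]

    def test_standardized_columns_have_zero_mean_unit_variance(self, small_genome):
        assessments = self._assessments(
            small_genome, {t.feature_id for t in small_genome.tes[::2]}
        )
        data = build_design(assessments, small_genome.tes, small_genome)
        for j, name in enumerate(data.columns):
            if name in ("intercept", "div_x_high"):
                continue
            col = data.X[:, j]
            assert abs(col.mean()) < 1e-12
            assert abs(col.std(ddof=0) - 1.0) < 1e-12

    def test_interaction_is_product_of_standardized_columns(self, small_genome):
        assessments = self._assessments(
            small_genome, {t.feature_id for t in small_genome.tes[::2]}
        )
        data = build_design(assessments, small_genome.tes, small_genome)
        c = data.columns
        np.testing.assert_allclose(
            data.X[:, c.index("div_x_high")],
            data.X[:, c.index("divergence")] * data.X[:, c.index("high_copies")],
        )

    def test_zero_variance_predictor_is_named(self, small_genome):
        # every TE perfect and every divergence distinct, but force constant
        # length by using a single-family genome with no variance in length
        from repeatproof.synthetic_data import TEFamilySpec, generate_genome

        g = generate_genome(
            1, 100_000,
            [TEFamilySpec("f", 500, 6, mean_divergence=0.05)],
            gene_density=0, seed=4, truncation_prob=0.0,
        )
        assessments = [
            FeatureAssessment(t.feature_id, "TE", True, "c", 1.0, 1.0,
                              perfect=(i % 2 == 0))
            for i, t in enumerate(g.tes)
        ]
        with pytest.raises(ValueError, match="length"):
            build_design(assessments, g.tes, g)


class TestFitGlmm:
    def test_sigma_zero_reduces_to_plain_logistic(self):
        d = simulate_glmm_data(400, 8, {"length": -1.0, "divergence": 0.8},
                               sigma=0.0, seed=2)
        fit = fit_glmm(d, fix_sigma=0.0)
        logit = sm.Logit(d.y, d.X).fit(disp=0)
        assert np.abs(fit.beta - logit.params).max() < 1e-4

    def test_laplace_tracks_quadrature_on_small_toy(self):
        """At modest random-effect variance the Laplace likelihood agrees
        with adaptive 51-point Gauss-Hermite quadrature; an implementation
        error (mode, curvature or determinant term) would show up orders of
        magnitude above this tolerance."""
        beta = np.array([0.2, -0.5, 0.3, 0.4, -0.2, 0.1])
        sigma = 0.25
        for seed in range(5):
            d = simulate_glmm_data(12, 3, {"length": -0.5}, sigma=0.5, seed=seed)
            ll_lap = marginal_loglik(beta, sigma, d.X, d.y, d.family_index, 3)
            ll_q = marginal_loglik_quadrature(
                beta, sigma, d.X, d.y, d.family_index, 3
            )
            assert abs(ll_lap - ll_q) < 1e-3

    def test_parameter_recovery_within_two_se(self):
        truth = {"intercept": 0.3, "length": -1.0, "divergence": 0.8}
        d = simulate_glmm_data(3000, 50, truth, sigma=0.7, seed=0)
        fit = fit_glmm(d)
        for name, value in truth.items():
            i = fit.columns.index(name) if name != "intercept" else 0
            assert abs(fit.beta[i] - value) <= 2 * fit.se[i]
        assert abs(fit.sigma_family - 0.7) < 0.35

    def test_constant_outcome_rejected(self):
        d = simulate_glmm_data(50, 5, {}, sigma=0.5, seed=3)
        d.y[:] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_glmm(d)

    def test_single_family_rejected(self):
        d = simulate_glmm_data(50, 5, {}, sigma=0.5, seed=3)
        d.family_index[:] = 0
        d.family_labels = ["only"]
        with pytest.raises(ValueError, match="families"):
            fit_glmm(d)

    def test_complete_separation_raises(self):
        d = simulate_glmm_data(200, 4, {}, sigma=0.0, seed=8)
        d.y = (d.X[:, 1] > 0).astype(float)  # perfectly separable on length
        with pytest.raises((SeparationError, RuntimeError)):
            fit_glmm(d)


class TestPredictCurves:
    def _fit(self, beta, sigma=0.3, seed=4):
        d = simulate_glmm_data(800, 10, beta, sigma=sigma, seed=seed)
        return fit_glmm(d), d

    def test_negative_length_effect_gives_decreasing_curve(self):
        fit, d = self._fit({"length": -1.2})
        curves = predict_curves(fit, d, "length")
        probs = curves[curves.condition == "all"].probability.to_numpy()
        assert all(np.diff(probs) <= 1e-12)

    def test_unknown_covariate_rejected(self):
        fit, d = self._fit({"length": -1.0})
        with pytest.raises(ValueError, match="unknown covariate"):
            predict_curves(fit, d, "nope")

    def test_interaction_orders_conditions_along_divergence_grid(self):
        fit, d = self._fit({"divergence": 0.8, "div_x_high": 0.9}, seed=6)
        curves = predict_curves(
            fit, d, "divergence", conditions={"low": -1.0, "high": 1.0}
        )
        lo = curves[curves.condition == "low"].probability.to_numpy()
        hi = curves[curves.condition == "high"].probability.to_numpy()
        # positive interaction: the high-copies curve rises faster with
        # divergence, so it lies below at the low end if it crosses
        grid = np.linspace(-2, 2, 41)
        slope_lo = np.polyfit(grid, lo, 1)[0]
        slope_hi = np.polyfit(grid, hi, 1)[0]
        assert slope_hi > slope_lo
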