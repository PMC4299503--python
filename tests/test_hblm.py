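import numpy as np
import pytest

from agrimeta.effects import EffectSize, effects_from_records
from agrimeta.hblm import (
    DesignMatrix,
    FitResult,
    build_design,
    credible_interval,
    fit_hblm,
    heterogeneity,
    residuals_and_precision,
    typical_within_variance,
)
from agrimeta.simulate import SimulationConfig, simulate_meta_dataset

from .oracles import dense_grid_posterior, reml_random_effects


def _stub_fit(beta, post_se, N, p, tau2=0.0, s2=1.0):
    beta = np.atleast_1d(np.asarray(beta, float))
    post_se = np.atleast_1d(np.asarray(post_se, float))
    return FitResult(
        beta=beta, post_se=post_se, post_cov=np.diag(post_se**2),
        labels=["intercept"], tau2=tau2, tau=np.sqrt(tau2), var_tau=0.0,
        var_tau2=0.0, phi=0.0, phi_mean=0.0, I2=0.0, s2_typical=s2,
        residuals=np.zeros(N), N=N, p=p, log_evidence=0.0,
        tau_grid=np.array([0.0]), phi_grid=np.array([0.0]),
    )


class TestBuildDesign:
    def test_intercept_only(self, small_dataset):
        records, _ = small_dataset
        d = build_design(records, [])
        assert d.X.shape == (len(records), 1)
        assert np.all(d.X == 1.0)
        assert d.labels == ["intercept"]

    def test_treatment_contrasts_scale(self, small_dataset):
        records, _ = small_dataset
        d = build_design(records, [{"var": "scale", "reference": "farm"}])
        assert d.labels == ["intercept", "scale:field", "scale:plot"]
        # dummy rows match the records
        for row, rec in zip(d.X, records):
            assert row[1] == (1.0 if rec.scale == "field" else 0.0)
            assert row[2] == (1.0 if rec.scale == "plot" else 0.0)

    def test_separate_slopes_interaction(self, small_dataset):
        records, _ = small_dataset
        d = build_design(
            records,
            [{"var": "pct_arable", "kind": "continuous", "scale": 0.01,
              "by": "functional_group"}],
        )
        n_groups = len({r.functional_group for r in records})
        assert d.X.shape[1] == 1 + n_groups  # intercept + one slope per group
        slope_cols = d.X[:, 1:]
        # each row has exactly one nonzero slope entry: its own group
        assert np.all((slope_cols != 0).sum(axis=1) <= 1)

    def test_unseen_level_error(self, small_dataset):
        records, _ = small_dataset
        with pytest.raises(ValueError, match="unseen level"):
            build_design(records, [{"var": "scale", "levels": ["farm"],
                                    "reference": "farm"}])

    def test_rank_deficiency_error(self, small_dataset):
        records, _ = small_dataset
        with pytest.raises(ValueError, match="aliased"):
            build_design(
                records,
                [{"var": "pct_arable", "kind": "continuous"},
                 {"var": "pct_arable", "kind": "continuous"}],
            )

    def test_cell_means_counts_levels(self, small_dataset):
        records, _ = small_dataset
        d = build_design(records, [{"var": "crop_type", "cell_means": True}],
                         intercept=False)
        assert d.X.shape[1] == len({r.crop_type for r in records})
        assert np.all(d.X.sum(axis=1) == 1.0)


class TestFitHblm:
    def test_single_effect_fixed_effect_limit(self):
        fit = fit_hblm([EffectSize(0.5, 0.01, "a")], tau=0.0)
        assert fit.beta[0] == pytest.approx(0.5)
        assert fit.post_se[0] == pytest.approx(0.1)

    def test_two_effects_inverse_variance_mean(self, effects_factory):
        effects = effects_factory([0.5, 0.1], [0.01, 0.04])
        fit = fit_hblm(effects, tau=0.0)
        assert fit.beta[0] == pytest.approx(0.42)  # (50 + 2.5) / 125

    def test_fixed_effect_limit_equals_wls(self, small_effects):
        fit = fit_hblm(small_effects, tau=0.0)
        y = np.array([e.y for e in small_effects])
        w = 1.0 / np.array([e.v for e in small_effects])
        assert fit.beta[0] == pytest.approx((w * y).sum() / w.sum(), rel=1e-12)
        assert fit.post_se[0] == pytest.approx(1.0 / np.sqrt(w.sum()), rel=1e-12)

    def test_n_less_than_p_error(self, effects_factory):
        effects = effects_factory([0.5, 0.2], [0.01, 0.01])
        X = np.column_stack([np.ones(2), [0.0, 1.0], [1.0, 3.0]])
        design = DesignMatrix(X=X, labels=["a", "b", "c"])
        with pytest.raises(ValueError, match="N=2"):
            fit_hblm(effects, design, tau=0.0)

    def test_n_equal_p_error_when_tau_free(self, effects_factory):
        with pytest.raises(ValueError):
            fit_hblm(effects_factory([0.5], [0.01]))

    def test_nonpositive_variance_error(self, effects_factory):
        with pytest.raises(ValueError):
            fit_hblm(effects_factory([0.5, 0.2], [0.01, 0.0]))

    def test_independence_limit_phi_irrelevant(self, effects_factory):
        # one observation per publication: results invariant to phi
        effects = effects_factory([0.5, 0.1, 0.3, -0.2], [0.01, 0.04, 0.02, 0.05])
        fits = [fit_hblm(effects, phi=ph) for ph in (0.0, 0.5, 0.9)]
        for f in fits[1:]:
            assert f.beta[0] == pytest.approx(fits[0].beta[0], abs=1e-12)
            assert f.post_se[0] == pytest.approx(fits[0].post_se[0], abs=1e-12)

    def test_determinism_bitwise(self, small_effects):
        f1 = fit_hblm(small_effects)
        f2 = fit_hblm(small_effects)
        assert np.array_equal(f1.beta, f2.beta)
        assert np.array_equal(f1.post_se, f2.post_se)
        assert f1.tau2 == f2.tau2

    def test_row_order_invariance_of_estimates(self, small_effects):
        # blocks are regrouped internally; a shuffled input gives the same
        # posterior and correctly unscrambled residuals
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(small_effects))
        shuffled = [small_effects[i] for i in perm]
        f1 = fit_hblm(small_effects)
        f2 = fit_hblm(shuffled)
        assert f2.beta[0] == pytest.approx(f1.beta[0], abs=1e-10)
        np.testing.assert_allclose(f2.residuals, f1.residuals[perm], atol=1e-10)

    def test_oracle_equivalence_small(self, effects_factory):
        rng = np.random.default_rng(5)
        ys = rng.normal(0.3, 0.3, 10)
        vs = rng.uniform(0.005, 0.05, 10)
        pubs = [f"p{i // 2}" for i in range(10)]
        effects = effects_factory(ys, vs, pubs)
        fit = fit_hblm(effects, tau_grid_size=51)
        bm, se = dense_grid_posterior(
            ys, vs, pubs, np.ones((10, 1)), fit.tau_grid, fit.phi_grid
        )
        assert fit.beta[0] == pytest.approx(bm[0], abs=1e-10)
        assert fit.post_se[0] == pytest.approx(se[0], abs=1e-10)

    def test_reml_reduction_agreement(self):
        # independent observations, phi pinned to 0: agrees with a standard
        # REML random-effects fit within the documented tolerance
        cfg = SimulationConfig(n_publications=80, obs_per_pub_probs=(1.0,),
                               seed=11)
        records, _ = simulate_meta_dataset(cfg)
        effects = effects_from_records(records)
        fit = fit_hblm(effects, phi=0.0)
        y = [e.y for e in effects]
        v = [e.v for e in effects]
        mu, se, _ = reml_random_effects(y, v)
        assert fit.beta[0] == pytest.approx(mu, abs=0.01)
        assert fit.post_se[0] == pytest.approx(se, rel=0.10)

    def test_parameter_recovery_smoke(self):
        # truth beta0 = 0.3; a single fit should land within a few SEs
        records, _ = simulate_meta_dataset(SimulationConfig(seed=3))
        fit = fit_hblm(effects_from_records(records))
        assert fit.beta[0] == pytest.approx(0.3, abs=4 * fit.post_se[0])
        assert fit.phi >= 0.0

    def test_metaregression_slope_recovery(self):
        cfg = SimulationConfig(seed=21, beta={"pct_arable": 0.5})
        records, _ = simulate_meta_dataset(cfg)
        effects = effects_from_records(records)
        design = build_design(records, [{"var": "pct_arable",
                                         "kind": "continuous", "scale": 0.01}])
        fit = fit_hblm(effects, design)
        ci = credible_interval(fit)
        assert ci[1, 0] < 0.5 < ci[1, 1]


class TestCredibleInterval:
    def test_reproduces_printed_interval(self):
        # independent quantile oracle: t_{183, 0.975} = 1.9729
        fit = _stub_fit(0.296, 0.032945, N=184, p=1)
        ci = credible_interval(fit)
        assert ci[0, 0] == pytest.approx(0.231, abs=5e-4)
        assert ci[0, 1] == pytest.approx(0.361, abs=5e-4)

    def test_zero_width_limit(self):
        ci = credible_interval(_stub_fit(0.3, 0.0, N=10, p=1))
        assert ci[0, 0] == ci[0, 1] == 0.3

    def test_nesting(self):
        fit = _stub_fit(0.3, 0.05, N=20, p=1)
        ci95 = credible_interval(fit, 0.95)
        ci99 = credible_interval(fit, 0.99)
        assert ci99[0, 0] < ci95[0, 0] < ci95[0, 1] < ci99[0, 1]

    def test_level_out_of_range(self):
        with pytest.raises(ValueError):
            credible_interval(_stub_fit(0.3, 0.05, N=20, p=1), 1.5)


class TestHeterogeneity:
    def test_equal_weights_i2_75(self):
        s2 = 0.01
        fit = _stub_fit(0.0, 1.0, N=10, p=1, tau2=3 * s2)
        out = heterogeneity(fit, [s2] * 10)
        assert out["I2"] == pytest.approx(75.0)

    def test_tau_zero_i2_zero(self):
        fit = _stub_fit(0.0, 1.0, N=10, p=1, tau2=0.0)
        assert heterogeneity(fit, [0.01] * 10)["I2"] == 0.0

    def test_printed_pair_consistency(self):
        # back-solved oracle: tau = 0.304 with typical variance 0.002467
        fit = _stub_fit(0.296, 1.0, N=184, p=1, tau2=0.304**2)
        out = heterogeneity(fit, [0.002467] * 184)
        assert out["I2"] == pytest.approx(97.4, abs=0.05)

    def test_typical_variance_formula(self):
        v = np.array([0.01, 0.02, 0.04])
        w = 1.0 / v
        expected = (3 - 1) * w.sum() / (w.sum() ** 2 - (w**2).sum())
        assert typical_within_variance(v) == pytest.approx(expected, rel=1e-12)

    def test_single_effect_error(self):
        with pytest.raises(ValueError):
            typical_within_variance(np.array([0.01]))


class TestResidualsAndPrecision:
    def test_precision_arithmetic(self, effects_factory):
        effects = effects_factory([0.5, 0.1], [0.04, 0.01])
        fit = fit_hblm(effects, tau=0.0)
        pairs = residuals_and_precision(fit, effects)
        assert pairs[0][1] == pytest.approx(5.0)
        assert pairs[1][1] == pytest.approx(10.0)

    def test_symmetric_residuals_sum_zero(self, effects_factory):
        effects = effects_factory([-0.2, 0.2], [0.01, 0.01])
        fit = fit_hblm(effects, tau=0.0)
        pairs = residuals_and_precision(fit, effects)
        assert sum(r for r, _ in pairs) == pytest.approx(0.0, abs=1e-12)
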