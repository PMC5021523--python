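import itertools

import numpy as np
import pandas as pd
import pytest

from attnorm.popstats import (
    alpha_L_vs_distance, attention_surface, bayes_factor_config, binned_summary,
    compare_slopes, interaction_regression, one_sample_permutation_test,
    paired_permutation_test,
)


def _index_table(n, b1=0.1, b2=0.0, b3=1.0, noise=0.05, seed=0, config_shift=0.0):
    """Synthetic pair-index rows with a known linear generative rule."""
    rng = np.random.default_rng(seed)
    sel = rng.uniform(0, 1, n)
    sup = rng.uniform(-0.2, 0.6, n)
    cfg = rng.choice(["crf-crf", "srf-crf"], n)
    shift = np.where(cfg == "srf-crf", config_shift, 0.0)
    am = b1 * sel + (b2 + shift) * sup + b3 * sel * sup + rng.normal(0, noise, n)
    return pd.DataFrame(
        {"selectivity": sel, "suppression": sup, "attention_modulation": am,
         "rf_configuration": cfg, "pair_included": True}
    )


class TestInteractionRegression:
    def test_recovers_null_interaction(self):
        df = _index_table(2000, b3=0.0, seed=1)
        r = interaction_regression(df)
        lo, hi = r.conf_int.loc["selectivity:suppression"]
        assert lo <= 0.0 <= hi

    def test_recovers_known_interaction(self):
        df = _index_table(2000, b3=1.5, seed=2)
        r = interaction_regression(df)
        lo, hi = r.conf_int.loc["selectivity:suppression"]
        assert lo <= 1.5 <= hi
        assert r.pvalues["selectivity:suppression"] < 1e-6

    def test_coverage_of_confidence_intervals(self):
        """95% CIs cover the true interaction at roughly nominal rate."""
        hits = 0
        reps = 200
        for i in range(reps):
            r = interaction_regression(_index_table(150, b3=0.8, seed=1000 + i))
            lo, hi = r.conf_int.loc["selectivity:suppression"]
            hits += lo <= 0.8 <= hi
        # binomial 3-sigma band around 0.95 at 200 reps
        assert 0.90 <= hits / reps <= 0.995

    def test_suppression_main_effect_is_effect_at_zero_selectivity(self):
        df = _index_table(3000, b1=0.0, b2=0.4, b3=0.0, noise=0.02, seed=3)
        r = interaction_regression(df)
        assert r.params["suppression"] == pytest.approx(0.4, abs=0.05)

    def test_collinear_design_rejected(self):
        df = _index_table(100, seed=4)
        df["suppression"] = df["selectivity"]
        with pytest.raises(ValueError, match="collinear|rank"):
            interaction_regression(df)

    def test_requires_minimum_rows(self):
        with pytest.raises(ValueError):
            interaction_regression(_index_table(5))


class TestCompareSlopes:
    def test_detects_simulated_slope_difference(self):
        df = _index_table(2000, b2=0.3, config_shift=0.3, noise=0.05, seed=5)
        p, _ = compare_slopes(df)
        assert p < 0.01

    def test_null_calibration(self):
        """With no true group difference, the test rejects at ~alpha."""
        rejects = 0
        reps = 120
        for i in range(reps):
            p, _ = compare_slopes(_index_table(200, seed=2000 + i))
            rejects += p < 0.05
        rate = rejects / reps
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_single_group_rejected(self):
        df = _index_table(100, seed=6)
        df["rf_configuration"] = "crf-crf"
        with pytest.raises(ValueError):
            compare_slopes(df)

    def test_three_way_term_option(self):
        p_all, _ = compare_slopes(_index_table(500, seed=7))
        p_3, _ = compare_slopes(_index_table(500, seed=7), terms="three_way")
        assert 0 <= p_all <= 1 and 0 <= p_3 <= 1


class TestBayesFactor:
    @pytest.mark.parametrize("method", ["jzs", "bic"])
    def test_favors_configuration_free_model_under_null(self, method):
        df = _index_table(1500, seed=8)
        assert bayes_factor_config(df, method=method) > 1.0

    @pytest.mark.parametrize("method", ["jzs", "bic"])
    def test_detects_configuration_effect(self, method):
        df = _index_table(1500, config_shift=0.5, noise=0.05, seed=9)
        assert bayes_factor_config(df, method=method) < 1.0

    def test_identical_models_have_unit_bayes_factor(self):
        """A model compared against itself has BF 1 (sanity of the marginal
        likelihood ratio)."""
        from attnorm.popstats import _jzs_log_bf_vs_null

        lbf = _jzs_log_bf_vs_null(0.3, 500, 3, np.sqrt(2) / 4)
        assert np.isfinite(lbf)
        assert np.exp(lbf - lbf) == pytest.approx(1.0)
        df = _index_table(800, seed=10)
        b = bayes_factor_config(df, method="bic")
        assert b == pytest.approx(
            1.0 / bayes_factor_config_reversed_bic(df), rel=1e-6
        )


def bayes_factor_config_reversed_bic(df):
    """Oracle helper: BIC Bayes factor computed with roles swapped."""
    import statsmodels.api as sm
    from attnorm.popstats import _design_matrices

    y, X_free, X_cfg = _design_matrices(df, "rf_configuration")
    b_free = sm.OLS(y, sm.add_constant(X_free)).fit().bic
    b_cfg = sm.OLS(y, sm.add_constant(X_cfg)).fit().bic
    return float(np.exp((b_free - b_cfg) / 2.0))


class TestPermutationTests:
    def test_identical_samples_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert paired_permutation_test(x, x) == 1.0

    def test_exact_enumeration_matches_brute_force(self):
        """n=5 exhaustive sign-flip p agrees with an itertools oracle."""
        x = np.array([2.1, 0.4, 1.3, 0.8, 1.9])
        y = np.array([1.0, 0.9, 0.2, 0.5, 0.3])
        d = x - y

        def tstat(v):
            v = np.asarray(v)
            sd = v.std(ddof=1)
            return np.inf if sd == 0 else v.mean() / (sd / np.sqrt(len(v)))

        t_obs = abs(tstat(d))
        hits = sum(
            abs(tstat(d * np.array(s))) >= t_obs - 1e-12
            for s in itertools.product([-1, 1], repeat=5)
        )
        assert paired_permutation_test(x, y, n_perm=10_000) == pytest.approx(hits / 32)

    def test_large_consistent_shift_is_significant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(2.0, 0.3, 20)
        y = rng.normal(0.0, 0.3, 20)
        assert paired_permutation_test(x, y, n_perm=20_000, seed=1) <= 0.001

    def test_one_sample_all_zero(self):
        assert one_sample_permutation_test(np.zeros(6)) == 1.0

    def test_one_sample_strong_positive(self):
        assert one_sample_permutation_test(np.full(15, 2.0) ) < 0.001

    def test_one_sample_type_i_calibration(self):
        """Symmetric null: rejection rate at alpha=0.05 stays near nominal."""
        rng = np.random.default_rng(3)
        rejects = sum(
            one_sample_permutation_test(rng.normal(0, 1, 12), n_perm=5000) < 0.05
            for _ in range(300)
        )
        rate = rejects / 300
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 300)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_permutation_test(np.ones(3), np.ones(4))


class TestBinnedSummary:
    def test_constant_y_flat_with_zero_sem(self):
        c = binned_summary(np.linspace(0, 1, 50), np.full(50, 2.0), bins=5)
        assert np.allclose(c.mean, 2.0) and np.allclose(c.sem, 0.0)
        assert (c.count >= 1).all()

    def test_identity_trend_recovered(self):
        x = np.linspace(0, 1, 500)
        c = binned_summary(x, x, bins=10)
        assert np.allclose(c.mean, c.bin_centers, atol=0.06)
        assert np.all(np.diff(c.mean) > 0)


class TestAlphaLVsDistance:
    def _fake_results(self, n=40, seed=0, l_scale=1.0, a_scale=3.0):
        """Synthetic fits + geometries with L decaying faster than alpha."""
        import attnorm as an
        from attnorm.model import FitResult, ModelParams
        from attnorm.rf import RFGeometry

        design = an.TaskDesign()
        rng = np.random.default_rng(seed)
        loc_xy = np.array([design.location_xy(l) for l in (1, 2, 3)])
        fits, geos = [], []
        for _ in range(n):
            center = loc_xy.mean(axis=0) + rng.normal(0, 1.5, 2)
            d = np.linalg.norm(loc_xy - center, axis=1)
            a = np.exp(-d / a_scale)
            a = a / a[0]
            L = 10 * np.exp(-0.5 * (d / l_scale) ** 2)
            p = ModelParams(L=np.repeat(L[:, None], 2, axis=1),
                            alpha2=a[1], alpha3=a[2], sigma=0.1, beta=1.5)
            fits.append(FitResult(params=p, sse=0.0, variant="full", n_free=10,
                                  converged=True, n_restarts=1, n_iterations=1))
            geos.append(RFGeometry(center_of_mass=center, amplitude=10.0,
                                   center=center, cov=np.eye(2),
                                   explained_variance=0.95, reliable=True))
        return design, fits, geos

    def test_excitation_falls_below_suppression_at_distance(self):
        design, fits, geos = self._fake_results()
        a_curve, l_curve = alpha_L_vs_distance(fits, geos, design, bins=4)
        assert l_curve.mean[-1] < a_curve.mean[-1]
        assert np.all(a_curve.mean <= 1.0 + 1e-9)
        np.testing.assert_array_equal(a_curve.bin_centers, l_curve.bin_centers)

    def test_mahalanobis_metric_variant(self):
        design, fits, geos = self._fake_results()
        a_curve, l_curve = alpha_L_vs_distance(
            fits, geos, design, metric="mahalanobis", bins=3
        )
        assert len(a_curve.mean) == len(l_curve.mean) > 0


class TestAttentionSurface:
    def test_constant_modulation_gives_constant_surface(self):
        df = _index_table(200, seed=11)
        df["attention_modulation"] = 0.25
        _, _, surf = attention_surface(df)
        assert np.allclose(surf, 0.25, atol=1e-9)

    def test_high_high_corner_maximal_for_interactive_rule(self):
        df = _index_table(3000, b1=0.0, b2=0.0, b3=1.0, noise=0.02, seed=12)
        GX, GY, surf = attention_surface(df, grid_size=21)
        corner = surf[-1, -1]  # high selectivity, high suppression
        assert corner == surf.max()

    def test_grid_shape(self):
        df = _index_table(200, seed=13)
        GX, GY, surf = attention_surface(df, grid_size=15)
        assert GX.shape == GY.shape == surf.shape == (15, 15)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            attention_surface(_index_table(20, seed=14))
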