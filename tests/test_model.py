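import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import attnorm as an
from attnorm.model import (
    ConditionDesign, ModelParams, cross_validate, explained_variance, fit,
    nested_f_test, predict, suppression_index_from_params,
)
from attnorm.neurometrics import suppression_index
from attnorm.synth import expected_count, simulate_trials
from attnorm.task import AWAY, Condition

from conftest import random_params


def brute_force_response(params: ModelParams, condition: Condition) -> float:
    """Independent literal transcription of the normalization equations."""
    if condition.is_blank:
        return 0.0
    alpha = [1.0, params.alpha2, params.alpha3]
    num = 0.0
    den = params.sigma
    for (loc, ori) in condition.stimuli:
        if condition.attention == loc:
            num += params.beta * params.L[loc - 1][ori - 1]
            den += params.beta * alpha[loc - 1]
        else:
            num += params.L[loc - 1][ori - 1]
            den += alpha[loc - 1]
    return num / den


class TestPredict:
    def test_matches_brute_force_oracle(self, conditions):
        """predict() agrees with a literal equation transcription over a
        1000-point random parameter grid."""
        rng = np.random.default_rng(1)
        for _ in range(1000 // len(conditions) + 1):
            p = random_params(rng)
            for c in conditions:
                assert predict(p, c) == pytest.approx(
                    brute_force_response(p, c), abs=1e-12
                )

    def test_vectorised_design_agrees_with_scalar(self, conditions):
        rng = np.random.default_rng(2)
        des = ConditionDesign(conditions)
        for _ in range(20):
            p = random_params(rng)
            vec = des.predict_vector(p)
            scal = np.array([predict(p, c) for c in conditions])
            np.testing.assert_allclose(vec, scal, atol=1e-12)

    def test_agrees_with_generator_expected_count(self, population, conditions):
        """The model's predict and the generator's expected_count share one
        contract."""
        for n in population[:3]:
            for c in conditions:
                assert predict(n.params, c) == expected_count(n, c)


class TestFit:
    def test_noiseless_parameter_recovery(self, population, conditions):
        """Fitting noiseless model responses recovers every parameter to 1%
        (with a 1e-3-count absolute floor) and near-zero SSE."""
        for n in population[:5]:
            y = np.array([expected_count(n, c) for c in conditions])
            fr = fit(y, conditions, n_restarts=3, seed=0)
            assert fr.sse < 1e-8
            assert np.isclose(fr.params.beta, n.beta, rtol=0.01, atol=1e-3)
            assert np.isclose(fr.params.alpha2, n.alpha[1], rtol=0.01, atol=1e-3)
            assert np.isclose(fr.params.alpha3, n.alpha[2], rtol=0.01, atol=1e-3)
            assert np.allclose(fr.params.L, n.L, rtol=0.01, atol=1e-3)

    def test_nested_variants_never_beat_full_on_training_sse(self, population, conditions):
        y = np.array([expected_count(population[1], c) for c in conditions])
        full = fit(y, conditions, n_restarts=3, seed=0)
        for variant, kw in [("fixed_alpha", {}), ("no_sigma", {}),
                            ("single_L", {}), ("fixed_beta", {"fixed_beta_value": 1.5})]:
            red = fit(y, conditions, variant=variant, n_restarts=3, seed=0, **kw)
            assert red.sse >= full.sse - 1e-9

    def test_single_L_strictly_worse_for_selective_neuron(self, conditions):
        n = an.ModelParams(L=np.array([[12, 2], [6, 1], [3, 0.5]]),
                           alpha2=0.8, alpha3=0.6, sigma=0.1, beta=1.6)
        des = ConditionDesign(conditions)
        y = des.predict_vector(n)
        full = fit(y, conditions, n_restarts=3, seed=0)
        single = fit(y, conditions, variant="single_L", n_restarts=3, seed=0)
        assert single.sse > full.sse + 1e-3

    def test_no_sigma_cannot_express_single_stimulus_attention(self, conditions):
        """Without sigma, an attended lone stimulus predicts identically to the
        unattended one (beta cancels), so those conditions are mispredicted
        for a neuron with true sigma > 0 and beta > 1."""
        truth = an.ModelParams(L=np.array([[10, 4], [6, 2], [3, 1]]),
                               alpha2=0.9, alpha3=0.7, sigma=1.5, beta=2.0)
        des = ConditionDesign(conditions)
        y = des.predict_vector(truth)
        ns = fit(y, conditions, variant="no_sigma", n_restarts=3, seed=0)
        full = fit(y, conditions, variant="full", n_restarts=3, seed=0)
        for loc, ori in ((1, 1), (1, 2), (2, 1), (2, 2), (3, 1), (3, 2)):
            att = Condition(((loc, ori),), loc)
            away = Condition(((loc, ori),), AWAY)
            # algebraic identity: attended == unattended prediction
            assert predict(ns.params, att) == pytest.approx(
                predict(ns.params, away), abs=1e-9
            )
            obs_att = des.predict_vector(truth)[conditions.index(att)]
            obs_away = des.predict_vector(truth)[conditions.index(away)]
            gap = abs(obs_att - obs_away)
            err = abs(predict(ns.params, att) - obs_att) + abs(
                predict(ns.params, away) - obs_away
            )
            # one shared prediction cannot hit both targets: total error >= gap
            assert err >= gap - 1e-9
            assert gap > 0.1  # the attended-single effect no_sigma must miss
        assert full.sse < 1e-8 < ns.sse

    def test_scale_identifiability(self, conditions):
        """Scaling all responses by c scales L by c and leaves alpha and beta
        unchanged (alpha_1 pins the suppressive scale)."""
        truth = an.ModelParams(L=np.array([[8, 3], [5, 2], [2, 1]]),
                               alpha2=0.7, alpha3=1.3, sigma=0.2, beta=1.7)
        des = ConditionDesign(conditions)
        y = des.predict_vector(truth)
        f1 = fit(y, conditions, n_restarts=2, seed=0)
        f2 = fit(3.0 * y, conditions, n_restarts=2, seed=0)
        np.testing.assert_allclose(f2.params.L, 3.0 * f1.params.L, rtol=0.02, atol=1e-2)
        assert f2.params.alpha2 == pytest.approx(f1.params.alpha2, rel=0.02, abs=1e-3)
        assert f2.params.beta == pytest.approx(f1.params.beta, rel=0.02)

    def test_rejects_bad_input(self, conditions):
        with pytest.raises(ValueError):
            fit(np.ones(10), conditions)
        with pytest.raises(ValueError):
            fit(np.full(36, np.nan), conditions)


class TestExplainedVariance:
    def test_perfect_and_affine(self):
        y = np.array([1.0, 3.0, 2.0, 5.0])
        assert explained_variance(y, y) == pytest.approx(1.0)
        # squared correlation ignores sign and offset (documented caveat)
        assert explained_variance(-y + 7, y) == pytest.approx(1.0)

    def test_matches_brute_force_correlation(self):
        p = np.array([2.0, 4.0, 1.0, 6.0])
        o = np.array([1.5, 3.0, 2.5, 5.0])
        # independent oracle: direct covariance formula
        num = np.mean((p - p.mean()) * (o - o.mean()))
        r = num / (p.std() * o.std())
        assert explained_variance(p, o) == pytest.approx(r**2, abs=1e-12)

    def test_constant_observed_is_nan(self):
        assert np.isnan(explained_variance(np.array([1, 2, 3.0]), np.ones(3)))


class TestCrossValidation:
    def _noiseless_table(self, params, conditions, reps=4):
        des = ConditionDesign(conditions)
        y = des.predict_vector(params)
        rows = []
        for c, mu in zip(conditions, y):
            stim = "+".join(f"l{l}o{o}" for l, o in c.stimuli) or "blank"
            for t in range(reps):
                rows.append((0, c.condition_id, stim, str(c.attention), t, mu))
        return pd.DataFrame(rows, columns=["neuron_id", "condition_id", "stimuli",
                                           "attention", "trial", "count"])

    def test_noiseless_duplicated_trials_give_cv_equal_training(self, conditions):
        truth = an.ModelParams(L=np.array([[9, 3], [5, 2], [2, 1]]),
                               alpha2=0.8, alpha3=1.1, sigma=0.15, beta=1.5)
        tt = self._noiseless_table(truth, conditions)
        fr = cross_validate(tt, conditions, n_repeats=2, seed=0, n_restarts=2)
        assert fr.cv_explained_variance > 0.999

    def test_deterministic_under_seed(self, neuron, conditions):
        tt = simulate_trials(neuron, conditions, 10, seed=4)
        a = cross_validate(tt, conditions, n_repeats=2, seed=7, n_restarts=1)
        b = cross_validate(tt, conditions, n_repeats=2, seed=7, n_restarts=1)
        assert a.cv_explained_variance == b.cv_explained_variance

    def test_single_trial_conditions_excluded(self, neuron, conditions):
        tt = simulate_trials(neuron, conditions, 4, seed=4)
        tt = tt[~((tt.condition_id == conditions[0].condition_id) & (tt.trial > 0))]
        fr = cross_validate(tt, conditions, n_repeats=1, seed=0, n_restarts=1)
        assert fr.notes["n_conditions_skipped"] == 1


class TestNestedFTest:
    def test_identical_fits_give_p_one(self, conditions):
        y = np.arange(36.0) + 1
        full = fit(y, conditions, n_restarts=1, seed=0)
        reduced = fit(y, conditions, variant="no_sigma", n_restarts=1, seed=0)
        reduced.sse = full.sse  # same error, extra constraint buys nothing
        res = nested_f_test(full, reduced, 36)
        assert res.f == 0.0 and res.p == 1.0

    def test_df_bookkeeping(self, conditions):
        """Full model has 10 free parameters (6 L, alpha_2, alpha_3, sigma,
        beta); dropping sigma gives df 1 over 36-10 residual df."""
        y = np.arange(36.0) + 1
        full = fit(y, conditions, n_restarts=1, seed=0)
        ns = fit(y, conditions, variant="no_sigma", n_restarts=1, seed=0)
        sl = fit(y, conditions, variant="single_L", n_restarts=1, seed=0)
        assert full.n_free == 10 and ns.n_free == 9 and sl.n_free == 5
        res = nested_f_test(full, ns, 36)
        assert (res.df_num, res.df_den) == (1, 26)
        assert nested_f_test(full, sl, 36).df_num == 5

    def test_strong_sigma_effect_detected(self, conditions):
        truth = an.ModelParams(L=np.array([[10, 4], [6, 2], [3, 1]]),
                               alpha2=0.9, alpha3=0.7, sigma=1.5, beta=2.0)
        des = ConditionDesign(conditions)
        y = des.predict_vector(truth)
        full = fit(y, conditions, n_restarts=3, seed=0)
        ns = fit(y, conditions, variant="no_sigma", n_restarts=3, seed=0)
        assert nested_f_test(full, ns, 36).p < 0.01


class TestSuppressionFromParams:
    def test_hand_value(self):
        p = an.ModelParams(L=np.array([[8.0, 0], [0, 0], [0, 0]]),
                           alpha2=1.0, alpha3=1.0, sigma=0.0, beta=1.0)
        # P alone: 8/1 = 8; pair adds only suppression: 8/2 = 4 -> (8-4)/12
        assert suppression_index_from_params(
            p, ((1, 1), (2, 1))
        ) == pytest.approx(1 / 3, abs=1e-12)

    def test_adding_nothing_gives_zero(self):
        p = an.ModelParams(L=np.array([[8.0, 0], [0, 0], [0, 0]]),
                           alpha2=0.0, alpha3=1.0, sigma=0.0)
        assert suppression_index_from_params(p, ((1, 1), (2, 1))) == 0.0

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_closed_form_equals_index_of_predictions(self, seed):
        """The parameter expression reproduces suppression_index applied to
        model predictions exactly, for arbitrary parameters."""
        rng = np.random.default_rng(seed)
        p = random_params(rng)
        pair = ((1, 1), (2, 2))
        P = predict(p, Condition((pair[0],), AWAY))
        PN = predict(p, Condition(pair, AWAY))
        if P + PN <= 0:
            return
        assert suppression_index_from_params(p, pair) == pytest.approx(
            suppression_index(P, PN), abs=1e-12
        )
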