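import itertools

import numpy as np
import pytest

from motiveloop import (
    Categorical,
    CompletePosterior,
    DirichletContextPredictor,
    FiniteSpace,
    FixedNextSensorPredictor,
    GenerativeModel,
    History,
    ImpossibleHistoryError,
    ParameterBelief,
    ParameterPoint,
    UnsupportedBackendError,
    complete_posterior,
    history_space_model,
    posterior_factor,
    predictive_factor,
    url_specialize,
)
from motiveloop.fixtures import (
    det2,
    ensemble_model_for,
    env_to_parameter_point,
    generative_model_for,
    noisy2,
)
from motiveloop.genmodel import DirichletBlocks
from motiveloop.probtables import CondTable

from .oracles import brute_evidence, brute_joint_future


class TestPosteriorFactor:
    def test_t1_weights_match_simplex_quadrature(self):
        # asymmetric priors; the component weight of ê_0 = e is
        # E[θ³_e] · E[θ¹_{e,s0}] under the prior, by direct numerical
        # integration of the two Beta marginals
        env = noisy2()
        xi1 = np.array([[3.0, 1.0], [1.5, 2.5]])
        gm = generative_model_for(env, n=1, xi1=xi1)
        blocks = gm.prior.dirichlet
        blocks.xi3[:] = [2.0, 1.0]
        pf = posterior_factor(gm, History(("x0",), ()))
        x = np.linspace(1e-6, 1 - 1e-6, 20_001)

        def beta_mean(a, b):
            dens = x ** (a - 1) * (1 - x) ** (b - 1)
            return np.trapezoid(x * dens, x) / np.trapezoid(dens, x)

        w = np.zeros(2)
        for e in range(2):
            w[e] = beta_mean(blocks.xi3[e], blocks.xi3[1 - e]) \
                * beta_mean(xi1[e, 0], xi1[e, 1])
        w /= w.sum()
        got = np.zeros(2)
        for c in pf.components:
            got[c.e_prev] += c.weight
        assert np.allclose(got, w, atol=1e-6)
        # counts incremented at the component's ê_0
        for c in pf.components:
            assert c.counts.xi3[c.e_prev] == blocks.xi3[c.e_prev] + 1
            assert c.counts.xi1[c.e_prev, 0] == xi1[c.e_prev, 0] + 1

    def test_single_true_environment_weight_one(self):
        gm = ensemble_model_for([det2()], n=1)
        h = History(("x0", "x1", "x1"), ("flip", "stay"))
        pf = posterior_factor(gm, h)
        assert len(pf.components) == 1
        assert pf.components[0].weight == pytest.approx(1.0)

    @pytest.mark.parametrize("backend", ["dirichlet", "ensemble"])
    def test_weights_sum_to_one(self, backend):
        env = noisy2()
        gm = (generative_model_for(env, n=1) if backend == "dirichlet"
              else ensemble_model_for([det2(), noisy2()], n=1))
        pf = posterior_factor(gm, History(("x0", "x0"), ("stay",)))
        assert pf.weights().sum() == pytest.approx(1.0, abs=1e-12)
        assert np.exp(pf.log_evidence) == pytest.approx(
            brute_evidence(gm, History(("x0", "x0"), ("stay",))), rel=1e-10)

    def test_impossible_history_raises(self):
        gm = ensemble_model_for([det2()], n=1)
        with pytest.raises(ImpossibleHistoryError):
            posterior_factor(gm, History(("x0", "x0"), ("flip",)))

    def test_empty_history_rejected(self, gm_dirichlet):
        with pytest.raises(ValueError):
            posterior_factor(gm_dirichlet, History.empty())


class TestCompletePosterior:
    @pytest.mark.parametrize("backend", ["dirichlet", "ensemble"])
    @pytest.mark.parametrize("hist,future", [
        ((("x0",), ()), ("stay",)),
        ((("x0", "x1"), ("flip",)), ("stay", "flip")),
    ])
    def test_joint_matches_brute_force(self, backend, hist, future):
        env = noisy2()
        gm = (generative_model_for(env, n=len(future))
              if backend == "dirichlet"
              else ensemble_model_for([det2(), noisy2()], n=len(future)))
        h = History(*hist)
        cp = complete_posterior(gm, h)
        jt = cp.joint_future(future)
        expect = brute_joint_future(gm, h, future)
        assert np.abs(jt.probs - expect).max() < 1e-10
        assert jt.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_point_mass_belief_equals_predictive_factor(self):
        gm = ensemble_model_for([det2()], n=1)
        h = History(("x0", "x1"), ("flip",))
        cp = complete_posterior(gm, h)
        jt = cp.joint_future(("stay",))
        pf = predictive_factor(gm, gm.prior.points[0], ("stay",), "x1",
                               t_start=2)
        assert np.allclose(jt.probs, pf.probs, atol=1e-14)

    def test_symmetric_histories_give_relabeled_posteriors(self):
        # symmetric two-state world with uniform start: swapping all
        # labels in the history swaps the posterior the same way
        env = noisy2()
        init = Categorical(env.E, np.array([0.5, 0.5]))
        from motiveloop.paloop import EnvironmentSpec
        sym = EnvironmentSpec(env.E, env.S, env.A, init, env.trans, env.sensor)
        gm = generative_model_for(sym, n=1)
        cp_a = complete_posterior(gm, History(("x0", "x0"), ("stay",)))
        cp_b = complete_posterior(gm, History(("x1", "x1"), ("stay",)))
        pa = cp_a.sensor_path_predictive(("stay",))
        pb = cp_b.sensor_path_predictive(("stay",))
        assert np.allclose(pa, pb[::-1], atol=1e-12)

    def test_predictive_marginals_consistent(self, gm_ensemble):
        h = History(("x0", "x0"), ("stay",))
        cp = complete_posterior(gm_ensemble, h)
        je = cp.posterior_predictive_env(("flip",))
        js = cp.posterior_predictive_sensors(("flip",))
        assert je.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert js.probs.sum() == pytest.approx(1.0, abs=1e-12)
        jt = cp.joint_future(("flip",))
        assert np.allclose(js.probs, jt.probs.sum(axis=1), atol=1e-14)

    def test_deterministic_point_sensor_path(self):
        gm = ensemble_model_for([det2()], n=2)
        cp = complete_posterior(gm, History(("x0",), ()))
        js = cp.posterior_predictive_sensors(("flip", "stay", "flip"))
        # x0 -flip-> x1 -stay-> x1 -flip-> x0
        assert js.probs[1, 1, 0] == pytest.approx(1.0)

    def test_factorization_identity_pointwise(self):
        # complete posterior = sum of weight x predictive factor
        gm = ensemble_model_for([det2(), noisy2()], n=1)
        h = History(("x0", "x1"), ("flip",))
        cp = complete_posterior(gm, h)
        jt = cp.joint_future(("stay", "flip"))
        acc = np.zeros_like(jt.probs)
        for c in cp.factor.components:
            pf = predictive_factor(gm, c.theta, ("stay", "flip"),
                                   gm.Ehat.labels[c.e_prev], t_start=2)
            acc += c.weight * pf.probs
        assert np.abs(jt.probs - acc).max() < 1e-12


class TestParameterPosterior:
    def _sensor_only_model(self, rows, weights=None):
        E = FiniteSpace("Ehat", ("h0",))
        S = FiniteSpace("Shat", ("s0", "s1"))
        A = FiniteSpace("Ahat", ("a0",))
        pts = [
            ParameterPoint(
                CondTable(S, (E,), np.array([row])),
                CondTable(E, (A, E), np.ones((1, 1, 1))),
                Categorical(E, np.array([1.0])),
            )
            for row in rows
        ]
        prior = ParameterBelief.from_points(pts, weights)
        return GenerativeModel(E, S, A, prior, ("rolling", 1))

    def test_point_mass_prior_unchanged(self):
        gm = self._sensor_only_model([[0.7, 0.3]])
        cp = complete_posterior(gm, History(("s0", "s1"), ("a0",)))
        post = cp.parameter_posterior()
        assert np.allclose(post.weights, [1.0])

    def test_zero_likelihood_point_eliminated(self):
        gm = self._sensor_only_model([[1.0, 0.0], [0.0, 1.0]])
        cp = complete_posterior(gm, History(("s0",), ()))
        post = cp.parameter_posterior()
        # the inconsistent model carries zero mass: only θ_A survives
        assert np.allclose(post.weights, [1.0])
        assert np.allclose(post.points[0].t1, [[1.0, 0.0]])

    def test_one_step_bayes_rule_weights(self):
        gm = self._sensor_only_model([[0.8, 0.2], [0.2, 0.8]])
        cp = complete_posterior(gm, History(("s0",), ()))
        post = cp.parameter_posterior()
        assert np.allclose(post.weights, [0.8, 0.2])

    def test_independent_of_future_actions(self, gm_ensemble):
        # the belief over θ never depends on contemplated actions
        h = History(("x0", "x0"), ("stay",))
        cp = complete_posterior(gm_ensemble, h)
        w = cp.parameter_posterior().weights
        # conditioning on future sensors and marginalizing them out
        # recovers the unconditional posterior, for either action
        for a in (("stay",), ("flip",)):
            js = cp.posterior_predictive_sensors(a).probs
            mixed = np.zeros_like(w)
            for i, s in enumerate(gm_ensemble.Shat.labels):
                cond = cp.parameter_posterior_given_sensors(a, (s,))
                mixed += js[i] * cond.weights
            assert np.allclose(mixed, w, atol=1e-12)

    def test_conditional_requires_ensemble_backend(self, gm_dirichlet):
        cp = complete_posterior(gm_dirichlet, History(("x0",), ()))
        with pytest.raises(UnsupportedBackendError):
            cp.parameter_posterior_given_sensors(("stay",), ("x0",))

    def test_dirichlet_posterior_is_count_mixture(self, gm_dirichlet):
        cp = complete_posterior(gm_dirichlet, History(("x0", "x1"), ("flip",)))
        post = cp.parameter_posterior()
        assert post.backend == "dirichlet_mixture"
        total = sum(w for w, _ in post.mixture)
        assert total == pytest.approx(1.0, abs=1e-12)


class TestBackendConvergence:
    def test_dirichlet_agrees_with_fine_grid_ensemble(self):
        # |Ehat| = 1, |S| = 2: the flat Dirichlet sensor model against a
        # uniform grid over the one-dimensional simplex, step 1e-3
        E = FiniteSpace("Ehat", ("h0",))
        S = FiniteSpace("Shat", ("s0", "s1"))
        A = FiniteSpace("Ahat", ("a0",))
        blocks = DirichletBlocks(np.ones((1, 2)), np.ones((1, 1, 1)),
                                 np.ones(1))
        gm_d = GenerativeModel(E, S, A,
                               ParameterBelief.from_dirichlet(blocks),
                               ("rolling", 0))
        grid = np.arange(5e-4, 1.0, 1e-3)
        pts = [
            ParameterPoint(
                CondTable(S, (E,), np.array([[p, 1 - p]])),
                CondTable(E, (A, E), np.ones((1, 1, 1))),
                Categorical(E, np.array([1.0])),
            )
            for p in grid
        ]
        gm_e = GenerativeModel(E, S, A, ParameterBelief.from_points(pts),
                               ("rolling", 0))
        h = History(("s0", "s0", "s1"), ("a0", "a0"))
        pd = complete_posterior(gm_d, h).sensor_path_predictive(("a0",))
        pe = complete_posterior(gm_e, h).sensor_path_predictive(("a0",))
        assert np.abs(pd - pe).max() < 1e-3
        # and the Dirichlet predictive is the Laplace rule (2+1)/(3+2)
        assert pd[0] == pytest.approx(3 / 5, abs=1e-12)


class TestURL:
    def test_single_model_weights_stay_one(self):
        S = FiniteSpace("S", ("s0", "s1"))
        A = FiniteSpace("A", ("a0",))
        m = FixedNextSensorPredictor(S, lambda s, a, act: [0.6, 0.4])
        post = url_specialize(S, A, [m], [1.0], History(("s0", "s1"), ("a0",)))
        assert np.allclose(post.weights, [1.0])
        assert np.allclose(post.predictive("a0").probs, [0.6, 0.4])

    def test_two_deterministic_models_one_observation(self):
        S = FiniteSpace("S", ("s0", "s1"))
        A = FiniteSpace("A", ("a0",))
        m0 = FixedNextSensorPredictor(S, lambda s, a, act: [1.0, 0.0])
        m1 = FixedNextSensorPredictor(S, lambda s, a, act: [0.0, 1.0])
        post = url_specialize(S, A, [m0, m1], [0.5, 0.5], History(("s0",), ()))
        assert np.allclose(post.weights, [1.0, 0.0])

    def test_laplace_rule_for_flat_context_predictor(self):
        S = FiniteSpace("S", ("s0", "s1"))
        A = FiniteSpace("A", ("a0",))
        pred = DirichletContextPredictor(S, 1.0, context_fn=lambda s, a: ())
        post = url_specialize(S, A, [pred], [1.0],
                              History(("s0", "s0"), ("a0",)))
        assert np.allclose(post.predictive("a0").probs, [2 / 3, 1 / 3])

    def test_matches_history_space_posterior_factor(self):
        S = FiniteSpace("S", ("s0", "s1"))
        A = FiniteSpace("A", ("a0", "a1"))
        m0 = FixedNextSensorPredictor(
            S, lambda s, a, act: [0.8, 0.2] if act != "a1" else [0.4, 0.6])
        m1 = FixedNextSensorPredictor(S, lambda s, a, act: [0.3, 0.7])
        h = History(("s0", "s1"), ("a1",))
        post = url_specialize(S, A, [m0, m1], [0.5, 0.5], h)
        gm = history_space_model(S, A, [m0, m1], [0.5, 0.5], T=3)
        pf = posterior_factor(gm, h)
        by_model = np.zeros(2)
        for c in pf.components:
            by_model[c.param_id] += c.weight
        assert np.allclose(by_model, post.weights, atol=1e-12)
        # one-step predictives coincide too
        cp = CompletePosterior(gm, pf)
        for a in A.labels:
            assert np.allclose(cp.sensor_path_predictive((a,)),
                               post.predictive(a).probs, atol=1e-12)

    def test_impossible_observation_raises(self):
        S = FiniteSpace("S", ("s0", "s1"))
        A = FiniteSpace("A", ("a0",))
        m0 = FixedNextSensorPredictor(S, lambda s, a, act: [1.0, 0.0])
        with pytest.raises(ImpossibleHistoryError):
            url_specialize(S, A, [m0], [1.0], History(("s1",), ()))
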