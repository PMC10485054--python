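"""Covariate HMM: densities, likelihood, fitting, decoding, inference."""

import itertools

import numpy as np
import pytest
from scipy import integrate, special, stats

import sharkmove as sm
from sharkmove.hmm import (
    EmissionParams,
    FitConfig,
    HMMModel,
    TransitionModel,
    emission_logdensity,
    emission_standard_errors,
    forward_loglik,
    gamma_reparam,
    gamma_unreparam,
    select_model,
    state_posteriors,
    stationary,
    stationary_distribution,
    transition_matrix,
    viterbi,
    wald_tests,
)
from sharkmove.preprocess import StepSeries
from sharkmove.synthetic import ScenarioSpec, StateEmission

from .conftest import two_state_spec


def make_series(steps, angles, covariate=0, video_id="s"):
    steps = np.asarray(steps, dtype=float)
    angles = np.asarray(angles, dtype=float)
    heading = np.concatenate([[0.0], np.cumsum(np.nan_to_num(angles[1:]))])
    return StepSeries(
        video_id=video_id, step=steps, angle=angles, heading=heading,
        covariate=np.full(len(steps), covariate),
    )


def random_model(rng, k, use_covariate=True):
    em = EmissionParams(
        mu=rng.uniform(0.05, 1.0, k),
        sigma=rng.uniform(0.05, 0.8, k),
        theta=rng.uniform(-np.pi, np.pi, k),
        kappa=rng.uniform(0.0, 3.0, k),
        zeta=rng.uniform(0.0, 0.4, k),
    )
    beta0 = rng.normal(0, 1.0, (k, k))
    beta1 = rng.normal(0, 0.7, (k, k)) if use_covariate else np.zeros((k, k))
    np.fill_diagonal(beta0, 0.0)
    np.fill_diagonal(beta1, 0.0)
    return HMMModel(
        emissions=em,
        transitions=TransitionModel(beta0=beta0, beta1=beta1),
        delta_init=rng.dirichlet(np.ones(k)),
        use_covariate=use_covariate,
    )


def random_series(rng, t, covariate):
    steps = rng.gamma(2.0, 0.2, t)
    steps[rng.random(t) < 0.2] = 0.0
    angles = rng.uniform(-np.pi, np.pi, t)
    angles[0] = np.nan
    return make_series(steps, angles, covariate)


def brute_force_loglik(model, sequences):
    """Exhaustive sum over all hidden state paths (tiny instances only)."""
    k = model.n_states
    total = 0.0
    for s in sequences:
        gamma = model.transition_matrix(int(s.covariate[0]))
        n = len(s)
        logd = np.column_stack(
            [
                emission_logdensity(
                    s.step, s.angle,
                    model.emissions.mu[j], model.emissions.sigma[j],
                    model.emissions.theta[j], model.emissions.kappa[j],
                    model.emissions.zeta[j],
                )
                for j in range(k)
            ]
        )
        with np.errstate(divide="ignore"):
            lg = np.log(gamma)
            ld = np.log(model.delta_init)
        path_lls = []
        for path in itertools.product(range(k), repeat=n):
            lp = ld[path[0]] + logd[0, path[0]]
            for t in range(1, n):
                lp += lg[path[t - 1], path[t]] + logd[t, path[t]]
            path_lls.append(lp)
        total += special.logsumexp(path_lls)
    return float(total)


class TestGammaReparam:
    def test_exponential_case(self):
        assert gamma_reparam(1.0, 1.0) == (1.0, 1.0)

    def test_slow_state_values(self):
        shape, rate = gamma_reparam(2.21e-2, 1.37e-2)
        assert shape == pytest.approx(2.602, rel=1e-3)
        assert rate == pytest.approx(117.75, rel=1e-3)

    @pytest.mark.parametrize("mu,sigma", [(0.5, 0.1), (2.21e-2, 1.37e-2), (3.0, 3.0)])
    def test_roundtrip(self, mu, sigma):
        m, s = gamma_unreparam(*gamma_reparam(mu, sigma))
        assert m == pytest.approx(mu, abs=1e-12)
        assert s == pytest.approx(sigma, abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            gamma_reparam(-1.0, 1.0)


class TestEmissionDensity:
    def test_zero_step_uses_zeta_only(self):
        a = emission_logdensity(0.0, np.nan, mu=1.0, sigma=1.0, theta=0.0, kappa=1.0, zeta=0.5)
        b = emission_logdensity(0.0, np.nan, mu=9.0, sigma=0.1, theta=0.0, kappa=1.0, zeta=0.5)
        assert a == pytest.approx(np.log(0.5))
        assert b == pytest.approx(np.log(0.5))

    def test_kappa_zero_uniform_angle(self):
        for ang in (-3.0, 0.0, 2.5):
            d = emission_logdensity(
                1.0, ang, mu=1.0, sigma=1.0, theta=0.7, kappa=0.0, zeta=0.0
            ) - emission_logdensity(1.0, np.nan, mu=1.0, sigma=1.0, theta=0.7, kappa=0.0, zeta=0.0)
            assert d == pytest.approx(-np.log(2 * np.pi))

    @pytest.mark.parametrize("kappa", [0.0422, 0.609, 1.10])
    def test_angle_density_integrates_to_one(self, kappa):
        def dens(phi):
            return np.exp(
                emission_logdensity(1.0, phi, mu=1.0, sigma=1.0, theta=-0.4, kappa=kappa, zeta=0.0)
                - emission_logdensity(1.0, np.nan, mu=1.0, sigma=1.0, theta=-0.4, kappa=kappa, zeta=0.0)
            )
        val, _ = integrate.quad(dens, -np.pi, np.pi, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)


class TestTransitionMatrix:
    def test_zero_betas_uniform(self):
        tm = TransitionModel(beta0=np.zeros((3, 3)), beta1=np.zeros((3, 3)))
        np.testing.assert_allclose(transition_matrix(tm, 0), np.full((3, 3), 1 / 3))

    def test_no_covariate_effect(self, rng):
        b0 = rng.normal(size=(3, 3))
        tm = TransitionModel(beta0=b0, beta1=np.zeros((3, 3)))
        np.testing.assert_allclose(transition_matrix(tm, 0), transition_matrix(tm, 1))

    def test_rows_stochastic(self, rng):
        for _ in range(20):
            tm = TransitionModel(beta0=rng.normal(0, 3, (4, 4)), beta1=rng.normal(0, 3, (4, 4)))
            for c in (0, 1):
                g = transition_matrix(tm, c)
                np.testing.assert_allclose(g.sum(axis=1), 1.0, atol=1e-12)
                assert np.all(g >= 0)


class TestForwardLoglik:
    def test_single_state_is_sum_of_densities(self, rng):
        model = random_model(rng, 1, use_covariate=False)
        s = random_series(rng, 20, 0)
        direct = float(
            np.sum(
                emission_logdensity(
                    s.step, s.angle,
                    model.emissions.mu[0], model.emissions.sigma[0],
                    model.emissions.theta[0], model.emissions.kappa[0],
                    model.emissions.zeta[0],
                )
            )
        )
        assert forward_loglik(model, [s]) == pytest.approx(direct, abs=1e-9)

    def test_matches_exhaustive_enumeration(self, rng):
        model = random_model(rng, 2)
        s = random_series(rng, 6, 1)
        assert forward_loglik(model, [s]) == pytest.approx(
            brute_force_loglik(model, [s]), abs=1e-10
        )

    def test_duplicated_sequence_doubles_contribution(self, rng):
        model = random_model(rng, 3)
        s = random_series(rng, 30, 1)
        assert forward_loglik(model, [s, s]) == pytest.approx(
            2 * forward_loglik(model, [s]), rel=1e-12
        )

    def test_impossible_data_raises_with_context(self, rng):
        model = random_model(rng, 2)
        model.emissions.zeta[:] = 0.0  # zero step then has density 0
        s = make_series([0.5, 0.0, 0.5], [np.nan, 0.1, 0.2])
        with pytest.raises(ValueError, match="frame transition 1"):
            forward_loglik(model, [s])


class TestFit:
    def test_single_state_recovery_within_3se(self):
        spec = ScenarioSpec(
            emissions=[StateEmission(mu=0.3, sigma=0.2, theta=0.4, kappa=1.5, zeta=0.05)],
            beta0=np.zeros((1, 1)), beta1=np.zeros((1, 1)), delta0=np.array([1.0]),
            n_sequences=10, length_range=(1001, 1001), covariate_assignment=0.0, seed=21,
        )
        series = [sm.steps_and_angles(t) for t in sm.simulate_tracks(spec)]
        fit = sm.fit_hmm(series, 1, use_covariate=False, config=FitConfig(n_starts=5, seed=0))
        se = emission_standard_errors(fit)
        truth = spec.emissions[0]
        for name in ("mu", "sigma", "theta", "kappa", "zeta"):
            err = abs(float(getattr(fit.emissions, name)[0]) - getattr(truth, name))
            assert err < 3 * float(se[name][0]), f"{name}: err {err} vs 3se {3 * se[name][0]}"

    def test_determinism_same_seed(self, preset_series):
        cfg = FitConfig(n_starts=2, seed=42, compute_hessian=False)
        sub = preset_series[:6]
        a = sm.fit_hmm(sub, 2, True, cfg)
        b = sm.fit_hmm(sub, 2, True, cfg)
        assert a.log_likelihood == b.log_likelihood
        np.testing.assert_array_equal(a.emissions.mu, b.emissions.mu)
        np.testing.assert_array_equal(a.transitions.beta1, b.transitions.beta1)

    def test_states_canonical_ascending_mu(self, preset_series):
        fit = sm.fit_hmm(
            preset_series[:8], 2, True, FitConfig(n_starts=3, seed=1, compute_hessian=False)
        )
        assert np.all(np.diff(fit.emissions.mu) > 0)

    def test_aic_identity_and_param_counts(self, preset_series):
        sub = preset_series[:6]
        cov = sm.fit_hmm(sub, 2, True, FitConfig(n_starts=2, seed=3, compute_hessian=False))
        null = sm.fit_hmm(sub, 2, False, FitConfig(n_starts=2, seed=3, compute_hessian=False))
        for f, expected_p in ((cov, 15), (null, 13)):
            assert f.n_parameters == expected_p
            assert f.aic == pytest.approx(-2 * f.log_likelihood + 2 * f.n_parameters, abs=1e-6)
        # nesting: the covariate model can always match the null
        assert cov.log_likelihood >= null.log_likelihood - 1e-6

    def test_k3_parameter_counts(self):
        from sharkmove.hmm import n_free_parameters

        assert n_free_parameters(3, True) == 29
        assert n_free_parameters(3, False) == 23


class TestSelectModel:
    def test_equal_ll_fewer_params_wins(self, rng):
        a = random_model(rng, 2)
        b = random_model(rng, 3)
        a.log_likelihood = b.log_likelihood = -100.0
        a.aic = -2 * a.log_likelihood + 2 * a.n_parameters
        b.aic = -2 * b.log_likelihood + 2 * b.n_parameters
        a.data_fingerprint = b.data_fingerprint = ("d",)
        best, table = select_model([a, b])
        assert best is a
        assert table.loc[0, "delta_aic"] == 0.0

    def test_different_data_rejected(self, rng):
        a, b = random_model(rng, 2), random_model(rng, 2)
        a.aic = b.aic = 1.0
        a.data_fingerprint, b.data_fingerprint = ("x",), ("y",)
        with pytest.raises(ValueError, match="different data"):
            select_model([a, b])


class TestStationary:
    def test_symmetric_three_state(self):
        tm = TransitionModel(beta0=np.zeros((3, 3)), beta1=np.zeros((3, 3)))
        em = EmissionParams(np.ones(3), np.ones(3), np.zeros(3), np.ones(3), np.zeros(3))
        m = HMMModel(emissions=em, transitions=tm, delta_init=np.ones(3) / 3)
        res = stationary(m, 0, n_boot=0)
        np.testing.assert_allclose(res.delta, 1 / 3, atol=1e-12)

    def test_hand_solved_two_state(self):
        g = np.array([[0.9, 0.1], [0.3, 0.7]])
        np.testing.assert_allclose(stationary_distribution(g), [0.75, 0.25], atol=1e-12)

    def test_defining_equation_residual(self, rng):
        for _ in range(25):
            tm = TransitionModel(beta0=rng.normal(0, 2, (3, 3)), beta1=np.zeros((3, 3)))
            g = transition_matrix(tm, 0)
            d = stationary_distribution(g)
            assert np.max(np.abs(d @ g - d)) < 1e-10

    def test_reducible_matrix_rejected(self):
        with pytest.raises(ValueError, match="reducible"):
            stationary_distribution(np.eye(2))

    def test_bootstrap_cis_bracket_estimate(self, preset_series):
        fit = sm.fit_hmm(preset_series[:8], 2, True, FitConfig(n_starts=3, seed=5))
        res = stationary(fit, 1, n_boot=200, seed=0)
        assert np.all(res.ci_lower <= res.delta + 1e-12)
        assert np.all(res.delta <= res.ci_upper + 1e-12)
        assert res.delta.sum() == pytest.approx(1.0, abs=1e-12)


class TestViterbi:
    def test_single_state_all_ones(self, rng):
        model = random_model(rng, 1, use_covariate=False)
        s = random_series(rng, 15, 0)
        np.testing.assert_array_equal(viterbi(model, s), np.ones(15, dtype=int))

    def test_matches_exhaustive_argmax(self, rng):
        for trial in range(5):
            model = random_model(rng, 2)
            s = random_series(rng, 6, trial % 2)
            k = model.n_states
            logd = np.column_stack(
                [
                    emission_logdensity(
                        s.step, s.angle,
                        model.emissions.mu[j], model.emissions.sigma[j],
                        model.emissions.theta[j], model.emissions.kappa[j],
                        model.emissions.zeta[j],
                    )
                    for j in range(k)
                ]
            )
            gamma = model.transition_matrix(int(s.covariate[0]))
            best, best_lp = None, -np.inf
            for path in itertools.product(range(k), repeat=len(s)):
                lp = np.log(model.delta_init[path[0]]) + logd[0, path[0]]
                for t in range(1, len(s)):
                    lp += np.log(gamma[path[t - 1], path[t]]) + logd[t, path[t]]
                if lp > best_lp:
                    best, best_lp = path, lp
            np.testing.assert_array_equal(viterbi(model, s), np.array(best) + 1)

    def test_recovery_on_separated_states(self):
        spec = two_state_spec(seed=17, n_sequences=6, length_range=(400, 500))
        tracks = sm.simulate_tracks(spec)
        series = [sm.steps_and_angles(t) for t in tracks]
        fit = sm.fit_hmm(series, 2, True, FitConfig(n_starts=5, seed=2, compute_hessian=False))
        agree = []
        for t, s in zip(tracks, series):
            path = viterbi(fit, s)
            agree.append(np.mean(path - 1 == t.states))
        # >=90% agreement is a heuristic for well-separated emissions
        assert np.mean(agree) >= 0.90

    def test_posteriors_sum_to_one(self, preset_series):
        fit = sm.fit_hmm(
            preset_series[:4], 2, True, FitConfig(n_starts=2, seed=8, compute_hessian=False)
        )
        post = state_posteriors(fit, preset_series[:4])
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)


class TestWald:
    def test_requires_covariate_model(self, rng):
        m = random_model(rng, 2, use_covariate=False)
        with pytest.raises(ValueError, match="covariate"):
            wald_tests(m)

    def test_p_values_valid_and_symmetric(self, preset_series):
        fit = sm.fit_hmm(preset_series[:8], 2, True, FitConfig(n_starts=3, seed=5))
        table = wald_tests(fit)
        assert np.all((table["p_value"] >= 0) & (table["p_value"] <= 1))
        for _, row in table.iterrows():
            assert row["p_value"] == pytest.approx(
                2 * stats.norm.sf(abs(row["beta1"] / row["se"]))
            )

    def test_power_against_large_effect(self):
        # one strongly shifted transition should be flagged
        beta1 = np.array([[0.0, 2.5], [0.0, 0.0]])
        spec = two_state_spec(seed=23, n_sequences=12, length_range=(500, 600), beta1=beta1)
        series = [sm.steps_and_angles(t) for t in sm.simulate_tracks(spec)]
        fit = sm.fit_hmm(series, 2, True, FitConfig(n_starts=4, seed=3))
        table = wald_tests(fit)
        assert bool(table.loc["1->2", "significant"])
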