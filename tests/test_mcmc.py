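"""Inference machinery: conjugate updates, FFBS exactness, full sampler."""

import itertools
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from kinosc.mcmc import (
    MCMCConfig,
    PriorSpec,
    drift_conditional_moments,
    log_likelihood,
    run_mcmc,
    sample_hidden_states,
    tau_posterior_pf,
    update_drift_params,
    update_tau,
    update_transition_probs,
    update_transition_probs_from_counts,
)
from kinosc.model import (
    ModelParameters,
    SimulationConfig,
    StatePath,
    Trajectory,
    pair_transition_matrix,
    simulate_trajectory,
)


def _tiny_trajectory(dx, dt=1.0):
    """Trajectory whose sister displacements are exactly `dx` (n-1, 2)."""
    dx = np.asarray(dx, dtype=float)
    x1 = np.r_[1.0, 1.0 + np.cumsum(dx[:, 0])]
    x2 = np.r_[-1.0, -1.0 + np.cumsum(dx[:, 1])]
    return Trajectory(x1=x1, x2=x2, dt=dt)


ZERO_DRIFT = ModelParameters(0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 0.5, 0.5)


class TestLogLikelihood:
    def test_zero_residuals_maximal_quadratic_term(self, sim_noise_free):
        traj, states, params = sim_noise_free
        tau_pf = params.tau / traj.dt**2
        n1 = traj.n_frames - 1
        ll = log_likelihood(traj, params, states)
        # residuals vanish, so only the normaliser remains
        assert ll == pytest.approx(n1 * (np.log(tau_pf) - np.log(2 * np.pi)), rel=1e-6)

    def test_single_displacement_quadratic_term(self):
        # dx1 = 0.1 with zero drift and per-frame tau' = 100:
        # quadratic penalty = -(100/2) * 0.01 = -0.5 relative to zero residual
        traj = _tiny_trajectory([[0.1, 0.0]], dt=1.0)
        params = replace(ZERO_DRIFT, tau=100.0)
        states = StatePath(np.array([[1, -1]]))
        ll = log_likelihood(traj, params, states)
        base = np.log(100.0) - np.log(2 * np.pi)
        assert ll - base == pytest.approx(-0.5)

    def test_state_length_mismatch_rejected(self, sim_medium, fig1b):
        traj, states = sim_medium
        with pytest.raises(ValueError, match="intervals"):
            log_likelihood(traj, fig1b, StatePath(states.sigma[:-5]))

    def test_L_vplus_symmetry_invariance(self, sim_medium, fig1b):
        # with theta == 0, (L, v+, v-) -> (L + delta, v+ + kappa*delta,
        # v- + kappa*delta) leaves the likelihood exactly unchanged
        traj, states = sim_medium
        delta = 0.1
        shifted = replace(
            fig1b,
            L=fig1b.L + delta,
            v_plus=fig1b.v_plus + fig1b.kappa * delta,
            v_minus=fig1b.v_minus + fig1b.kappa * delta,
        )
        ll0 = log_likelihood(traj, fig1b, states)
        ll1 = log_likelihood(traj, shifted, states)
        assert abs(ll1 - ll0) <= 1e-8 * abs(ll0)


class TestUpdateTau:
    def test_conjugate_algebra(self):
        # c=1, d=1, n=2, per-frame residuals (0.1, 0) -> Gamma(2, 1.005)
        shape, rate = tau_posterior_pf(0.1**2 + 0.0, 1, c=1.0, d_pf=1.0)
        assert (shape, rate) == (2.0, 1.005)
        assert shape / rate == pytest.approx(1.990, abs=1e-3)

    def test_draws_match_conjugate_posterior(self):
        traj = _tiny_trajectory([[0.1, 0.0]], dt=1.0)
        states = StatePath(np.array([[1, -1]]))
        prior = replace(PriorSpec(), c=1.0, d=1.0)
        rng = np.random.default_rng(0)
        draws = np.array(
            [update_tau(traj, ZERO_DRIFT, states, prior, rng) for _ in range(40000)]
        )
        assert draws.mean() == pytest.approx(2.0 / 1.005, rel=0.02)
        assert draws.var() == pytest.approx(2.0 / 1.005**2, rel=0.05)

    def test_posterior_concentrates_at_generative_tau(self, sim_medium, fig1b):
        traj, states = sim_medium
        prior = PriorSpec()
        rng = np.random.default_rng(1)
        draws = np.array(
            [update_tau(traj, fig1b, states, prior, rng) for _ in range(2000)]
        )
        assert draws.mean() == pytest.approx(1000.0, rel=0.10)


class TestUpdateTransitionProbs:
    def test_conjugate_algebra_from_counts(self):
        rng = np.random.default_rng(0)
        draws, (a, b) = update_transition_probs_from_counts(9, 1, 1.0, 1.0, rng)
        assert (a, b) == (10.0, 2.0)
        many = np.array(
            [update_transition_probs_from_counts(9, 1, 1.0, 1.0, rng)[0] for _ in range(20000)]
        )
        assert many.mean() == pytest.approx(10 / 12, rel=0.01)

    def test_counting_convention_on_hand_path(self):
        # pair states: (+,-) (+,-) (+,+) (+,-): transitions c->c (2 persists),
        # ic->c (sister 2 switches: 1 persist + 1 switch), c->? none after
        # wait: 4 labels -> 3 transitions: c->c, c->ic (sister2 switches),
        # ic->c (sister2 switches back)
        sig = np.array([[1, -1], [1, -1], [1, 1], [1, -1]])
        prior = replace(PriorSpec(), alpha_c=1, beta_c=1, alpha_ic=1, beta_ic=1)
        rng = np.random.default_rng(2)
        draws_c = []
        draws_ic = []
        for _ in range(20000):
            pc, pic = update_transition_probs(StatePath(sig), prior, rng)
            draws_c.append(pc)
            draws_ic.append(pic)
        # coherent transitions: frames 1->2 (2 persist), 2->3 (1 persist,
        # 1 switch) => Beta(1+3, 1+1); incoherent: 3->4 => Beta(1+1, 1+1)
        assert np.mean(draws_c) == pytest.approx(4 / 6, rel=0.01)
        assert np.mean(draws_ic) == pytest.approx(2 / 4, rel=0.01)

    def test_no_coherent_frames_draws_from_prior(self):
        sig = np.array([[1, 1], [1, 1], [1, 1]])
        prior = replace(PriorSpec(), alpha_c=3.0, beta_c=2.0)
        rng = np.random.default_rng(3)
        draws = np.array(
            [update_transition_probs(StatePath(sig), prior, rng)[0] for _ in range(20000)]
        )
        assert draws.mean() == pytest.approx(3 / 5, rel=0.02)

    def test_negative_effective_counts_rejected(self):
        with pytest.raises(ValueError, match="counting"):
            update_transition_probs_from_counts(-2, 1, 1.0, 1.0)

    def test_recovers_generative_probabilities(self, sim_medium):
        _, states = sim_medium
        rng = np.random.default_rng(4)
        pcs, pics = zip(
            *[update_transition_probs(states, PriorSpec(), rng) for _ in range(500)]
        )
        assert np.mean(pcs) == pytest.approx(0.94, abs=0.04)
        assert np.mean(pics) == pytest.approx(0.61, abs=0.10)


class TestUpdateDriftParams:
    def test_noise_free_recovery(self, sim_noise_free):
        traj, states, params = sim_noise_free
        prior = PriorSpec().with_informed_L(0.8, 0.11)
        m, _ = drift_conditional_moments(traj, states, params.tau, prior, L=params.L)
        dt = traj.dt
        truth = np.array(
            [params.v_plus * dt, params.v_minus * dt, params.kappa * dt, params.alpha * dt]
        )
        np.testing.assert_allclose(m, truth, rtol=1e-6)

    def test_prior_only_limit(self, sim_medium):
        traj, states = sim_medium
        prior = PriorSpec()
        rng = np.random.default_rng(5)
        draws = np.array(
            [
                update_drift_params(traj, states, 1e-12, prior, rng)
                for _ in range(4000)
            ]
        )
        assert draws[:, 0].mean() == pytest.approx(prior.mu_v, abs=3 * prior.s_v / 60)
        assert draws[:, 0].std() == pytest.approx(prior.s_v, rel=0.1)
        # kappa draws follow the truncated prior
        a = -prior.mu_kappa / prior.s_kappa
        tmean = stats.truncnorm.mean(a, np.inf, loc=prior.mu_kappa, scale=prior.s_kappa)
        assert draws[:, 2].mean() == pytest.approx(tmean, rel=0.05)
        assert (draws[:, 2] >= 0).all() and (draws[:, 3] >= 0).all()

    def test_conditional_moments_match_gls_oracle(self):
        # independent generalised-least-squares computation on the same design
        rng = np.random.default_rng(6)
        prior = PriorSpec()
        for trial in range(20):
            n = 12
            x1 = np.cumsum(rng.normal(0.3, 0.1, n))
            x2 = x1 - rng.uniform(0.7, 1.2, n)
            traj = Trajectory(x1=x1, x2=x2, dt=2.0)
            sig = rng.choice([-1, 1], size=(n - 1, 2))
            states = StatePath(sig)
            tau = rng.uniform(100, 2000)
            L = rng.uniform(0.5, 1.0)
            m, V = drift_conditional_moments(traj, states, tau, prior, L)
            # oracle: build design explicitly, Bayesian GLS
            dt = traj.dt
            rows, ys = [], []
            for i in range(n - 1):
                for k, sign in ((0, -1.0), (1, +1.0)):
                    xk = (x1 if k == 0 else x2)[i]
                    stretch = x1[i] - x2[i] - L
                    vp = sign if sig[i, k] > 0 else 0.0
                    vm = sign if sig[i, k] < 0 else 0.0
                    rows.append([vp, vm, sign * stretch, -xk])
                    ys.append((x1 if k == 0 else x2)[i + 1] - xk)
            A = np.array(rows)
            y = np.array(ys)
            tau_pf = tau / dt**2
            P0 = np.diag(
                1.0
                / np.array(
                    [prior.s_v * dt, prior.s_v * dt, prior.s_kappa * dt, prior.s_alpha * dt]
                )
                ** 2
            )
            m0 = np.array(
                [prior.mu_v * dt, -prior.mu_v * dt, prior.mu_kappa * dt, prior.mu_alpha * dt]
            )
            V_or = np.linalg.inv(P0 + tau_pf * A.T @ A)
            m_or = V_or @ (P0 @ m0 + tau_pf * A.T @ y)
            np.testing.assert_allclose(m, m_or, rtol=1e-8, atol=1e-12)
            np.testing.assert_allclose(V, V_or, rtol=1e-8, atol=1e-14)


class TestSampleHiddenStates:
    @staticmethod
    def _enumeration_marginals(traj, params):
        """Brute-force oracle: exact marginals by summing all 4^(n-1) paths."""
        from kinosc.model import PAIR_STATES, drift_displacement

        n1 = traj.n_frames - 1
        T = pair_transition_matrix(params.p_c, params.p_ic)
        dx = traj.displacements()
        sd = traj.dt / np.sqrt(params.tau)
        logw = np.zeros((n1, 4))
        for i in range(n1):
            for s, (a, b) in enumerate(PAIR_STATES):
                d1, d2 = drift_displacement(
                    params, a, b, traj.x1[i], traj.x2[i], traj.theta[i], traj.dt
                )
                logw[i, s] = stats.norm.logpdf(dx[i, 0], d1, sd) + stats.norm.logpdf(
                    dx[i, 1], d2, sd
                )
        marg = np.zeros((n1, 4))
        total = 0.0
        for path in itertools.product(range(4), repeat=n1):
            lp = np.log(0.25) + logw[0, path[0]]
            for i in range(1, n1):
                lp += np.log(T[path[i - 1], path[i]]) + logw[i, path[i]]
            w = np.exp(lp)
            total += w
            for i, s in enumerate(path):
                marg[i, s] += w
        return marg / total

    def test_ffbs_marginals_match_enumeration(self, fig1b):
        traj, _ = simulate_trajectory(SimulationConfig(params=fig1b, n_frames=5, seed=31))
        _, marginals = sample_hidden_states(traj, fig1b, rng=0)
        oracle = self._enumeration_marginals(traj, fig1b)
        np.testing.assert_allclose(marginals, oracle, atol=1e-10)

    def test_ffbs_marginals_match_enumeration_n6(self, fig1b):
        traj, _ = simulate_trajectory(SimulationConfig(params=fig1b, n_frames=6, seed=32))
        _, marginals = sample_hidden_states(traj, fig1b, rng=0)
        oracle = self._enumeration_marginals(traj, fig1b)
        np.testing.assert_allclose(marginals, oracle, atol=1e-10)

    def test_uninformative_emissions_uniform_marginals(self, sim_medium):
        traj, _ = sim_medium
        params = ModelParameters(0.03, -0.03, 0.0, 0.0, 0.0, 1e-6, 0.5, 0.5)
        _, marginals = sample_hidden_states(traj, params, rng=0)
        np.testing.assert_allclose(marginals, 0.25, atol=1e-3)
        np.testing.assert_allclose(marginals.sum(axis=1), 1.0, atol=1e-12)

    def test_state_recovery_on_low_noise_simulation(self, sim_medium, fig1b):
        traj, truth = sim_medium
        draw, _ = sample_hidden_states(traj, fig1b, rng=0)
        accuracy = np.mean(draw.sigma == truth.sigma)
        assert accuracy > 0.90


class TestRunMCMC:
    def test_parameter_recovery_within_credible_intervals(self, fitted_medium, fig1b):
        traj, post, report, _ = fitted_medium
        assert report.converged
        for name in ("v_plus", "v_minus", "kappa", "L", "alpha", "tau"):
            lo, hi = post.credible_interval(name)
            truth = getattr(fig1b, name)
            assert lo <= truth <= hi, f"{name}: truth {truth} outside [{lo}, {hi}]"

    def test_state_marginals_sum_to_one(self, fitted_medium):
        _, post, _, _ = fitted_medium
        np.testing.assert_allclose(post.state_marginals.sum(axis=1), 1.0, atol=1e-12)

    def test_pure_noise_posterior_overlaps_zero(self, sim_pure_noise):
        post, report = run_mcmc(
            sim_pure_noise,
            PriorSpec().with_informed_L(0.8, 0.11),
            MCMCConfig(n_sweeps=1200, n_chains=1),
            seed=2,
        )[0:2]
        lo, hi = post.credible_interval("v_plus")
        assert lo < 0 < hi or abs(post.summary["v_plus"]["mean"]) < 0.01

    def test_flat_L_prior_warns_about_identifiability(self, sim_medium):
        traj, _ = sim_medium
        with pytest.warns(UserWarning, match="identifiability"):
            run_mcmc(
                traj,
                PriorSpec().with_informed_L(0.8, 1.0),
                MCMCConfig(n_sweeps=50, n_chains=1),
                seed=0,
            )

    def test_too_short_trajectory_rejected(self, fig1b):
        traj, _ = simulate_trajectory(SimulationConfig(params=fig1b, n_frames=10, seed=0))
        with pytest.raises(ValueError, match="frames"):
            run_mcmc(traj, PriorSpec())

    def test_multichain_scale_reduction_below_threshold(self, fitted_medium):
        _, _, report, _ = fitted_medium
        assert report.n_chains == 2
        assert all(v < 1.1 for v in report.rhat.values())

    def test_credible_interval_calibration(self, fig1b):
        """Over 20 simulated trajectories, >= 90% of 95% CIs cover truth."""
        rng = np.random.SeedSequence(99)
        names = ("v_plus", "v_minus", "kappa", "L", "alpha", "tau")
        covered = 0
        total = 0
        prior = PriorSpec().with_informed_L(0.8, 0.11)
        for i, cs in enumerate(rng.spawn(20)):
            traj, _ = simulate_trajectory(
                SimulationConfig(params=fig1b, n_frames=150, seed=1000 + i)
            )
            post, _ = run_mcmc(
                traj, prior, MCMCConfig(n_sweeps=1200, n_chains=1), seed=2000 + i
            )
            for name in names:
                lo, hi = post.credible_interval(name)
                covered += lo <= getattr(fig1b, name) <= hi
                total += 1
        assert covered / total >= 0.90
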