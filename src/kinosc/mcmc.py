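"""Bayesian inference for the coherence–incoherence model.

The posterior of the model parameters and the hidden per-sister K-fibre
states given one paired trajectory factorises into fully conjugate blocks:

* ``(v+, v-, kappa, alpha)`` — multivariate Gaussian (the drift is linear in
  them given ``L``), truncated at zero for ``kappa`` and ``alpha``;
* ``L`` — univariate Gaussian given ``kappa`` (informed prior from
  nocodazole resting-length estimates resolves the (L, v±) identifiability
  problem);
* ``tau`` — Gamma;
* ``(p_c, p_ic)`` — Beta, from per-sister persistence/switch counts;
* the state path — exact joint draw of the 4-state pair chain by forward
  filtering / backward sampling (FFBS).

Internally time is measured in frames ("per-frame" units: velocities and
force gradients multiplied by dt, the noise precision divided by dt^2); the
public API accepts and returns physical, seconds-based units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .model import (
    ModelParameters,
    StatePath,
    Trajectory,
    pair_transition_matrix,
)

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "PosteriorSamples",
    "ConvergenceReport",
    "log_likelihood",
    "update_tau",
    "update_transition_probs",
    "update_transition_probs_from_counts",
    "update_drift_params",
    "sample_hidden_states",
    "run_mcmc",
]

PARAM_NAMES = ("v_plus", "v_minus", "kappa", "L", "alpha", "tau", "p_c", "p_ic")


# --------------------------------------------------------------------------
# priors
# --------------------------------------------------------------------------


@dataclass
class PriorSpec:
    """Conjugate prior hyperparameters, in physical (seconds-based) units.

    v± ~ N(±mu_v, s_v^2); tau ~ Gamma(c, d) (shape/rate); kappa and alpha ~
    N(mu, s^2) truncated at zero; L ~ N(mu_L, s_L^2) truncated at zero
    (informed from nocodazole-treated cells by default); p_c ~ Beta(alpha_c,
    beta_c) and p_ic ~ Beta(alpha_ic, beta_ic), shifted away from zero
    persistence.
    """

    mu_v: float = 0.03  # um/s
    s_v: float = 0.1
    c: float = 0.5  # tau shape
    d: float = 1e-3  # tau rate (1 / (s^2 um^-2))
    mu_kappa: float = 0.01  # 1/s
    s_kappa: float = 0.1
    mu_alpha: float = 0.01  # 1/s
    s_alpha: float = 0.1
    mu_L: float = 0.775  # um
    s_L: float = 0.110
    alpha_c: float = 2.0
    beta_c: float = 1.0
    alpha_ic: float = 2.0
    beta_ic: float = 1.0

    def validate(self) -> "PriorSpec":
        for name in ("s_v", "c", "d", "s_kappa", "s_alpha", "s_L",
                     "alpha_c", "beta_c", "alpha_ic", "beta_ic"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior hyperparameter '{name}' must be > 0")
        return self

    def with_informed_L(self, mu_L: float, s_L: float) -> "PriorSpec":
        from dataclasses import replace

        if s_L <= 0:
            raise ValueError("s_L must be > 0")
        return replace(self, mu_L=mu_L, s_L=s_L)


# --------------------------------------------------------------------------
# FFBS kernels (optionally numba-jitted)
# --------------------------------------------------------------------------


def _forward_filter_impl(logemis, T, init):
    n = logemis.shape[0]
    alphas = np.empty((n, 4))
    loglik = 0.0
    pred = init.copy()
    for i in range(n):
        m = logemis[i, 0]
        for s in range(1, 4):
            if logemis[i, s] > m:
                m = logemis[i, s]
        c = 0.0
        for s in range(4):
            w = np.exp(logemis[i, s] - m) * pred[s]
            alphas[i, s] = w
            c += w
        for s in range(4):
            alphas[i, s] /= c
        loglik += np.log(c) + m
        if i < n - 1:
            for t in range(4):
                acc = 0.0
                for s in range(4):
                    acc += T[s, t] * alphas[i, s]
                pred[t] = acc
    return alphas, loglik


def _backward_sample_impl(alphas, T, u):
    n = alphas.shape[0]
    out = np.empty(n, dtype=np.int64)
    # last frame from the filtered distribution
    acc = 0.0
    s_next = 3
    for s in range(4):
        acc += alphas[n - 1, s]
        if u[n - 1] < acc:
            s_next = s
            break
    out[n - 1] = s_next
    for i in range(n - 2, -1, -1):
        tot = 0.0
        w = np.empty(4)
        for s in range(4):
            w[s] = alphas[i, s] * T[s, s_next]
            tot += w[s]
        acc = 0.0
        s_next = 3
        for s in range(4):
            acc += w[s] / tot
            if u[i] < acc:
                s_next = s
                break
        out[i] = s_next
    return out


try:  # pragma: no cover - exercised implicitly when numba is installed
    from numba import njit

    _forward_filter = njit(cache=True)(_forward_filter_impl)
    _backward_sample = njit(cache=True)(_backward_sample_impl)
except ImportError:  # pragma: no cover
    _forward_filter = _forward_filter_impl
    _backward_sample = _backward_sample_impl


def _smoothed_marginals(logemis: np.ndarray, T: np.ndarray, init: np.ndarray) -> np.ndarray:
    """Exact per-frame smoothing marginals by forward-backward recursion."""
    alphas, _ = _forward_filter(np.ascontiguousarray(logemis), T, init)
    n = logemis.shape[0]
    gamma = np.empty((n, 4))
    beta = np.ones(4)
    gamma[n - 1] = alphas[n - 1]
    for i in range(n - 2, -1, -1):
        w = np.exp(logemis[i + 1] - logemis[i + 1].max()) * beta
        beta = T @ w
        beta /= beta.sum()
        g = alphas[i] * beta
        gamma[i] = g / g.sum()
    return gamma


def _truncnorm_draw(rng: np.random.Generator, mean: float, sd: float, lower: float = 0.0) -> float:
    """Inverse-cdf draw from N(mean, sd^2) truncated to [lower, inf)."""
    a = ndtr((lower - mean) / sd)
    u = a + (1.0 - a) * rng.random()
    u = min(max(u, 1e-15), 1.0 - 1e-15)
    return mean + sd * ndtri(u)


# --------------------------------------------------------------------------
# the Gibbs sampler on per-frame quantities
# --------------------------------------------------------------------------


class GibbsSampler:
    """One-trajectory Gibbs sampler; state kept in per-frame units.

    Exposed for reuse by the marginal-likelihood estimator, which needs
    reduced runs with some blocks held fixed and exact conditional-density
    evaluations at a fixed ordinate.
    """

    def __init__(self, trajectory: Trajectory, prior: PriorSpec, rng: np.random.Generator):
        trajectory.validate()
        prior.validate()
        self.prior = prior
        self.rng = rng
        self.dt = trajectory.dt
        n = trajectory.n_frames
        self.n = n
        self.dx = trajectory.displacements()  # (n-1, 2) um
        self.x = np.stack([trajectory.x1[:-1], trajectory.x2[:-1]], axis=1)
        self.d = trajectory.distance[:-1]
        self.cth = np.cos(trajectory.theta[:-1])
        # per-frame prior for beta = (v+~, v-~, kappa~, alpha~)
        dt = self.dt
        self.beta_m0 = np.array(
            [prior.mu_v * dt, -prior.mu_v * dt, prior.mu_kappa * dt, prior.mu_alpha * dt]
        )
        self.beta_P0 = np.diag(
            1.0 / np.array([prior.s_v * dt, prior.s_v * dt, prior.s_kappa * dt, prior.s_alpha * dt]) ** 2
        )
        self.tau_rate_pf = prior.d * dt**2  # rate of the per-frame precision prior
        # current state
        self.sig = self._init_states()
        self.beta = self.beta_m0.copy()
        self.beta[2] = max(self.beta[2], 1e-4)
        self.beta[3] = max(self.beta[3], 1e-4)
        self.L = prior.mu_L
        v0 = np.var(self.dx)
        self.tau_pf = 1.0 / max(v0, 1e-8)
        self.p_c, self.p_ic = 0.9, 0.6

    # -- helpers -----------------------------------------------------------

    def _init_states(self) -> np.ndarray:
        """Heuristic initial states from displacement signs.

        Sister 1 drifts at -v_sigma (positive displacement suggests a
        depolymerising K-fibre), sister 2 at +v_sigma.
        """
        s1 = np.where(self.dx[:, 0] > 0, -1, 1)
        s2 = np.where(self.dx[:, 1] > 0, 1, -1)
        return np.stack([s1, s2], axis=1).astype(np.int8)

    def _design(self) -> tuple[np.ndarray, np.ndarray]:
        """Design matrix for beta given L, and the response vector."""
        sgn = np.array([-1.0, 1.0])  # (-1)^k for sisters 1, 2
        stretch = self.d - self.L * self.cth
        plus = (self.sig > 0).astype(float)
        A = np.empty((self.n - 1, 2, 4))
        A[:, :, 0] = sgn * plus
        A[:, :, 1] = sgn * (1.0 - plus)
        A[:, :, 2] = sgn * stretch[:, None]
        A[:, :, 3] = -self.x
        return A.reshape(-1, 4), self.dx.reshape(-1)

    def drift_means(self, beta=None, L=None, sig=None) -> np.ndarray:
        """Per-frame drift f~ for both sisters, shape (n-1, 2)."""
        beta = self.beta if beta is None else beta
        L = self.L if L is None else L
        sig = self.sig if sig is None else sig
        sgn = np.array([-1.0, 1.0])
        v = np.where(sig > 0, beta[0], beta[1])
        stretch = self.d - L * self.cth
        return sgn * v + sgn * (beta[2] * stretch[:, None]) - beta[3] * self.x

    def residual_ss(self) -> float:
        r = self.dx - self.drift_means()
        return float(np.sum(r * r))

    def beta_conditional_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Mean and covariance of the (untruncated) Gaussian full conditional."""
        A, y = self._design()
        P = self.beta_P0 + self.tau_pf * (A.T @ A)
        V = np.linalg.inv(P)
        V = 0.5 * (V + V.T)
        m = V @ (self.beta_P0 @ self.beta_m0 + self.tau_pf * (A.T @ y))
        return m, V

    def L_conditional_moments(self) -> tuple[float, float]:
        """Mean and sd of the Gaussian full conditional of L given beta."""
        sgn = np.array([-1.0, 1.0])
        v = np.where(self.sig > 0, self.beta[0], self.beta[1])
        f_noL = sgn * v + sgn * (self.beta[2] * self.d[:, None]) - self.beta[3] * self.x
        g = -sgn * self.beta[2] * self.cth[:, None]
        y = self.dx - f_noL
        prec = 1.0 / self.prior.s_L**2 + self.tau_pf * np.sum(g * g)
        mean = (self.prior.mu_L / self.prior.s_L**2 + self.tau_pf * np.sum(g * y)) / prec
        return float(mean), float(1.0 / np.sqrt(prec))

    def persistence_counts(self) -> tuple[int, int, int, int]:
        """Per-sister (persist_c, switch_c, persist_ic, switch_ic) counts."""
        sig = self.sig
        same = sig[1:] == sig[:-1]
        coh = (sig[:-1, 0] != sig[:-1, 1])
        a_c = int(same[coh].sum())
        b_c = int((~same[coh]).sum())
        a_ic = int(same[~coh].sum())
        b_ic = int((~same[~coh]).sum())
        return a_c, b_c, a_ic, b_ic

    def log_emissions(self, include_constant: bool = False) -> np.ndarray:
        """(n-1, 4) log emission densities for the pair states."""
        b = self.beta
        stretch = self.d - self.L * self.cth
        # sister 1 means for sigma1 in {+, -}; sister 2 likewise
        m1 = np.stack([-b[0] - b[2] * stretch - b[3] * self.x[:, 0],
                       -b[1] - b[2] * stretch - b[3] * self.x[:, 0]], axis=1)
        m2 = np.stack([+b[0] + b[2] * stretch - b[3] * self.x[:, 1],
                       +b[1] + b[2] * stretch - b[3] * self.x[:, 1]], axis=1)
        r1 = self.dx[:, [0]] - m1  # (n-1, 2)
        r2 = self.dx[:, [1]] - m2
        le = np.empty((self.n - 1, 4))
        for s in range(4):
            a, bb = s // 2, s % 2
            le[:, s] = -0.5 * self.tau_pf * (r1[:, a] ** 2 + r2[:, bb] ** 2)
        if include_constant:
            le += np.log(self.tau_pf) - np.log(2 * np.pi)
        return le

    def forward_loglik(self) -> float:
        """log pi(displacements | parameters), hidden states summed out."""
        le = self.log_emissions(include_constant=True)
        T = pair_transition_matrix(self.p_c, self.p_ic)
        _, ll = _forward_filter(np.ascontiguousarray(le), T, np.full(4, 0.25))
        return float(ll)

    # -- block updates -----------------------------------------------------

    def step_beta(self) -> None:
        m, V = self.beta_conditional_moments()
        Lc = np.linalg.cholesky(V)
        for _ in range(100):
            z = m + Lc @ self.rng.standard_normal(4)
            if z[2] >= 0.0 and z[3] >= 0.0:
                self.beta = z
                return
        # near-boundary fallback: coordinate-wise truncated Gibbs passes
        beta = self.beta.copy()
        P = np.linalg.inv(V)
        for _ in range(2):
            for j in range(4):
                cond_var = 1.0 / P[j, j]
                cond_mean = m[j] - cond_var * (P[j] @ (beta - m) - P[j, j] * (beta[j] - m[j]))
                sd = np.sqrt(cond_var)
                if j >= 2:
                    beta[j] = _truncnorm_draw(self.rng, cond_mean, sd, 0.0)
                else:
                    beta[j] = cond_mean + sd * self.rng.standard_normal()
        self.beta = beta

    def step_L(self) -> None:
        mean, sd = self.L_conditional_moments()
        self.L = _truncnorm_draw(self.rng, mean, sd, 0.0)

    def step_tau(self) -> None:
        shape = self.prior.c + (self.n - 1)
        rate = self.tau_rate_pf + 0.5 * self.residual_ss()
        self.tau_pf = self.rng.gamma(shape, 1.0 / rate)

    def step_p(self) -> None:
        a_c, b_c, a_ic, b_ic = self.persistence_counts()
        pr = self.prior
        self.p_c = self.rng.beta(pr.alpha_c + a_c, pr.beta_c + b_c)
        self.p_ic = self.rng.beta(pr.alpha_ic + a_ic, pr.beta_ic + b_ic)
        eps = 1e-12
        self.p_c = min(max(self.p_c, eps), 1 - eps)
        self.p_ic = min(max(self.p_ic, eps), 1 - eps)

    def step_states(self) -> None:
        le = self.log_emissions()
        T = pair_transition_matrix(self.p_c, self.p_ic)
        alphas, _ = _forward_filter(np.ascontiguousarray(le), T, np.full(4, 0.25))
        u = self.rng.random(self.n - 1)
        idx = _backward_sample(alphas, T, u)
        self.sig = StatePath.from_pair_index(idx).sigma

    def sweep(self, fix: frozenset = frozenset()) -> None:
        if "beta" not in fix:
            self.step_beta()
        if "L" not in fix:
            self.step_L()
        if "tau" not in fix:
            self.step_tau()
        if "states" not in fix:
            self.step_states()
        if "p" not in fix:
            self.step_p()

    # -- unit conversion ---------------------------------------------------

    def physical_params(self) -> ModelParameters:
        dt = self.dt
        return ModelParameters(
            v_plus=self.beta[0] / dt,
            v_minus=self.beta[1] / dt,
            kappa=self.beta[2] / dt,
            L=self.L,
            alpha=self.beta[3] / dt,
            tau=self.tau_pf * dt**2,
            p_c=self.p_c,
            p_ic=self.p_ic,
        )

    def set_physical(self, params: ModelParameters) -> None:
        dt = self.dt
        self.beta = np.array(
            [params.v_plus * dt, params.v_minus * dt, params.kappa * dt, params.alpha * dt]
        )
        self.L = params.L
        self.tau_pf = params.tau / dt**2
        self.p_c, self.p_ic = params.p_c, params.p_ic


# --------------------------------------------------------------------------
# public single-block operations
# --------------------------------------------------------------------------


def _per_frame(trajectory: Trajectory, params: ModelParameters):
    dt = trajectory.dt
    beta = np.array([params.v_plus * dt, params.v_minus * dt, params.kappa * dt, params.alpha * dt])
    tau_pf = params.tau / dt**2
    return beta, tau_pf


def _drift_pf(trajectory: Trajectory, params: ModelParameters, states: StatePath) -> np.ndarray:
    beta, _ = _per_frame(trajectory, params)
    sig = states.sigma
    x = np.stack([trajectory.x1[:-1], trajectory.x2[:-1]], axis=1)
    d = trajectory.distance[:-1]
    cth = np.cos(trajectory.theta[:-1])
    sgn = np.array([-1.0, 1.0])
    v = np.where(sig > 0, beta[0], beta[1])
    return sgn * v + sgn * (beta[2] * (d - params.L * cth)[:, None]) - beta[3] * x


def log_likelihood(trajectory: Trajectory, params: ModelParameters, states: StatePath) -> float:
    """Exact Gaussian log likelihood of the displacements given the states.

    Computed in per-frame units (dt absorbed into the parameters) with the
    full Gaussian normaliser included — the value equals
    ``(n-1) log tau' - (n-1) log(2 pi) - (tau'/2) * RSS`` so it is directly
    usable inside marginal-likelihood estimates.
    """
    params.validate()
    if states.n_intervals != trajectory.n_frames - 1:
        raise ValueError(
            f"states cover {states.n_intervals} intervals, expected {trajectory.n_frames - 1}"
        )
    _, tau_pf = _per_frame(trajectory, params)
    r = trajectory.displacements() - _drift_pf(trajectory, params, states)
    n1 = trajectory.n_frames - 1
    return float(n1 * np.log(tau_pf) - n1 * np.log(2 * np.pi) - 0.5 * tau_pf * np.sum(r * r))


def update_tau(
    trajectory: Trajectory,
    params: ModelParameters,
    states: StatePath,
    prior: PriorSpec,
    rng: np.random.Generator | int = 0,
) -> float:
    """Exact conjugate Gamma draw of the noise precision (physical units).

    The per-frame precision posterior is Gamma(c + (n-1), d' + RSS/2) with d'
    the per-frame prior rate and RSS the per-frame residual sum of squares
    over both sisters.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    r = trajectory.displacements() - _drift_pf(trajectory, params, states)
    n1 = trajectory.n_frames - 1
    shape = prior.c + n1
    rate = prior.d * trajectory.dt**2 + 0.5 * float(np.sum(r * r))
    return float(rng.gamma(shape, 1.0 / rate) * trajectory.dt**2)


def tau_posterior_pf(residual_ss: float, n_intervals: int, c: float, d_pf: float) -> tuple[float, float]:
    """Closed-form (shape, rate) of the per-frame precision posterior."""
    return c + n_intervals, d_pf + 0.5 * residual_ss


def update_transition_probs_from_counts(
    persist: int, switch: int, a: float, b: float, rng: np.random.Generator | int = 0
) -> tuple[float, tuple[float, float]]:
    """Beta(a + persist, b + switch) draw; returns (draw, (a_post, b_post))."""
    a_post, b_post = a + persist, b + switch
    if a_post <= 0 or b_post <= 0:
        raise ValueError("effective Beta parameters must be positive (counting bug?)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return float(rng.beta(a_post, b_post)), (a_post, b_post)


def update_transition_probs(
    states: StatePath, prior: PriorSpec, rng: np.random.Generator | int = 0
) -> tuple[float, float]:
    """Conjugate Beta draws of (p_c, p_ic) from a sampled state path.

    Counting convention: each pair transition contributes TWO independent
    per-sister persistence Bernoulli trials, with success probability p_c
    when the pair is currently coherent and p_ic when incoherent — exactly
    the product form used by the FFBS transition matrix, preserving the
    Beta exponent structure of the posterior.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sig = states.sigma
    same = sig[1:] == sig[:-1]
    coh = sig[:-1, 0] != sig[:-1, 1]
    p_c, _ = update_transition_probs_from_counts(
        int(same[coh].sum()), int((~same)[coh].sum()), prior.alpha_c, prior.beta_c, rng
    )
    p_ic, _ = update_transition_probs_from_counts(
        int(same[~coh].sum()), int((~same)[~coh].sum()), prior.alpha_ic, prior.beta_ic, rng
    )
    return p_c, p_ic


def update_drift_params(
    trajectory: Trajectory,
    states: StatePath,
    tau: float,
    prior: PriorSpec,
    rng: np.random.Generator | int = 0,
    L: float | None = None,
) -> tuple[float, float, float, float, float]:
    """Blocked draw of (v+, v-, kappa, alpha, L) in physical units.

    (v+, v-, kappa, alpha) are drawn jointly from their exact multivariate
    Gaussian full conditional given L (truncated at zero for kappa, alpha),
    then L from its univariate Gaussian full conditional given the new
    kappa.  If a state value is absent from the path the corresponding
    velocity's conditional collapses to its prior automatically.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    s = GibbsSampler(trajectory, prior, rng)
    s.sig = states.sigma
    s.tau_pf = tau / trajectory.dt**2
    s.L = prior.mu_L if L is None else L
    s.step_beta()
    s.step_L()
    dt = trajectory.dt
    return (s.beta[0] / dt, s.beta[1] / dt, s.beta[2] / dt, s.beta[3] / dt, s.L)


def drift_conditional_moments(
    trajectory: Trajectory,
    states: StatePath,
    tau: float,
    prior: PriorSpec,
    L: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Untruncated Gaussian full-conditional moments of the per-frame
    (v+~, v-~, kappa~, alpha~) block — exposed for cross-checking against an
    independent generalised-least-squares computation."""
    s = GibbsSampler(trajectory, prior, np.random.default_rng(0))
    s.sig = states.sigma
    s.tau_pf = tau / trajectory.dt**2
    s.L = L
    return s.beta_conditional_moments()


def sample_hidden_states(
    trajectory: Trajectory,
    params: ModelParameters,
    rng: np.random.Generator | int = 0,
    n_samples: int = 1,
) -> tuple[StatePath | list[StatePath], np.ndarray]:
    """Exact joint state-path draw(s) plus exact per-frame smoothing marginals.

    Uses forward filtering–backward sampling on the 4-state pair chain with
    Gaussian displacement emissions for both sisters and the transition
    matrix built from (p_c, p_ic).
    """
    params.validate()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    s = GibbsSampler(trajectory, PriorSpec(), rng)
    s.set_physical(params)
    le = s.log_emissions()
    T = pair_transition_matrix(params.p_c, params.p_ic)
    init = np.full(4, 0.25)
    alphas, _ = _forward_filter(np.ascontiguousarray(le), T, init)
    marginals = _smoothed_marginals(le, T, init)
    draws = []
    for _ in range(n_samples):
        u = rng.random(trajectory.n_frames - 1)
        draws.append(StatePath.from_pair_index(_backward_sample(alphas, T, u)))
    return (draws[0] if n_samples == 1 else draws), marginals


# --------------------------------------------------------------------------
# full sampler
# --------------------------------------------------------------------------


@dataclass
class MCMCConfig:
    n_sweeps: int = 3200  # per chain; retained = n_sweeps * (1 - burn_frac)
    burn_frac: float = 0.2
    n_chains: int = 2
    min_frames: int = 20
    rhat_threshold: float = 1.1
    store_states: bool = True


@dataclass
class ConvergenceReport:
    converged: bool
    rhat: dict
    ess: dict
    n_chains: int
    threshold: float = 1.1


@dataclass
class PosteriorSamples:
    """Retained posterior draws (physical units) for one trajectory."""

    params: pd.DataFrame  # columns: chain, draw, v_plus ... p_ic
    states: np.ndarray | None  # (n_draws_total, n-1, 2) int8, or None
    state_marginals: np.ndarray  # (n-1, 4) empirical pair-state frequencies
    burn_in: int
    n_chains: int
    dt: float
    summary: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.params)

    def mean_parameters(self) -> ModelParameters:
        m = self.params[list(PARAM_NAMES)].mean()
        return ModelParameters(**{k: float(m[k]) for k in PARAM_NAMES})

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        q = (1 - level) / 2
        col = self.params[name]
        return float(col.quantile(q)), float(col.quantile(1 - q))

    def modal_states(self) -> StatePath:
        return StatePath.from_pair_index(np.argmax(self.state_marginals, axis=1))

    def state_samples(self, max_samples: int | None = None, rng=None) -> list[StatePath]:
        if self.states is None:
            raise ValueError("state draws were not stored")
        idx = np.arange(self.states.shape[0])
        if max_samples is not None and max_samples < len(idx):
            rng = np.random.default_rng(rng)
            idx = rng.choice(idx, size=max_samples, replace=False)
            idx.sort()
        return [StatePath(self.states[i]) for i in idx]


def _summarise(df: pd.DataFrame) -> dict:
    out = {}
    for name in PARAM_NAMES:
        col = df[name]
        out[name] = {
            "mean": float(col.mean()),
            "sd": float(col.std()),
            "q2.5": float(col.quantile(0.025)),
            "q97.5": float(col.quantile(0.975)),
        }
    return out


def run_mcmc(
    trajectory: Trajectory,
    prior: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    seed: int = 0,
) -> tuple[PosteriorSamples, ConvergenceReport]:
    """Fit the coherence–incoherence model to one paired trajectory.

    Alternates the blocked drift update, the L update, the tau update, the
    joint FFBS state draw and the transition-probability update; runs
    ``config.n_chains`` independent chains and assesses convergence with the
    split-chain scale-reduction statistic.  Non-convergence is reported, not
    fatal.
    """
    prior = (prior or PriorSpec()).validate()
    config = config or MCMCConfig()
    if trajectory.n_frames < config.min_frames:
        raise ValueError(
            f"trajectory has {trajectory.n_frames} frames; minimum is {config.min_frames}"
        )
    if prior.s_L > 0.3:
        warnings.warn(
            "wide prior on L: the model has an a posteriori identifiability "
            "problem between L and v±; supply an informed resting-length prior",
            stacklevel=2,
        )
    burn = int(config.burn_frac * config.n_sweeps)
    retained = config.n_sweeps - burn
    n1 = trajectory.n_frames - 1
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(config.n_chains)

    rows = []
    states_store = (
        np.empty((config.n_chains * retained, n1, 2), dtype=np.int8)
        if config.store_states
        else None
    )
    marg_counts = np.zeros((n1, 4))
    k = 0
    for chain, cs in enumerate(chain_seeds):
        rng = np.random.default_rng(cs)
        sampler = GibbsSampler(trajectory, prior, rng)
        for sweep in range(config.n_sweeps):
            sampler.sweep()
            if sweep >= burn:
                p = sampler.physical_params()
                rows.append(
                    (chain, sweep - burn)
                    + tuple(getattr(p, name) for name in PARAM_NAMES)
                )
                idx = sampler.sig
                if states_store is not None:
                    states_store[k] = idx
                pair_idx = 2 * (idx[:, 0] < 0) + (idx[:, 1] < 0)
                marg_counts[np.arange(n1), pair_idx] += 1
                k += 1

    df = pd.DataFrame(rows, columns=["chain", "draw"] + list(PARAM_NAMES))
    marginals = marg_counts / marg_counts.sum(axis=1, keepdims=True)

    rhat, ess = _convergence_stats(df, config.n_chains, retained)
    converged = all(np.isfinite(v) and v < config.rhat_threshold for v in rhat.values())
    report = ConvergenceReport(
        converged=converged,
        rhat=rhat,
        ess=ess,
        n_chains=config.n_chains,
        threshold=config.rhat_threshold,
    )
    post = PosteriorSamples(
        params=df,
        states=states_store,
        state_marginals=marginals,
        burn_in=burn,
        n_chains=config.n_chains,
        dt=trajectory.dt,
        summary=_summarise(df),
    )
    return post, report


def _convergence_stats(df: pd.DataFrame, n_chains: int, retained: int) -> tuple[dict, dict]:
    try:
        import arviz as az
    except ImportError:  # pragma: no cover
        return {k: float("nan") for k in PARAM_NAMES}, {k: float("nan") for k in PARAM_NAMES}
    data = {
        name: df[name].to_numpy().reshape(n_chains, retained) for name in PARAM_NAMES
    }
    if n_chains == 1:
        # split the single chain into halves so the scale-reduction
        # statistic remains defined
        half = retained // 2
        data = {name: arr[0, : 2 * half].reshape(2, half) for name, arr in data.items()}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.convert_to_dataset(data)
        rh = az.rhat(idata)
        es = az.ess(idata)
    rhat = {name: float(rh[name].values) for name in PARAM_NAMES}
    ess = {name: float(es[name].values) for name in PARAM_NAMES}
    return rhat, ess
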