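"""Trajectory-quality and model-comparison statistics.

Oscillation quality of a fitted trajectory is scored three ways: the Bayes
factor of the coherence–incoherence model against Brownian-motion null
models, the explained variance (EV) of the fitted drift, and a directional
correlation statistic D based on the binomial distribution of the number of
direction changes under a random walk.  All marginal likelihoods are for
per-frame displacement data, so Bayes factors between models are directly
comparable.

The Brownian null models are conjugate normal–gamma linear models:
``M_BM`` (i.i.d. zero-mean Gaussian displacements), ``M_spring-BM`` (adds a
mean-reverting inter-sister spring column) and ``M_spring-drift-BM`` (adds a
constant drift per sister); their marginal likelihoods are closed form.  The
marginal likelihood of the coherence–incoherence model itself is estimated
from MCMC output with a single-high-density-point (Chib/Chen) estimator
whose conditional ordinates are the sampler's exact conjugate full
conditionals, with the hidden states summed out by the forward filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

from .mcmc import (
    GibbsSampler,
    PosteriorSamples,
    PriorSpec,
)
from .model import ModelParameters, StatePath, Trajectory

__all__ = [
    "BMPrior",
    "ModelComparison",
    "bm_log_marginal",
    "fit_bm_variants",
    "conjugate_lm_log_marginal",
    "chib_conjugate_lm",
    "estimate_log_marginal_chen",
    "explained_variance",
    "directional_statistic",
    "half_period_autocorrelation",
    "filter_trajectories",
]


@dataclass
class BMPrior:
    """Normal–gamma prior for the Brownian null models.

    The per-frame precision has a Gamma(c, d) prior; regression
    coefficients (spring, drift) have beta | tau ~ N(0, tau^-1 * v0 * I).
    Defaults match the coherent model's tau prior converted to per-frame
    units at dt = 2 s.
    """

    c: float = 0.5
    d: float = 4e-3
    v0: float = 100.0


@dataclass
class ModelComparison:
    pair_id: str
    explained_variance: float
    log_marginal_coh: float
    log_marginal_coh_se: float
    log_marginal_bm: float
    log_marginal_spring_bm: float
    log_marginal_spring_drift_bm: float
    d_statistic: dict
    half_period_s: float | None
    converged: bool
    filter_pass: bool | None = None

    @property
    def log_bayes_factor(self) -> float:
        return self.log_marginal_coh - self.log_marginal_bm


# --------------------------------------------------------------------------
# closed-form conjugate linear-model marginals
# --------------------------------------------------------------------------


def conjugate_lm_log_marginal(
    y: np.ndarray, X: np.ndarray | None, prior: BMPrior
) -> float:
    """Closed-form log marginal of y = X beta + N(0, tau^-1) under the
    normal–gamma prior; X may be None/empty (pure precision model)."""
    y = np.asarray(y, dtype=float).ravel()
    m = len(y)
    c, d = prior.c, prior.d
    if X is None or X.size == 0:
        logdet_ratio = 0.0
        quad = float(y @ y)
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != m:
            raise ValueError("design matrix rows must match observations")
        p = X.shape[1]
        V0inv = np.eye(p) / prior.v0
        Vn = np.linalg.inv(V0inv + X.T @ X)
        mu_n = Vn @ (X.T @ y)
        sign, logdet_Vn = np.linalg.slogdet(Vn)
        logdet_ratio = logdet_Vn + p * np.log(1.0 / prior.v0)
        quad = float(y @ y - mu_n @ (V0inv + X.T @ X) @ mu_n)
    dn = d + 0.5 * quad
    return float(
        -0.5 * m * np.log(2 * np.pi)
        + 0.5 * logdet_ratio
        + c * np.log(d)
        - gammaln(c)
        + gammaln(c + 0.5 * m)
        - (c + 0.5 * m) * np.log(dn)
    )


def _pooled_displacements(trajectory: Trajectory) -> np.ndarray:
    """Per-frame displacements, sister 1 rows then sister 2 rows."""
    dx = trajectory.displacements()
    return np.concatenate([dx[:, 0], dx[:, 1]])


def _variant_design(trajectory: Trajectory, variant: str) -> np.ndarray | None:
    """Regression columns for the BM variants (rows match
    :func:`_pooled_displacements`)."""
    n1 = trajectory.n_frames - 1
    if variant == "bm":
        return None
    d = trajectory.distance[:-1]
    spring = np.concatenate([-(d - d.mean()), +(d - d.mean())])[:, None]
    if variant == "spring_bm":
        return spring
    if variant == "spring_drift_bm":
        drift1 = np.concatenate([np.ones(n1), np.zeros(n1)])[:, None]
        drift2 = np.concatenate([np.zeros(n1), np.ones(n1)])[:, None]
        return np.hstack([spring, drift1, drift2])
    raise ValueError(f"unknown variant '{variant}'")


def bm_log_marginal(trajectory: Trajectory, prior: BMPrior | None = None) -> float:
    """Exact log marginal likelihood of the plain Brownian-motion model.

    Both sisters move as independent 1D random walks: per-frame
    displacements are i.i.d. N(0, 1/tau) with tau ~ Gamma(c, d), giving a
    Gamma-function closed form in n, c, d and the residual sum of squares.
    """
    prior = prior or BMPrior()
    return conjugate_lm_log_marginal(_pooled_displacements(trajectory), None, prior)


def fit_bm_variants(trajectory: Trajectory, prior: BMPrior | None = None) -> dict:
    """Closed-form log marginals for M_BM, M_spring-BM, M_spring-drift-BM."""
    if trajectory.n_frames < 3:
        raise ValueError("variants need at least 3 frames")
    prior = prior or BMPrior()
    y = _pooled_displacements(trajectory)
    return {
        v: conjugate_lm_log_marginal(y, _variant_design(trajectory, v), prior)
        for v in ("bm", "spring_bm", "spring_drift_bm")
    }


def chib_conjugate_lm(
    y: np.ndarray,
    X: np.ndarray | None,
    prior: BMPrior,
    n_sweeps: int = 2000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Chib single-ordinate marginal-likelihood estimate for the conjugate
    linear model, run through its own two-block Gibbs sampler.

    Returns (estimate, Monte-Carlo standard error).  Cross-validates the
    estimator against :func:`conjugate_lm_log_marginal`.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    y = np.asarray(y, dtype=float).ravel()
    m = len(y)
    c, d = prior.c, prior.d
    has_beta = X is not None and X.size > 0
    if has_beta:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        p = X.shape[1]
        V0inv = np.eye(p) / prior.v0
        Vn = np.linalg.inv(V0inv + X.T @ X)
        mu_n = Vn @ (X.T @ y)
        Ln = np.linalg.cholesky(Vn)
    else:
        p = 0

    burn = max(1, n_sweeps // 5)
    tau = 1.0 / max(np.var(y), 1e-10)
    beta = mu_n.copy() if has_beta else None
    taus, betas, rates = [], [], []
    for sweep in range(n_sweeps):
        if has_beta:
            beta = mu_n + (Ln @ rng.standard_normal(p)) / np.sqrt(tau)
            resid = y - X @ beta
            rate = d + 0.5 * float(resid @ resid + beta @ V0inv @ beta)
            shape = c + 0.5 * (m + p)
        else:
            rate = d + 0.5 * float(y @ y)
            shape = c + 0.5 * m
        tau = rng.gamma(shape, 1.0 / rate)
        if sweep >= burn:
            taus.append(tau)
            rates.append(rate)
            if has_beta:
                betas.append(beta)

    tau_star = float(np.mean(taus))
    shape = c + 0.5 * (m + p)
    # likelihood + priors at the ordinate
    if has_beta:
        beta_star = np.mean(betas, axis=0)
        resid = y - X @ beta_star
        loglik = 0.5 * m * np.log(tau_star / (2 * np.pi)) - 0.5 * tau_star * float(resid @ resid)
        log_prior_beta = float(
            stats.multivariate_normal.logpdf(beta_star, mean=np.zeros(p), cov=prior.v0 / tau_star * np.eye(p))
        )
        log_post_beta = float(
            stats.multivariate_normal.logpdf(beta_star, mean=mu_n, cov=Vn / tau_star)
        )
    else:
        loglik = 0.5 * m * np.log(tau_star / (2 * np.pi)) - 0.5 * tau_star * float(y @ y)
        log_prior_beta = 0.0
        log_post_beta = 0.0
    log_prior_tau = c * np.log(d) - gammaln(c) + (c - 1) * np.log(tau_star) - d * tau_star
    # Rao-Blackwellised tau ordinate
    rates = np.asarray(rates)
    terms = shape * np.log(rates) - gammaln(shape) + (shape - 1) * np.log(tau_star) - rates * tau_star
    log_ord_tau = float(logsumexp(terms) - np.log(len(terms)))
    se = _batch_se_log(terms)
    logm = loglik + log_prior_beta + log_prior_tau - log_post_beta - log_ord_tau
    return float(logm), float(se)


def _batch_se_log(log_terms: np.ndarray, n_batches: int = 20) -> float:
    """Standard error of a log-mean-exp estimate by batch means."""
    log_terms = np.asarray(log_terms)
    g = len(log_terms)
    if g < 2 * n_batches:
        n_batches = max(2, g // 2)
    size = g // n_batches
    bm = np.array(
        [
            logsumexp(log_terms[i * size : (i + 1) * size]) - np.log(size)
            for i in range(n_batches)
        ]
    )
    return float(np.std(bm, ddof=1) / np.sqrt(n_batches))


# --------------------------------------------------------------------------
# Chib/Chen estimator for the coherence-incoherence model
# --------------------------------------------------------------------------


def _log_prior_pf(sampler: GibbsSampler, beta: np.ndarray, L: float, tau_pf: float,
                  p_c: float, p_ic: float) -> float:
    """Normalised log prior density at a per-frame-unit ordinate."""
    pr = sampler.prior
    dt = sampler.dt
    lp = stats.norm.logpdf(beta[0], pr.mu_v * dt, pr.s_v * dt)
    lp += stats.norm.logpdf(beta[1], -pr.mu_v * dt, pr.s_v * dt)
    for j, (mu, s) in enumerate(
        [(pr.mu_kappa * dt, pr.s_kappa * dt), (pr.mu_alpha * dt, pr.s_alpha * dt)]
    ):
        lp += stats.truncnorm.logpdf(beta[2 + j], -mu / s, np.inf, loc=mu, scale=s)
    lp += stats.truncnorm.logpdf(L, -pr.mu_L / pr.s_L, np.inf, loc=pr.mu_L, scale=pr.s_L)
    c, d_pf = pr.c, sampler.tau_rate_pf
    lp += c * np.log(d_pf) - gammaln(c) + (c - 1) * np.log(tau_pf) - d_pf * tau_pf
    lp += stats.beta.logpdf(p_c, pr.alpha_c, pr.beta_c)
    lp += stats.beta.logpdf(p_ic, pr.alpha_ic, pr.beta_ic)
    return float(lp)


def _log_trunc_mvn(x: np.ndarray, m: np.ndarray, V: np.ndarray) -> float:
    """Log density of N(m, V) truncated to {x[2] >= 0, x[3] >= 0}."""
    base = stats.multivariate_normal.logpdf(x, mean=m, cov=V, allow_singular=True)
    mz = m[2:4]
    Vz = V[2:4, 2:4]
    Z = stats.multivariate_normal.cdf(
        np.array([np.inf, np.inf]), mean=mz, cov=Vz, lower_limit=np.array([0.0, 0.0])
    )
    Z = min(max(float(Z), 1e-300), 1.0)
    return float(base - np.log(Z))


def estimate_log_marginal_chen(
    posterior_samples: PosteriorSamples,
    trajectory: Trajectory,
    prior: PriorSpec,
    seed: int | np.random.Generator = 0,
    reduced_sweeps: int = 1500,
    max_ordinate_draws: int = 1500,
    converged: bool | None = None,
) -> tuple[float, float]:
    """Marginal likelihood of the coherence–incoherence model from MCMC
    output, by chained conditional-density (single high-density point)
    estimation.

    The ordinate is the posterior mean; the state path is summed out exactly
    by the forward filter, the (tau, p_c, p_ic) ordinate is Rao-
    Blackwellised over the main-run draws, and the (v+, v-, kappa, alpha)
    and L ordinates come from two reduced Gibbs runs.  Returns the log
    marginal (per-frame displacement data) and a batch-means Monte-Carlo
    standard error.
    """
    if converged is False:
        raise ValueError("refusing marginal-likelihood estimate from a non-converged fit")
    if posterior_samples.states is None:
        raise ValueError("state draws are required (run with store_states=True)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sampler = GibbsSampler(trajectory, prior, rng)
    star = posterior_samples.mean_parameters()
    dt = trajectory.dt
    beta_star = np.array(
        [star.v_plus * dt, star.v_minus * dt, star.kappa * dt, star.alpha * dt]
    )
    L_star, tau_star = star.L, star.tau / dt**2
    pc_star, pic_star = star.p_c, star.p_ic
    pr = prior
    n1 = trajectory.n_frames - 1

    # ordinate 1: pi(tau*, p_c*, p_ic* | X), Rao-Blackwellised over main run
    G = posterior_samples.n_draws
    stride = max(1, G // max_ordinate_draws)
    idx = np.arange(0, G, stride)
    df = posterior_samples.params
    terms1 = np.empty(len(idx))
    for j, g in enumerate(idx):
        row = df.iloc[g]
        sampler.beta = np.array(
            [row.v_plus * dt, row.v_minus * dt, row.kappa * dt, row.alpha * dt]
        )
        sampler.L = float(row.L)
        sampler.sig = posterior_samples.states[g]
        S = sampler.residual_ss()
        a_c, b_c, a_ic, b_ic = sampler.persistence_counts()
        shape, rate = pr.c + n1, sampler.tau_rate_pf + 0.5 * S
        t = shape * np.log(rate) - gammaln(shape) + (shape - 1) * np.log(tau_star) - rate * tau_star
        t += stats.beta.logpdf(pc_star, pr.alpha_c + a_c, pr.beta_c + b_c)
        t += stats.beta.logpdf(pic_star, pr.alpha_ic + a_ic, pr.beta_ic + b_ic)
        terms1[j] = t
    log_ord1 = float(logsumexp(terms1) - np.log(len(terms1)))
    se1 = _batch_se_log(terms1)

    # reduced run 1: tau, p fixed at *; average the beta full-conditional density
    sampler.tau_pf, sampler.p_c, sampler.p_ic = tau_star, pc_star, pic_star
    sampler.beta = beta_star.copy()
    sampler.L = L_star
    sampler.step_states()
    burn = max(1, reduced_sweeps // 5)
    terms2 = []
    fix = frozenset({"tau", "p"})
    for sweep in range(reduced_sweeps):
        sampler.sweep(fix=fix)
        if sweep >= burn:
            m, V = sampler.beta_conditional_moments()
            terms2.append(_log_trunc_mvn(beta_star, m, V))
    terms2 = np.asarray(terms2)
    log_ord2 = float(logsumexp(terms2) - np.log(len(terms2)))
    se2 = _batch_se_log(terms2)

    # reduced run 2: beta also fixed at *; average the L full-conditional density
    sampler.beta = beta_star.copy()
    fix = frozenset({"tau", "p", "beta"})
    terms3 = []
    for sweep in range(reduced_sweeps):
        sampler.sweep(fix=fix)
        if sweep >= burn:
            mean, sd = sampler.L_conditional_moments()
            a = (0.0 - mean) / sd
            terms3.append(float(stats.truncnorm.logpdf(L_star, a, np.inf, loc=mean, scale=sd)))
    terms3 = np.asarray(terms3)
    log_ord3 = float(logsumexp(terms3) - np.log(len(terms3)))
    se3 = _batch_se_log(terms3)

    # assemble: log pi(X) = log pi(X|Theta*) + log pi(Theta*) - log pi(Theta*|X)
    sampler.beta, sampler.L, sampler.tau_pf = beta_star, L_star, tau_star
    sampler.p_c, sampler.p_ic = pc_star, pic_star
    loglik_marg = sampler.forward_loglik()
    log_prior = _log_prior_pf(sampler, beta_star, L_star, tau_star, pc_star, pic_star)
    logm = loglik_marg + log_prior - (log_ord1 + log_ord2 + log_ord3)
    se = float(np.sqrt(se1**2 + se2**2 + se3**2))
    return float(logm), se


# --------------------------------------------------------------------------
# intrinsic statistics
# --------------------------------------------------------------------------


def explained_variance(
    trajectory: Trajectory,
    posterior_samples: PosteriorSamples | None = None,
    params: ModelParameters | None = None,
    states: StatePath | None = None,
) -> float:
    """EV = 1 - RSS/TSS of pooled per-frame displacements.

    The model drift is evaluated at the posterior-mean parameters and the
    per-frame modal states (or at explicitly supplied params/states).  A
    pure Brownian motion scores near 0; a noise-free sawtooth scores 1.
    """
    if params is None or states is None:
        if posterior_samples is None:
            raise ValueError("either posterior_samples or (params, states) required")
        params = posterior_samples.mean_parameters()
        states = posterior_samples.modal_states()
    from .mcmc import _drift_pf

    dx = trajectory.displacements()
    tss = float(np.sum((dx - dx.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("zero displacement variance: EV undefined")
    r = dx - _drift_pf(trajectory, params, states)
    return float(1.0 - np.sum(r * r) / tss)


def directional_statistic(trajectory: Trajectory, subsample_n: int = 1) -> float:
    """Directional correlation statistic D in [0, 1].

    After subsampling every ``subsample_n``-th frame, counts the number k of
    sign changes between consecutive displacements, pooled over both
    sisters (m comparisons), and returns D = P(K > k) under K ~
    Binomial(m, 1/2).  D >= 0.99 flags significant directional correlation
    at the 1% level.  Zero displacements count as no direction change (the
    previous sign is carried forward).
    """
    if subsample_n < 1:
        raise ValueError("subsample_n must be >= 1")
    k = 0
    m = 0
    for series in (trajectory.x1, trajectory.x2):
        x = series[::subsample_n]
        if len(x) < 3:
            continue
        s = np.sign(np.diff(x))
        # carry the previous sign through zero displacements
        nz = s != 0.0
        idx = np.where(nz, np.arange(len(s)), -1)
        idx = np.maximum.accumulate(idx)
        filled = np.where(idx >= 0, s[np.maximum(idx, 0)], 0.0)
        f = filled[filled != 0.0]
        if len(f) < 2:
            continue
        k += int(np.sum(f[1:] != f[:-1]))
        m += len(f) - 1
    if m == 0:
        warnings.warn("too few frames after subsampling; D undefined", stacklevel=2)
        return float("nan")
    return float(stats.binom.sf(k, m, 0.5))


def half_period_autocorrelation(trajectory: Trajectory) -> float | None:
    """Half-period in seconds: lag of the first local minimum of the
    autocorrelation of the mean-subtracted sister-1 position.

    Returns None when no trustworthy minimum exists before lag n/2 (the
    minimum must dip below the white-noise band -2/sqrt(n)).
    """
    if trajectory.n_frames < 20:
        raise ValueError("need at least 20 frames for autocorrelation analysis")
    a = trajectory.x1 - trajectory.x1.mean()
    n = len(a)
    if np.allclose(a, 0.0):
        warnings.warn("constant position series: autocorrelation undefined", stacklevel=2)
        return None
    acf = np.correlate(a, a, mode="full")[n - 1 :]
    acf = acf / acf[0]
    limit = n // 2
    band = -2.0 / np.sqrt(n)
    for lag in range(1, limit):
        if acf[lag] <= acf[lag - 1] and acf[lag] < acf[lag + 1]:
            # the first local minimum; trustworthy only if it dips below
            # the white-noise band
            if acf[lag] < band:
                return float(lag * trajectory.dt)
            return None
    return None


def filter_trajectories(
    ev: np.ndarray,
    log_bf: np.ndarray,
    band_sds: float = 2.0,
) -> np.ndarray:
    """Flag trajectories inside a robust band around the EV–log-Bayes-factor
    line, excluding the high-BF/low-EV outlier group (tracking artefacts).

    Fits log_bf ~ EV by iteratively reweighted least squares with a
    MAD-based scale; pass = |residual| <= band_sds * robust scale.
    """
    ev = np.asarray(ev, dtype=float)
    log_bf = np.asarray(log_bf, dtype=float)
    if ev.shape != log_bf.shape:
        raise ValueError("ev and log_bf must have equal length")
    n = len(ev)
    if n < 10:
        warnings.warn("fewer than 10 trajectories: refusing to fit the band, all pass",
                      stacklevel=2)
        return np.ones(n, dtype=bool)
    mask = np.ones(n, dtype=bool)
    slope = intercept = 0.0
    scale = np.inf
    for _ in range(3):
        slope, intercept = np.polyfit(ev[mask], log_bf[mask], 1)
        resid = log_bf - (slope * ev + intercept)
        scale = 1.4826 * np.median(np.abs(resid[mask] - np.median(resid[mask])))
        if scale <= 1e-9 * (np.std(log_bf) + 1.0):
            # residuals numerically zero: everything sits on the line
            return np.ones(n, dtype=bool)
        mask = np.abs(resid) <= 2.5 * scale
        if mask.sum() < 3:
            mask = np.ones(n, dtype=bool)
            break
    resid = log_bf - (slope * ev + intercept)
    return np.abs(resid) <= band_sds * scale
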