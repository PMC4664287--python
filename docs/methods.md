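# Methods

This note records the model, the numerical choices and the limits of what
the test suite demonstrates. It is the package's own account; nothing here
is an empirical claim beyond what the tests and `scripts/acceptance.py`
compute.

## Model and discretisation

Sister kinetochores are points on the axis normal to the metaphase plate
(plate at x = 0, sister 1 on the right by convention: time-averaged
x¹ > x²). The system is overdamped, so force balance reduces to a velocity
balance; all forces are divided by the unknown drag coefficient γ and
therefore reported in velocity-commensurate units. Per frame Δt the
displacement of sister k is

    dxᵏ = Δt·[(−1)ᵏ v_{σᵏ} + (−1)ᵏ κ (x¹ − x² − L cos θ) − α xᵏ] + Δt·N(0, 1/τ)

with the sign convention that sister 1's pole lies at +∞ (its K-fibre term
enters with −, sister 2's with +). The noise enters the displacement as
Δt·N(0, s²), s² = 1/τ — not with √Δt scaling — so that τ in s² µm⁻²
reproduces the intended per-frame noise exactly; with τ = 1000 and
Δt = 2 s the per-frame displacement noise s.d. is 2/√1000 ≈ 0.063 µm.
This is a first-order (Euler) discretisation: forces are treated as
constant over a frame, accurate to O(Δt²).

Hidden states: each sister's K-fibre is + (polymerising) or −
(depolymerising). Conditional on the pair being coherent (σ¹ ≠ σ²), each
sister independently keeps its state with probability p_c per frame;
incoherent, with p_ic. The induced coherent/incoherent chain has
stationary coherent fraction 2p_ic q_ic / (2p_c q_c + 2p_ic q_ic) and mean
dwell times 1/(2p_c q_c), 1/(2p_ic q_ic) frames — used as closed-form
oracles in the tests.

### Reference parameter set and generator defaults

Simulations default to the reference set p_c = 0.94, p_ic = 0.61,
v₊ = 0.05, v₋ = −0.03 µm s⁻¹, L = 0.8 µm, κ = 0.05 s⁻¹, α = 0.03 s⁻¹,
τ = 1000 s² µm⁻², Δt = 2 s — the regime of visibly saw-toothed human
kinetochore oscillations. The generator draws the full state path first,
then the displacement noise (fixed stream order; numpy PCG64), starts the
pair plate-centred at ±L/2 with the initial pair state uniform over the
four states, and simulates in 1D (θ ≡ 0) unless a twist series is given.

## Inference

Time is measured in frames internally: v±, κ, α are multiplied by Δt and
τ divided by Δt², which makes every full conditional conjugate; the API
converts back to seconds-based units. The Gibbs sweep is:

1. **(v₊, v₋, κ, α) | L, τ, σ** — the drift is linear in these, so the
   full conditional is multivariate Gaussian (prior
   v± ~ N(±0.03, 0.1²) µm/s; κ, α ~ N(0.01, 0.1²) s⁻¹ truncated at 0).
   Truncation is enforced by rejection (≤ 100 tries), falling back to two
   coordinate-wise truncated-Gibbs passes when the mass sits against the
   boundary. A velocity whose state never occurs reverts to its prior
   automatically (its design column is zero and priors are independent).
2. **L | κ, τ, σ** — univariate Gaussian (coefficient −(−1)ᵏ κ cos θ),
   truncated at 0. The default prior N(0.775, 0.110²) µm comes from the
   resting-length module; a wide prior (s_L > 0.3 µm) triggers an
   identifiability warning, because with θ ≡ 0 the likelihood is exactly
   invariant under (L, v±) → (L + δ, v± + κδ) and only the prior pins L.
3. **τ | rest** — Gamma(c + (n−1), d′ + RSS/2) on the per-frame precision
   (prior τ ~ Γ(0.5, 10⁻³) in physical units; the exponent n−1 reflects
   the 2(n−1) displacement observations).
4. **σ | rest** — exact joint draw of the 4-state pair chain by forward
   filtering–backward sampling (FFBS), log-space-shifted and renormalised
   per frame to avoid underflow; initial distribution uniform over the
   four states. The kernels are numba-jitted when numba is available, with
   an identical pure-Python fallback (same pre-drawn uniforms, so results
   agree).
5. **(p_c, p_ic) | σ** — Beta updates using per-sister persistence counts:
   every pair transition contributes two independent Bernoulli trials,
   matching exactly the product form of the FFBS transition matrix (priors
   Beta(2, 1), shifting persistence away from zero).

Defaults: 2 chains × 3200 sweeps, 20% burn-in (≥ 5000 retained draws
total), split-chain R̂ < 1.1 on all eight parameters for convergence
(single chains are split in half for the diagnostic). Non-convergence is
reported, not fatal — such trajectories are meant to be discarded
downstream. State marginals are empirical frequencies over retained draws.

## Model selection

All marginal likelihoods refer to the per-frame displacement data, so
Bayes factors between models are directly comparable.

* **Brownian nulls.** M_BM (i.i.d. zero-mean Gaussian displacements),
  M_spring-BM (adds a centred inter-sister-distance regressor with
  opposite signs for the two sisters) and M_spring-drift-BM (adds a
  constant drift per sister) are conjugate normal–gamma linear models with
  closed-form marginals (τ ~ Γ(0.5, 4·10⁻³) per-frame; coefficient prior
  N(0, τ⁻¹·100·I)). Removing columns reproduces the nested marginal
  exactly.
* **Coherence–incoherence marginal.** A single-high-density-point (Chib)
  estimator: log π(X) = log π(X|Θ*) + log π(Θ*) − log π̂(Θ*|X) with Θ* the
  posterior mean, the hidden states summed out exactly by the forward
  filter, the (τ, p_c, p_ic) ordinate Rao-Blackwellised over the main run,
  and the (v₊, v₋, κ, α) and L ordinates from two reduced Gibbs runs.
  Truncated conditionals use their exact normalisers (bivariate Gaussian
  orthant probability). Standard errors are batch means (20 batches),
  which ignore residual autocorrelation and are therefore mildly
  optimistic; the estimator is validated against the closed-form conjugate
  marginals, where the plain-BM case is algebraically exact.
* **Explained variance.** EV = 1 − RSS/TSS on pooled displacements, drift
  evaluated at posterior-mean parameters and per-frame modal states
  (choice among modal/sampled/marginalised states is ours; modal keeps EV
  deterministic given a fit). Noise-free drift gives EV = 1; pure Brownian
  data gives EV ≈ 0; at the reference settings EV ≈ 1 − (Δt²/τ)/var(dx).
* **Directional statistic.** After subsampling every n-th frame, D = P(K >
  k) for K ~ Binomial(m, ½), with k the observed direction changes pooled
  over both sisters. Zero displacements inherit the previous sign ("no
  change"). D ≥ 0.99 flags directional correlation at 1%; by discreteness
  the test is conservative (achieved size slightly below nominal).
* **Half-period.** Lag (s) of the first local minimum of the sister-1
  position autocorrelation, accepted only if it dips below the white-noise
  band −2/√n, otherwise reported absent. On simulations from the model the
  geometric dwell-time spread blurs periodicity, so this statistic is most
  informative on strongly periodic (real or sinusoid-like) trajectories.
* **Population filter.** Robust line fit (IRLS with MAD scale) of
  log-Bayes-factor vs. EV; trajectories within 2 robust s.d. of the line
  pass, which excises the high-BF/low-EV group produced by tracking-spike
  artefacts. Fewer than 10 trajectories: no band is fitted and all pass,
  with a warning.

## Events and forces

A coherent run is a maximal stretch of one coherent pair state tolerating
interruptions of ≤ 3 consecutive frames and containing ≥ 5 consecutive
uninterrupted in-state frames. Runs are detected per MCMC state-path
sample; per-frame start/end probabilities are sample fractions, and end
events are consolidated by thresholding the probability mass in a ±1-frame
window at 0.5 (greedy peak-merge — the consolidation rule is our choice).
For each event, samples containing a matching run (end within ±2 frames)
vote on which sister's state changed first at run end; the leading sister
is the depolymerising one. Simultaneous switches count half to each class;
samples without a resolvable run leave residual probability, so
p_LIDS + p_TIDS ≤ 1. Classification is by the larger probability.

Force components at frame i, sister k (anti-poleward positive):
f_kfibre = v_{σᵏᵢ} (the state of the following displacement serves as the
state at the frame, hence undefined at the last frame), f_spring =
κ(dᵢ − L cos θᵢ), f_pef = (−1)ᵏ⁺¹ α xᵏᵢ; the identity f_total = f_kfibre +
f_spring + f_pef holds exactly. A plate-normal convention is available, in
which f_total·Δt is the deterministic drift displacement. Switch-aligned
profiles are averaged in a ±10-frame (±20 s) window around each event's
median switching time, by class and as a heat map binned by
p_LIDS − p_TIDS; boundary events contribute only their valid lags.
Absolute forces use Stokes' law F = 6πηrv with defaults r = 0.5 µm,
η = 190 Pa s (so F[pN] = 6π·η·r·v numerically when r is in µm and v in
µm/s).

## Resting length

Under spindle depolymerisation the inter-sister distance is modelled as
d_{i+1} = d_i − βΔt(d_i − L) + Δt·N(0, 1/τ), stable for βΔt < 2. The Gibbs
fit (Gaussian conditionals for L and β, β truncated positive, Gamma for τ)
flags series whose posterior mean reversion is indistinguishable from zero
(βΔt < 0.02 in most draws) or whose L posterior is prior-dominated —
there L is unidentifiable and the fit must not pretend otherwise. The
population summary is the mean ± s.d. of per-series posterior means of L
over series passing an increment-EV filter (threshold 0.25, configurable),
and feeds `build_informed_prior`. The synthetic generator defaults to
L = 0.775 µm, β = 0.3 s⁻¹, τ = 2000 s² µm⁻²: a ~3 s relaxation time that
is resolvable at Δt = 2 s and yields increment EV ≈ βΔt/2 = 0.3, clearing
the quality filter under its own stated conditions.

## What the synthetic data do and do not show

The generator emulates the model exactly: Gaussian displacement noise,
geometric dwell times, no missing frames, no tracking errors, θ ≡ 0, and a
single parameter set per population (radial positions are attached as
metadata, not mechanistically coupled to α unless a test constructs that
coupling explicitly). Passing tests therefore demonstrate correctness of
the algorithms and calibration *under the model*, not that real
kinetochore data satisfy the model: real trajectories carry tracking
noise and spikes, non-Gaussian and state-dependent fluctuations,
inter-trajectory parameter heterogeneity and finite twist, which is
precisely why the EV/Bayes-factor/D filters exist. Population-scale
results from live-cell datasets (EV distributions, LIDS:TIDS ratios,
radial trends) are outputs the pipeline can produce but are not asserted
against any external numbers here.

## Problem sizes and tolerances

Tests run at sizes chosen to keep the full suite around a minute while
leaving comfortable statistical margins: the recovery fit uses one
600-frame trajectory with 2 chains × 6000 sweeps; credible-interval
calibration uses 20 fits of 150-frame trajectories; switch-detection
recall uses 20 fits of 200-frame trajectories with 150 state samples each;
the D-statistic null calibration uses 10⁴ Brownian trajectories of 150
frames; the force-component ranking pools 12 × 20000 simulated frames
(the stationary |PEF|–|spring| gap at the reference settings is only ~8%,
so short samples can invert the ordering by chance). FFBS exactness is
checked against exhaustive path enumeration at n ≤ 6 to 10⁻¹⁰; conjugate
updates against hand algebra exactly; the Chib estimator against closed
forms within 3 batch-means standard errors.

## Known limitations

* Forces are identified only up to the drag coefficient; pN values rest
  entirely on the assumed Stokes radius and viscosity.
* The PEF is linearised about the plate and the spring is Hookean; both
  break down far from the plate or at large stretch.
* The sampler treats θ as observed and noise-free.
* Chen/Chib standard errors are batch-means approximations.
* Event consolidation and the LIDS/TIDS tie rule are reasonable but not
  unique conventions; both are configurable at the call sites.
* The half-period statistic is unreliable on trajectories whose dwell
  times are as dispersed as the model's geometric switching produces.
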