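# kinosc

Bayesian reverse engineering of metaphase sister-kinetochore oscillations.

During metaphase, paired sister kinetochores oscillate quasi-periodically
along the spindle axis, driven by three forces: the attached K-fibre
(a microtubule bundle that is either polymerising, pushing anti-poleward,
or depolymerising, pulling poleward), the centromeric chromatin connecting
the sisters (a Hookean spring of natural length *L*), and the polar
ejection force (PEF) pushing chromosome arms back to the metaphase plate.
`kinosc` implements a stochastic *coherence–incoherence* model of this
system and the machinery to fit it to high-resolution kinetochore tracking
data, so that hidden K-fibre states, switching events and the relative
force balance can be read off individual trajectories.

## The model

Sister positions \(x^1_t > x^2_t\) (µm, normal to the plate, plate at 0)
evolve per frame of length Δt (2 s) as

```
(x¹ₜ₊Δₜ − x¹ₜ)/Δt = −v_{σ¹ₜ} − κ (x¹ₜ − x²ₜ − L cos θₜ) − α x¹ₜ + N(0, s²)
(x²ₜ₊Δₜ − x²ₜ)/Δt = +v_{σ²ₜ} − κ (x²ₜ − x¹ₜ + L cos θₜ) − α x²ₜ + N(0, s²)
```

where σᵏₜ ∈ {+, −} is the hidden state of sister *k*'s K-fibre
(polymerising / depolymerising, speeds v₊ > 0 > v₋), κ and α are the
drag-normalised spring and PEF constants (s⁻¹), θ the twist angle, and
τ = s⁻² the noise precision. The states form a hidden Markov chain: each
sister keeps its state with probability p_c per frame while the pair is
*coherent* (moving together, σ¹ ≠ σ²) and p_ic while *incoherent*
(contracting +/+ or expanding −/−). Oscillations arise when p_c > p_ic.

Everything is conjugate given the states, so inference is a blocked Gibbs
sampler: exact multivariate-Gaussian updates for (v₊, v₋, κ, α) and L,
Gamma for τ, Beta for (p_c, p_ic), and an exact joint draw of the 4-state
pair chain by forward filtering–backward sampling. A single trajectory
cannot identify L and v± separately (an approximate model symmetry), so the
fit uses an informed Gaussian prior on L — estimated by the
`resting_length` module from inter-sister distances of spindle-depolymerised
(nocodazole-treated) cells, where the distance relaxes in a harmonic well
around L (default 0.775 ± 0.110 µm).

On top of the fit the package provides:

* **Model selection** (`kinosc.selection`): Bayes factors against
  Brownian-motion null models (closed-form conjugate marginals; a
  Chib/Chen single-ordinate estimator for the coherence–incoherence
  marginal), explained variance (EV), a binomial directional-correlation
  statistic D, and an autocorrelation half-period.
* **Event detection** (`kinosc.events`): coherent runs (≥ 5 consecutive
  frames in one coherent state, tolerating ≤ 3-frame transients),
  per-frame switch probabilities across MCMC state samples, and LIDS/TIDS
  classification — whether the leading (depolymerising) or trailing sister
  initiated each directional switch.
* **Force decomposition** (`kinosc.events`): per-frame K-fibre, spring and
  PEF components in µm s⁻¹ (velocity-commensurate, since forces are only
  identified up to the drag coefficient), switch-aligned force profiles,
  and absolute forces in pN via Stokes' law F = 6πηrv.
* **Population statistics** (`kinosc.population`): metaphase-plate
  alignment deviation, oscillation amplitude, plate thickness, radial
  binning and parameter–radius trends, plus a reproducible end-to-end
  pipeline.

## Worked example

Simulate a trajectory at the model's reference parameter set
(p_c = 0.94, p_ic = 0.61, v₊ = 0.05 µm/s, v₋ = −0.03 µm/s, L = 0.8 µm,
κ = 0.05 s⁻¹, α = 0.03 s⁻¹, τ = 1000 s² µm⁻², Δt = 2 s), then recover the
parameters and analyse the switches:

```python
import numpy as np
from kinosc import (
    fig1b_parameters, SimulationConfig, simulate_trajectory,
    PriorSpec, MCMCConfig, run_mcmc,
    explained_variance, directional_statistic, bm_log_marginal,
    estimate_log_marginal_chen, detect_switch_events, classify_lids_tids,
    force_decompose, stokes_force,
)

params = fig1b_parameters()
traj, truth = simulate_trajectory(SimulationConfig(params=params, n_frames=300, seed=3))

prior = PriorSpec().with_informed_L(0.8, 0.11)   # resting-length prior
post, report = run_mcmc(traj, prior, MCMCConfig(n_sweeps=3200, n_chains=2), seed=1)

print(f"converged: {report.converged}")
for name in ("v_plus", "v_minus", "kappa", "L", "alpha", "tau"):
    s = post.summary[name]
    print(f"{name:8s} {s['mean']:9.4f}  95% CI [{s['q2.5']:8.4f}, {s['q97.5']:8.4f}]")

ev = explained_variance(traj, post)
log_bf = estimate_log_marginal_chen(post, traj, prior, seed=2)[0] - bm_log_marginal(traj)
print(f"EV = {ev:.2f},  log B[coh/BM] = {log_bf:.1f},  D_1 = {directional_statistic(traj):.3f}")

samples = post.state_samples(max_samples=200, rng=0)
events = [classify_lids_tids(e, samples) for e in detect_switch_events(samples)]
print(f"{len(events)} switch events, {sum(e.classification == 'LIDS' for e in events)} LIDS")

profile = force_decompose(traj, post.mean_parameters(), post.modal_states())
for comp in ("f_kfibre", "f_spring", "f_pef"):
    print(f"mean |{comp}| = {np.nanmean(np.abs(profile.component(comp))):.4f} um/s")
print(f"F- (Stokes) = {stokes_force(abs(post.summary['v_minus']['mean'])):.1f} pN")
```

Output:

```
converged: True
v_plus      0.0530  95% CI [  0.0392,   0.0681]
v_minus    -0.0276  95% CI [ -0.0417,  -0.0123]
kappa       0.0537  95% CI [  0.0362,   0.0714]
L           0.7932  95% CI [  0.5503,   1.0083]
alpha       0.0305  95% CI [  0.0240,   0.0368]
tau      1034.1690  95% CI [897.0261, 1176.4112]
EV = 0.64,  log B[coh/BM] = 125.1,  D_1 = 1.000
16 switch events, 9 LIDS
mean |f_kfibre| = 0.0402 um/s
mean |f_spring| = 0.0192 um/s
mean |f_pef| = 0.0161 um/s
F- (Stokes) = 49.5 pN
```

Every generative value lies inside its 95% credible interval. The high EV
(0.64) and strongly positive log Bayes factor say this trajectory is a
clear oscillator; D₁ ≈ 1 flags significant directional persistence. The
K-fibre force dominates the decomposition, and converting the inferred
depolymerisation speed with Stokes' law (chromosome radius 0.5 µm, spindle
viscosity 190 Pa s) gives an absolute pulling force of order tens of pN.

There is also a CLI (`kinosc simulate|fit|select|events|population|all`)
wrapping the same functions; see `kinosc --help`.

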