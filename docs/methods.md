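# Methods

`epimap` estimates spatio-temporal seizure propagation — which brain
regions start a seizure (epileptogenic zone, EZ), which are recruited
later (propagation zone, PZ), and which stay out — by inverting a
generative model of SEEG log power built around the Epileptor neural-mass
model. This note documents the model, the numerical choices, and what the
synthetic validation does and does not establish.

## The forward model

**Source dynamics.** Each brain region is an Epileptor oscillator coupled
to the others through a structural connectome C (nonnegative,
max-normalized to 1, zero diagonal). Synthetic ground-truth data are
generated with the full 5-variable Epileptor per node: fast discharges
(x1, y1), spike-and-wave activity (x2, y2), and a slow permittivity z that
gates the transition between interictal and ictal states. The convolution
term g(x1) — an exponentially weighted moving average of x1 with decay
rate γ = 0.01 — is realized as a sixth state u with du/dt = x1 − γu,
u(0) = x1(0)/γ (its stationary value), which turns the integral into an
ODE any one-step scheme can integrate. Fixed constants: τ0 = 2857,
τ2 = 10, I1 = 3.1, I2 = 0.45. Coupling enters the permittivity equation:
dz_i/dt picks up −K Σ_j C_ij (x1_j − x1_i), so a seizing neighbour drags
z_i down toward that region's own seizure onset.

**Excitability and the seizure threshold.** The per-region parameter x0
sets how close a region sits to the seizure bifurcation. An isolated 2D
node has a stable fixed point only while the leftmost root x* of
x³ + 2x² + 4x = 1 + I1 + 4·x0 stays on the stable branch; the stability
boundary (Jacobian trace −3x² − 4x − 1/τ0 = 0) gives a critical
excitability of ≈ −2.05 at τ0 = 20, consistent with the −2.1 bound used
to interpret x0 clinically. The package estimates this threshold two
independent ways — bisection on simulated trajectories and the
closed-form linear-stability calculation — and the tests require them to
agree.

**Sensor model.** SEEG contacts see a linear mixture of regional
activity: s_i(t) = Σ_j G_ij φ_j(t), with gain coefficients summing
inverse-square distance contributions c·A_k/‖x_i − x_k‖² over each
region's surface vertices. Distances are clamped below at 1 length unit
so an implanted contact touching a vertex does not produce a singular
gain. Orientation of the neural tissue is deliberately not modelled. For
the synthetic pipeline the gain rows are normalized to unit sum: each
contact then records a weighted average of regional activity, which keeps
channel power on a common scale the way ongoing background activity does
in clinical recordings; the likelihood's amplitude/offset parameters (α,
β) absorb the global scale either way.

## The synthetic validation scenario

The bundled scenario emulates the standard ground-truth configuration:
2 EZ regions at x0 = −1.8 (autonomously seizing), 4 PZ regions at −2.3
(below threshold, strongly connected to the EZ), the rest at −3.0, global
coupling K = 1, Heun integration with dt = 0.04 for 2500 model time
units. Defaults chosen where the configuration is otherwise open:

- **Network fixture.** 24 regions / 96 contacts by default (a scaled-down
  stand-in for a whole-brain parcellation with a clinical implantation;
  contacts cluster around the EZ/PZ centroids). Background connectome
  weights are sparse log-normal (median e⁻⁴) with EZ–EZ and EZ–PZ links
  near the maximum; this scale separation is what lets the seizure
  recruit the PZ without the rest of the network holding the EZ at rest.
  The connectome is drawn before the sensor positions so the source
  dynamics for a seed do not depend on the implantation size.
- **Initial state.** All nodes start on the interictal branch with the
  permittivity clamped at z = 3.5 (the generative model's own prior-mean
  initial state) and the other five states equilibrated against it. From
  the true stable fixed point (z ≈ 4.05) the slow drift at τ0 = 2857
  would not reach seizure onset inside the 2500-unit window; starting at
  z = 3.5 puts EZ onset near t ≈ 1100 units with PZ recruitment a few
  hundred units later.
- **Background activity.** Small additive noise (SD 0.05, seeded) on the
  fast variables only, added after each Heun step; z and u stay
  deterministic so recruitment remains coupling-driven. Without it a
  deterministic interictal is exactly constant, the log power collapses
  to the numerical floor, and the feature geometry becomes an artifact;
  with it the interictal baseline of each channel reflects its gain-row
  mass, which is the structure the likelihood mean α·log⟨G_i, e^x⟩ + β
  expects.
- **Time mapping.** Model time is dimensionless; the 2500-unit simulation
  is nominally mapped to a 300 s recording (0.12 s per unit) so onset
  tolerances can be stated in seconds. Under this mapping the ictal
  discharge runs at ≈ 1.8 Hz, so the scenario's feature pipeline uses a
  1 Hz high-pass; the 10 Hz default applies to clinical-rate (≥ 256 Hz)
  recordings where discharges sit above 10 Hz.
- **Ground truth.** Recruitment and onset are defined by the first upward
  crossing of x1 through 0 (configurable).

Observation noise for robustness experiments is zero-mean Gaussian with a
single SD across channels, chosen so that the channel-averaged SNR —
mean over channels of clean signal variance, divided by the noise
variance — hits the requested level.

## Data features

Raw SEEG → high-pass (Butterworth order 4, zero-phase forward-backward so
the envelope is not lagged; onset times are the scientific output) →
mean-square power over a sliding 1 s rectangular window with 50% overlap
→ natural log (floored at 1e−12 before the log) → zero-phase low-pass
smoothing of the envelope (cutoff 0.1 of the envelope Nyquist; the knob
that is tuned per recording) → linear resampling to exactly T = 300
points spanning the recording. The augmented feature ρ_i is the second
sample moment of channel i's log-power trace, (1/T) Σ_j s_i(t_j)².

## The generative model

θ = (x0 per region, x(t0), z(t0), K, τ0, α, β, ε1, ε2), a flat vector of
length 3N + 6 (498 at N = 164). Priors are normal, conditioned on the
clinical hypothesis for the excitability block — N(−1.5, 1) inside the
hypothesis, N(−3.0, 1) outside — and N(−2, 10)/N(3.5, 10) for the initial
states, N(1, 10) for K, N(20, 10) for τ0, N(1, 10)/N(0, 10) for α/β,
N(1, 10) for both noise scales. K, τ0, ε1, ε2 are truncated below at
zero, with the renormalization constant included in the log density; α
and β are structurally signed/offset parameters and stay untruncated.

The latent trajectory is deterministic given θ (the δ-limit of the
state-transition prior): one classical RK4 step of size 0.1 of the
coupled 2D Epileptor between consecutive observation instants (substep
count configurable). The observation likelihood is Gaussian per sample,
s_i(t_j) ~ N(α·log⟨G_i, e^{x(t_j)}⟩ + β, ε1), natural log throughout.
The augmented term is ρ_i ~ N((1/T) Σ_j m_i(t_j)², ε2) with m the
model-predicted log-power mean. Evaluating the ρ mean on the predicted
rather than the observed log power is what makes the augmented feature
informative — it pulls the predicted power profile toward the observed
total power, which is its stated purpose — and it keeps the optimization
well-posed: with an observed-side mean the ρ residual is identically
zero and the posterior grows without bound as ε2 → 0.

## Gradients and optimization

The log-posterior gradient is analytic end to end. The likelihood
gradient with respect to the latent x feeds a hand-derived reverse-mode
(adjoint) sweep through the RK4 recursion: stage states are recomputed
from the stored substep starts and the vector-Jacobian product of the 2D
Epileptor field is applied at each stage, accumulating gradients for x0,
the initial state, K, and τ0. The auxiliary parameters (α, β, ε1, ε2)
have closed-form terms. The adjoint is verified against central finite
differences (relative tolerance 1e−4) in the test suite. Both the forward
integration and the adjoint are numba-compiled with preallocated
buffers; one objective-plus-gradient evaluation costs ≈ 1.5 ms at N = 24,
T = 300.

MAP runs scipy's L-BFGS-B (memory 10, strong-Wolfe line search, iteration
cap 20 000 by default) on the negative log posterior. Positive parameters
are optimized through a log transform with the log-Jacobian added to the
objective, so the reported mode is the transformed-space mode pulled back
to natural space — the behaviour of standard probabilistic-programming
optimizers. Convergence is declared when any of three criteria holds:
|Δ log posterior| < 1e−12 between accepted iterates, unconstrained
gradient norm < 1e−8, or the optimizer's own parameter-change test.
Latent-integration divergences during the line search return a large
finite penalty (1e10) with zero gradient, which fails the sufficient-
decrease condition and forces backtracking; a finite value is used
instead of +∞ because the line search handles it robustly and the
curvature pairs are never built from penalized points. A divergence at
the initial point raises with advice to pick a different start.
Multi-start draws initial vectors from normals centred at the prior means
with one absolute SD for all parameters (redrawing truncated coordinates
until positive) and keeps the run with the highest final posterior.

## EZ/PZ identification and evaluation

Onset time per region = first sample at which the inferred fast variable
crosses 0 upward, on the feature time grid (seconds). With t_λ the
earliest onset and tolerance t_ε (default 10 s), regions with onsets in
[t_λ, t_λ + t_ε] are EZ, later onsets are PZ, no crossing is
not-recruited. Precision/recall compare predicted EZ with a hypothesis
set, pooled over patients (aggregate counts, then divide) or per patient;
an empty predicted EZ leaves precision undefined (reported as missing,
not 0). The 3×2 confusion matrix crosses model labels with
hypothesis membership and normalizes percentages within each clinical
column.

## Problem sizes

The reference fits in the examples and test suite use the 24-region /
96-contact bundle, both for single inversions and for the noise and
initialization sweeps (coarse grids, small replicate counts); these sizes
were chosen as the package's own desk-scale validation configuration.
Twelve-region replicas exist and run faster, but their posterior
landscapes proved noticeably lumpier and more seed-dependent, so the
headline sweeps stay on the bundle. Larger grids and replicate counts
are a parameter away (`snr_robustness_experiment`,
`init_robustness_experiment`).

## Known limitations

- The synthetic generator emulates coupling-driven recruitment, sensor
  mixing, background activity, and observation noise; it does not emulate
  traveling ictal waves, bifurcation-type diversity on the fast timescale,
  parcellation errors in the forward solution, artifacts, or montage
  effects. Passing the synthetic validation therefore shows internal
  consistency of the inversion at desk scale, not clinical performance.
- MAP is a point estimate; the posterior is multimodal (wide proposal SDs
  land in spurious modes, reproduced in the initialization sweep) and the
  estimate carries no uncertainty. Full-posterior sampling is out of
  scope; the objective/gradient pair is exposed for anyone who wants to
  try.
- The inferred x0 values are identified only up to the structural
  degeneracies of the hierarchy (parameters → latent states → mixed
  sensors); downstream conclusions are read from the latent onset times,
  not from raw x0 magnitudes.
- A fit can legitimately return an empty recruited set (non-seizing mode)
  on weakly informative data; evaluation reports this as undefined
  precision rather than penalizing silently.
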