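# Methods

This note documents the model implemented by `ringsampler`, the conventions
and parameter choices behind it, and what the synthetic experiments do and do
not establish.

## Spike-coding network engine (`ringsampler.scn`)

A spike-coding network (SCN) of N leaky integrate-and-fire neurons represents
an M-dimensional signal z through a linear readout of filtered spike trains,

    zhat = D r,        r' = -λ r + o,

with D the M×N decoding matrix, o the spike train, and λ the shared
voltage/filter leak (1/s). Each neuron's voltage is, up to spike costs, the
projection of the readout error on its decoding column, v_i = D_iᵀ(z − zhat),
and the greedy spike rule — fire the neuron with the largest threshold
violation v_i − T_i, at most one per time step, ties to the lowest index —
guarantees every spike weakly decreases the instantaneous reconstruction
error ‖z − zhat‖². Thresholds are

    T_i = (ν λ + μ λ² + ‖D_i‖²) / 2,

where ν and μ are optional linear and quadratic spike costs (defaults 0).
Fast recurrent weights Ω_f = −DᵀD deliver the post-spike reset and
excitation/inhibition balance; there is no separate after-spike voltage
reset. Slow weights implement the target dynamics: for a readout-space drift
F(z) the neuron-space drive is Dᵀ(F(zhat) + λ zhat), the +λ zhat term
compensating the filter leak so that the *readout*, not the voltage, follows
F.

Conventions worth stating explicitly:

- **Spikes are unit-area events.** The fast-weight kick Ω_f[:, i] and the
  increment of r_i are applied once per spike, not scaled by dt. This makes
  each spike move the readout by exactly D_i, which is what the greedy-rule
  cost analysis assumes.
- **Integration** is explicit Euler–Maruyama with default dt = 1e-4 s;
  Wiener increments are scaled by √dt. Non-finite voltages abort with an
  error naming the step and neuron.
- **Filter conventions.** The default is r' = −λr + o with zhat = D r. A
  second convention, r' = −λr + λo with zhat = D r / λ, appears in some
  derivations of this network family; the two differ only by the fixed
  rescaling r → λr, which the test suite verifies spike-for-spike. The
  switch is `SCNParams.filter_convention`.
- **Voltage noise is correlated, never independent.** An M-dimensional
  Wiener drive ξ enters all neurons as η = Dᵀξ, so the injected noise has
  rank ≤ M and covariance ∝ DᵀD. This is what makes lag-0 subthreshold
  correlations mirror tuning similarity (+ for like-tuned, − for
  opposite-tuned pairs) — one of the model's testable signatures.

## Polynomial energies and multiplicative connectivity (`ringsampler.poly`)

Distributions P(z) ∝ exp(−U(z)) with polynomial U have polynomial score
functions: if U has degree g+1 then ∇U(z) = Σ_{d=0..g} A_d z^(d), where
z^(d) is the d-fold Kronecker power and A_d is M×M^d. Because of the
Kronecker mixed-product identity, A_d (D r)^(d) = A_d D^(d) r^(d), so the
drift lifts to neuron space as per-degree "multiplicative" weight matrices

    Ω_s^(d) = −(1/τ_s) Dᵀ A_d D^(d)     (d ≠ 1),
    Ω_s^(1) = Dᵀ(−(1/τ_s) A_1 + λ I) D,

acting on Kronecker powers of r — synaptic interactions where d presynaptic
activities multiply. At simulation time the engine evaluates the drift in
readout space and lifts it by Dᵀ (mathematically identical, numerically
cheaper); the materialized matrices are available for inspection and are
tested against the composed form. Kronecker index ordering is row-major
throughout, and each monomial of the gradient is assigned to its canonical
(sorted-index) slot, so `g_vector` and the A_d agree.

`check_normalizable` guards every sampling entry point: in 1-D the criterion
is analytic (even top degree, positive leading coefficient of U); in 2–3
dimensions exp(−U) is integrated on expanding grids and must stay finite and
stop growing.

## Langevin sampling (`ringsampler.langevin`)

Samples from P ∝ exp(−U) follow the overdamped Langevin equation

    dz = −(1/τ_s) ∇U(z) dt + √(2/τ_s) dW,

with τ_s the sampling timescale (default 50 ms). Two implementations exist:
a direct Euler–Maruyama integration (`langevin_oracle`, the reference) and
the spiking sampler (`build_sampler_network`), whose drift is the same score
function evaluated at the readout and whose voltage noise is the Dᵀ-projected
Wiener drive. Agreement between the two — means within 5%, variances within
10%, Kolmogorov–Smirnov distance < 0.1 on the double-well density — is the
package's first-line validation.

Numerical choices: paths are aborted when |z| exceeds 10× the outermost
stationary point of U (odd-degree drift blowups must fail loudly, with the
seed in the message); KS statistics are computed on samples thinned to one
per τ_s, because Langevin paths are autocorrelated and the KS test assumes
independence; the thinning interval is recorded in outputs. Sampling is
invariant to adding a constant to U (the gradient kills it), which is tested
path-for-path.

## Sensory populations and posterior inference (`ringsampler.sensory`)

An input population encodes a stimulus z through a rate kernel φ_i —
exponential exp(β_i·z), linear A_i·z + r0 (floored at 1e-6 events/s), or
logistic 1/(1+e^{−A_i·z}) — and a count-noise family. For Poisson counts
with a flat prior the posterior is P(z|σ) ∝ exp(−U) with

    U(z) = Σ_i [φ_i(z) − σ_i log φ_i(z)],
    ∇U(z) = Σ_i ∇φ_i(z) (1 − σ_i / φ_i(z)).

For the exponential kernel this reduces to Σ β_i (e^{β_i·z} − σ_i), which
the inference network evaluates exactly. For the linear and logistic kernels
the network-implementable form is a truncated power series (orders K = 2 and
K = 3 by default): the linear kernel expands 1/(1+x) as Σ (−x)^n, the
logistic kernel's score is expanded from the Taylor series of the logistic
function, generated by the coefficient recursion of φ' = φ(1−φ) rather than
a hand-copied table. Exact gradients remain available (`exact=True`) and
every kernel/family pairing is validated against central finite differences
of its log-likelihood.

Bernoulli, binomial(n), and geometric count laws use the logistic kernel as
their per-bin success probability; their score functions are β(f − σ),
β(nf − σ) and β((1+σ)f − 1) respectively, derived from the standard
likelihoods.

Dynamic stimuli rely on separation of timescales: the network samples much
faster than the stimulus moves, so causal moving-window moments
(`moment_filter`) of the readout track the instantaneous posterior. The
trajectory generator defaults to a behavioral step of 1 ms against a network
step of 0.1 ms; the ratio is configurable up to the 10³ used for
moment-recovery checks.

## Head-direction sampler (`ringsampler.hd`)

The heading estimate is updated by sampling from the Bayesian-filter
posterior P(θ_t | σ_t, θ_{t−1}), with σ_t Poisson counts encoding angular
velocity and the prior either flat (1-D) or a soft ring (2-D). Writing
α = 1 + dt βᵀβ, the 1-D update is

    θ_t = θ_{t−1} + (dt/α) βᵀ(σ_t − 1) + √(2 dt)/α · η_t,

and the 2-D Cartesian update — which avoids wraparound — is

    xy_t = xy_{t−1} + (dt/α) βᵀ(σ_t − 1) · (−y, x)
         − (γ dt/α) xy (x² + y² − c) + √(2 dt/α) η_t,

with attractor gain γ = 4. Two attractor conventions are exposed because the
source dynamics and the stated ring prior exp[−(x²+y²)(x²+y²−2ρ²)] are not
mutually consistent: the **literal** factor c = 2ρ² stabilizes radius √2·ρ,
while the **exact-gradient** of the prior gives c = ρ² and stable radius ρ.
Each mode is pinned to its own fixed point in the tests; no intent is
guessed. The rotation direction is (−y, x) so that positive ω advances
θ = atan2(y, x) counterclockwise with unit gain.

**Velocity encoder.** Two Poisson units with rate parameters ±β emit per-bin
counts with mean exp(β_i ω dt), so the mean count at ω = 0 is exactly 1 and
(σ − 1) is a zero-mean innovation at rest. The ± pair makes clockwise and
counterclockwise integration symmetric. β is sized by two constraints: the
per-step posterior must be tight (dt βᵀβ ≫ 1, making the integration gain
2β²dt/α ≈ 1), while β ω dt must stay small over the tested range, because
the exponential kernel's curvature otherwise biases the gain by ≈ (βωdt)²/6.
Defaults dt = 1e-4 s and β = ±700 s⁻¹ give α = 99 and gain 0.99–1.01 for
|ω| ≤ 5 rad/s. Input reliability is manipulated through β: the high-noise
condition β = ±220 (α ≈ 10.7) both diffuses faster and integrates with gain
≈ 0.91, so its heading error dominates at every horizon.

**Spiking implementation.** The same drift runs as an SCN with fast weights
−DᵀD, slow linear weights λDᵀD (the leak compensation — resolving the
ambiguity in the source bookkeeping by matching the noise-free fixed point of
the low-dimensional map), and voltage noise Dᵀξ at the α-scaled amplitude
√(2/α), again so that the spiking readout and the map share a stationary
law. The decoder is N = 8 columns at evenly spaced angles with common norm
0.125·ρ·√(2/N) (thresholds O(ρ²/N) with a small constant). The norm matters:
with coarse columns the λ·zhat compensation is evaluated on a heavily
quantized readout and acquires an O(λ‖D_i‖/2) inward radial bias that the
α-weakened attractor (γ/α ≈ 0.04) cannot counter, and the readout collapses;
at the default norm the noise-free network holds radius within ~1% of √2·ρ.

**Landmark reset.** A second Poisson population fires at rate
c·exp(−(x−r)² − y²) when the *true* heading points at a landmark fixed at
angle 0; its posterior contribution adds the term
2dt (x−r, y)(e^{−(x−r)²−y²} − 2σ^reset) to the update (taken literally,
including the factor 2σ). The gain matters qualitatively: the e^{−d²} part
of the term repels the estimate from the landmark's vicinity, so for mean
count c < 1/2 the literal dynamics stall at the bump-landmark distance where
e^{−d²} = 2c instead of completing the reset; the default c = 1 count/bin
keeps the net pull attractive at all distances and resets a π/2 displacement
within ~2 s, while the silent-landmark repulsion stays negligible
(≤ 2e^{−4}). Multiple input populations compose additively in
the update (products of likelihoods are sums of score functions), which
`multimodal_compose` makes explicit and the tests verify term-by-term.
The visual-remapping plasticity that would *learn* the landmark relation is
out of scope.

## Analysis statistics (`ringsampler.analysis`)

- **Voltage cross-correlations**: pairwise Pearson correlations at lags in
  [−max_lag, max_lag] (FFT-based); constant traces are flagged, not dropped
  silently.
- **Two-scale spike correlations**: trains convolved with Gaussian kernels
  of 1 ms and 100 ms, then Pearson-correlated. The 1 ms scale exposes the
  fast, balance-driven coordination (adjacent-tuned pairs alternate and
  anticorrelate; opposite-tuned pairs fire in rapid error-correcting pairs
  and correlate), the 100 ms scale the bump's rate comodulation (adjacent
  positive, long-range negative) — i.e. the sign structures of Ω_f and Ω_s
  respectively.
- **Tuning curves**: per-neuron mean r in 10° angle bins (36 bins default);
  unvisited bins are reported as missing, never interpolated.
- **Bump-velocity statistics**: wrapped finite differences of the decoded
  angle, grouped by velocity condition, with mean/variance/skewness and a
  (true ω, bump velocity) scatter. Wrap crossings count as small steps.
- **Drift curves**: per-time mean ± SD of the shortest-arc error
  |wrap(θhat − θ)| ∈ [0, π] across repetitions.
- **Localization index**: mean resultant length of the activity profile over
  preferred angles (1 = tight bump, 0 = delocalized). **Tuning
  heterogeneity**: one minus the mean pairwise correlation of peak-aligned,
  unit-mean tuning curves.

## Experiment conditions and problem sizes (`ringsampler.experiments`)

The figure-level experiments run at these reference sizes (chosen for
comfortable statistical margins at desk-scale compute; each function takes
a `seed` and derives all randomness from it):

| experiment | conditions |
|---|---|
| gradient/Kronecker equivalence | 100 random energies, dim ≤ 3, degree ≤ 5 |
| Gaussian sampling | N(1, 0.25), 20 neurons, 60 s, dt 1e-4, τ_s 50 ms |
| bimodal sampling | U = z⁴ − 2z², 120 s, thinned at τ_s |
| posterior inference | 10 exponential-kernel Poisson neurons, ω* = 1, one fixed count draw, 60 s |
| ring fixed point | noise-free map, starts 0.3–3× target, 150 s, both attractor modes |
| velocity integration | 8-neuron network, λ = 10, ω ∈ {±1, ±4}, 10 s each |
| drift vs noise | ω = 5 rad/s, 20 repetitions × 10 s per noise level, 10 ms checkpoints, 2 s burn-in |
| bump-velocity skew | low-D sampler, ±4 rad/s, 50 s each; KS mirror test on 25 ms-thinned velocities |
| correlation structure | 8-neuron network, ω = 0.5, 150 s |
| leak comparison | λ = 10 vs 0.5, ω = 0.5, 60 s each |
| landmark reset | 10 repetitions × 4 s, π/2 displacement, active vs silent landmark |

Two measurement choices deserve a note. Bump-velocity skewness is computed
on the low-dimensional sampler readout: the spiking decoder's per-spike
readout jumps (‖D_i‖) add symmetric quantization noise that dilutes the
skewness magnitude at any practical N without changing its sign, so the
low-D readout is the cleaner observable for that distribution-shape
prediction (the spiking network is used for every trajectory-level
statistic). Second, the correlation sign matrices are compared per angular
separation class (45°, 135°, 180°; the 90° class is excluded because the
ring connectivity is exactly zero there): pairs within a class are
statistically identical by symmetry, and individual adjacent-pair 1 ms
correlations sit near −0.01, too close to zero for single-pair signs to be
meaningful at any feasible run length.

## What the synthetic data does and does not show

All inputs are generated: angular-velocity trajectories (constant,
piecewise, Ornstein–Uhlenbeck, sinusoid), Poisson/Bernoulli/binomial/
geometric spike counts, and landmark streams. The generator reproduces the
statistical structure the model assumes — conditionally independent counts
given the stimulus, stationary kernels, a landmark fixed at angle 0 — and
none of the things real recordings add: spike-history dependence,
adaptation, heterogeneous and drifting tuning, common-input correlations
beyond the modeled ones, or behavioral feedback. Passing tests therefore
establishes internal consistency of the derivation and implementation
(sampler ↔ oracle ↔ quadrature agreement, network ↔ low-D map agreement,
predicted correlation signatures), not that biological HD circuits implement
this computation.

## Known limitations

- The strict 1-D circular implementation via trigonometric bases is not
  implemented (the 2-D Cartesian sampler is the primary object); the 1-D
  update is provided as the wrapped scalar map.
- Grid quadrature (densities and posteriors) covers 1–2 dimensions; higher
  dimensions would need importance sampling.
- The spiking HD network requires the documented decoder-norm regime; very
  coarse decoders make the self-referential embedding radially unstable (see
  above), which is a property of the quantized implementation, not of the
  underlying map.
- At most one neuron spikes per time step; rate-saturated regimes (network
  rates approaching 1/dt) would distort the dynamics before the instability
  guards trip.
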