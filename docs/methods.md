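# Methods

## Model

The single neuron is a modified Toporikova–Butera (TB) single-compartment
PBC burster. The somatic subsystem carries fast sodium (instantaneous
activation m∞, inactivation through 1−n), delayed-rectifier potassium
(n⁴), persistent sodium (mp∞ · h with slow inactivation h), a
calcium-activated nonspecific cation current (CAN, Hill activation in
[Ca] with exponent n_CAN and half-activation K_CAN), a passive leak, and
a constant stimulus current I_exc that enters the voltage equation with
a minus sign (larger I_exc hyperpolarizes). The calcium subsystem is an
autonomous linear rotation: (Ca, l) moves on the ellipse

    E = (Ca − Ca_c)²/d + d (l − l_c)²  =  const

with angular speed ε, so E is a conserved quantity of the flow (checked
analytically and to < 1e−6 relative drift per 1000 ms numerically) and
the rotation period is exactly 2π/ε ≈ 69.81 ms. By default the calcium
state starts at the ellipse center, making f(Ca) a constant and the
soma an autonomous three-variable burster; a nonzero ellipse amplitude
can be configured through the initial state.

### Gating kinetics and the τ assignment

All steady states are Boltzmann functions x∞(V) = 1/(1+exp((V−V_x)/s_x))
and both gate time constants have the form τ(V) = τ̄/cosh((V−V_x)/(2s_x)).
The two activation slopes are assigned s_m = −5 mV to fast-sodium m∞
(paired with V_m = −34 mV) and s_mp = −6 mV to persistent-sodium mp∞
(paired with V_p = −40 mV), the standard Butera-model pairing.

The maximal time constants are τ̄_n = 10 ms (fast potassium gate) and
τ̄_h = 10,000 ms (slow persistent-sodium inactivation). This is the
canonical Butera assignment and the one consistent with the model's
linear stability data: at the lower-branch Hopf equilibrium the Jacobian
entries ∂f₂/∂n = −1/τ_n(V) ≈ −0.87 /ms and ∂f₃/∂h = −1/τ_h(V) ≈
−1.07e−4 /ms require exactly this pairing, and slow h is what makes the
square-wave bursting mechanism work. Both values are exposed as plain
parameters (`tau_n_bar`, `tau_h_bar`) so the reversed variant can be
studied.

### Units

Conductances are in nS, voltages in mV, time in ms, calcium in μM, and
C_m = 21 in the capacitance unit that makes V̇ come out in mV/ms; all
results are invariant to the absolute unit as long as the ratios are
kept.

## Numerics

* **Integrator.** Fixed-step classical RK4, default dt = 0.02 ms
  (spikes are ~1 ms wide at their tip; halving dt changes sampled
  voltages by ~1e−6 mV). Fourth-order convergence is verified by a
  Richardson test. Integration is deterministic: identical
  configurations give bitwise-identical traces.
* **Delays.** Method of steps with a ring history buffer at integration
  resolution. Delayed voltages are evaluated by cubic Hermite
  interpolation; the node slope is taken from the final RK4 stage,
  whose O(dt³) accuracy keeps the interpolant at the integrator's
  order. The initial history is constant (equal to the initial state).
  With zero delays the coupled system is routed through the plain ODE
  driver, so the τ→0 limit is exact. For delays shorter than one step
  the lookup extrapolates the last completed Hermite interval by less
  than one step — only the weak-delay regime τ < 0.02 ms exercises
  this.
* **Run lengths.** Synchronization metrics use 2·10⁵ ms runs with the
  first 50% discarded and V sampled every 1 ms (≥ 20 burst cycles in
  the analysis window at the default burst period of ~2.4 s). Property
  tests use shorter runs (2–5·10⁴ ms) where only qualitative structure
  is asserted; the reduced two-parameter maps use 4·10⁴ ms per cell on
  5×5 / 4×4 grids, which preserves the qualitative contrasts
  (diagonal-delay dominance, coupling-sign contrast in similarity)
  of denser maps.
* **Initial conditions.** Somatic (V, n, h) = (−50, 0, 0.5); calcium at
  the ellipse center. Two-neuron runs offset neuron 2's voltage by
  +0.01 mV so complete synchronization is demonstrated as convergence
  of the transverse dynamics, not as an identity.

## Spike, burst and ISI conventions

Spikes are upward crossings of −30 mV with re-arming below −40 mV
(hysteresis rejects subthreshold oscillations; bursting spikes in this
model family overshoot −30 mV comfortably); crossing times are linearly
interpolated. Bursts are split at interspike intervals exceeding the
largest multiplicative gap of the sorted ISIs (accepted only when the
gap ratio exceeds 4; otherwise the train is flagged tonic). "Period-k
bursting" means every post-transient burst carries exactly k spikes with
onset-to-onset intervals varying by < 5%. Quiescence means zero spikes
in the post-transient window.

## Synchronization measures

* **R** — Pearson correlation of the two sampled membrane potentials.
* **max(e)** — infinity norm of V₁−V₂ over the analysis window.
* **Poincaré phase** — events are burst onsets (first spike of each
  burst); φ interpolates 2πn linearly between consecutive events.
  Phase synchronization is declared when max|φ₁−φ₂| < 2π over the
  common event span.
* **Similarity function** — S²(τ) = ⟨(x(t+τ)−y(t))²⟩ / √(⟨x²⟩⟨y²⟩) on
  mean-subtracted signals over the overlapping window; S = √S² is
  reported (the squared variant is available by flag). S(τ*) = 0
  diagnoses lag synchronization with lag τ*; for independent
  equal-power signals S² → 2. Lag recovery minimizes S over a grid,
  ties broken toward zero lag.
* **Classification** — complete iff R > 0.999 and max(e) < 1 mV;
  approximate iff R > 0.95; phase iff max|Δφ| < 2π; lag iff
  min S < 0.05 at nonzero lag; otherwise asynchronous. An out-of-phase
  flag marks best alignment near half the burst period. The thresholds
  are package conventions chosen so the labelled reference runs
  (complete at g_c = −0.5, approximate at −0.24, asynchronous at −0.1)
  land in their classes.

## Stability analysis

Equilibria fix [Ca] at the ellipse center and solve the scalar voltage
balance with n = n∞(V), h = h∞(V) (dense sign-change sweep + Brent; the
equilibrium branch is the classical cubic with up to three roots). The
Jacobian, Hessians and third-derivative tensors of the somatic
right-hand side come from symbolic differentiation (sympy), with finite
differences only as a test cross-check — third-order finite differences
are far too noisy at the critical frequency ω ~ 2e−3 rad/ms.

The Hopf point is located by bisection on the real part of the complex
eigenvalue pair along the lower equilibrium branch. At the default
parameter set it sits at I_exc ≈ 11.489 with equilibrium
V ≈ −51.55 mV, ω ≈ 2.40e−3 rad/ms and real eigenvalue ≈ −0.841 /ms.
This is consistent with the bursting phenomenology: the ISI scan loses
all spikes between 11.0 and 11.5, i.e. exactly where the quiescent
state stabilizes.

The first Lyapunov coefficient is computed with the critical right
eigenvector normalized to first component 1 and the left eigenvector
satisfying Aᵀp = −iωp with ⟨p, q⟩ = Σ conj(p)q = 1. The reported l1 is
the invariant Kuznetsov expression including the center-manifold
correction terms −2⟨p,B(q,A⁻¹B(q,q̄))⟩ + ⟨p,B(q̄,(2iωI−A)⁻¹B(q,q))⟩; the
bare combination Re(i g₂₀g₁₁ + ω g₂₁)/(2ω²) is also exposed
(`l1_plain`), with a selectable left-vector normalization for
comparison with literature values computed without the unit pairing.
Both implementations are validated on the analytic normal-form oracles
ż = iωz ± z|z|² (sign and exact magnitude) and on coordinate-change
invariance. At this model's Hopf point l1 = +0.293 > 0: the bifurcation
is **subcritical**. Direct simulation confirms this — below the Hopf
point there is no small stable cycle (trajectories grow slowly at the
~1e−6/ms linear rate and escape to the large bursting attractor), and
just above it the large attractor coexists with the stable equilibrium
(hysteresis), the classic subcritical signature. Reports of a
supercritical direction for this model family rest on normal-form
tensors evaluated with the reversed τ̄ assignment, which is not
consistent with the eigenvalue data above.

## Maximal Lyapunov exponent

Benettin two-trajectory renormalization: defaults d₀ = 1e−6 mV,
renormalization every 50 ms, 4·10⁵ ms duration with the first 25%
discarded. For delayed runs the perturbation is applied uniformly to
the V₁ history and the separation norm runs over the 8-D state plus
both voltage history rings, renormalizing state and history together so
the perturbed trajectory remains a valid DDE initial segment. Reference
behaviors: quiescent somatic subsystem λ < 0; calcium rotation λ ≈ 0
(neutral); positively coupled pair with τ = 10 ms λ > 0 (delay-induced
chaos). The estimate is stable (±~30%) under halving d₀ and the
renormalization interval.

## Synthetic trace generator

Surrogate voltage pairs emulate exactly the features the metrics read:
a baseline, raised-cosine spikes (2 ms wide) in clusters of
`spikes_per_burst` at `intra_isi` spacing repeating every
`burst_period`, optional Gaussian white noise at sampling resolution,
and controllable structure between the pair: identical, lagged (second
trace delayed), phase-shifted, anti-phase (half-period lag), correlated
noise with exact target Pearson correlation (shared-component
construction y = ρx + √(1−ρ²)ε), or independent. They do not emulate
the neuron model's chaotic attractor statistics, spike-shape
variability, or slow drifts — passing the recovery tests therefore
demonstrates the metrics' correctness on signals with known ground
truth, not their robustness to every feature of real recordings.

## Known limitations

* Periodic-orbit continuation (folds of cycles, period doubling,
  homoclinic structure near the Hopf point) is out of scope; criticality
  is assessed by the normal form plus direct simulation.
* The two-neuron network is the largest configuration supported.
* Fixed-step integration only; no adaptive or stiff solvers.
* The reconstructed kinetics reproduce the published equilibrium
  voltage at the ~0.5% level and the Hopf eigenvalues at the 2–3%
  level; residual discrepancies trace to ambiguities in the published
  parameter table (duplicate slope entries, the τ̄ assignment) that are
  documented above.
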