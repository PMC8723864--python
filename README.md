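# pbcsync

Simulation and synchronization analysis of delay-coupled pre-Bötzinger
complex (PBC) bursting neurons.

The PBC is the brainstem kernel of the inspiratory respiratory rhythm; a
subset of its cells burst intrinsically through a persistent-sodium
(I_NaP) mechanism modulated by a calcium-activated nonspecific cation
(CAN) current. `pbcsync` implements a modified Toporikova–Butera
single-compartment burster in which the intracellular calcium drive
traces a prescribed ellipse, couples two such neurons electrically with
transmission delays, and provides the complete toolbox used to classify
their joint dynamics: interspike-interval (ISI) bifurcation scans,
correlation coefficient, maximum synchronization difference, Poincaré
phase synchronization, similarity-function lag analysis, maximal
Lyapunov exponents, and Hopf bifurcation direction via the first
Lyapunov coefficient.

## Model

Single neuron (state `V, n, h, Ca, l`):

    C_m dV/dt = −I_Na − I_NaP − I_CAN − I_K − I_L − I_exc
       dn/dt = (n∞(V) − n)/τ_n(V)
       dh/dt = (h∞(V) − h)/τ_h(V)
      dCa/dt = −ε d (l − l_c)
       dl/dt = (ε/d)(Ca − Ca_c)

with I_Na = g_Na m∞³(V)(1−n)(V−V_Na), I_NaP = g_NaP mp∞(V) h (V−V_Na),
I_CAN = g_CAN f(Ca)(V−V_Na) where f(Ca) = 1/(1+(K_CAN/Ca)^n_CAN),
I_K = g_K n⁴(V−V_K), I_L = g_L(V−V_L); gating steady states are
Boltzmann functions and time constants have the usual 1/cosh form.
The calcium pair (Ca, l) rotates on an ellipse centered at (Ca_c, l_c);
with the default center-fixed initial condition the CAN drive is a
constant conductance and the soma is a three-variable I_NaP burster.

Two neurons couple electrically and share one calcium subsystem; neuron
*i* receives `I_ci = g_c (V_j(t−τ_i) − V_i(t))`, subtracted on the
right-hand side. Negative `g_c` is the diffusive, synchronizing
direction in this sign convention.

## Worked example

```python
import numpy as np
import pbcsync as pb

p = pb.ModelParams.table1()

# single neuron: period-3 bursting at I_exc = 8.5
tr = pb.run_single(p, 8.5, 2e5).discard_transient()
bursts = pb.detect_bursts(pb.detect_spikes(tr))
print(np.unique(bursts.spikes_per_burst), round(bursts.period, 1))
# -> [3] 2439.3    (every steady-state burst has 3 spikes; cycle ~2.44 s)

# coupled identical pair in the complete-synchronization band
net = pb.NetworkConfig(g_c=-0.4, I_exc1=8.5, I_exc2=8.5)
pair = pb.run_pair(p, net, 2e5).discard_transient()
print(pb.correlation_coefficient(pair["V1"], pair["V2"]),
      pb.max_sync_difference(pair["V1"], pair["V2"]))
# -> 1.0 0.0      (complete synchronization: R = 1, max|V1 - V2| = 0)

# Hopf point terminating the bursting range
h = pb.normal_form_coeffs(pb.locate_hopf(p, (8.0, 13.0)), p)
print(round(h.I_exc_star, 3), round(h.eq3[0], 3), h.direction)
# -> 11.489 -51.55 subcritical
```

The first block shows the hallmark bursting rhythm (three spikes per
burst riding a slow I_NaP/h cycle); the second shows that moderate
negative electrical coupling synchronizes two identical bursters
exactly; the third locates the Hopf bifurcation of the quiescent state
that ends the bursting range near I_exc ≈ 11.5 (quiescence onset) and
reports its direction from the first Lyapunov coefficient.

A thin CLI mirrors these workflows:

```sh
pbc-sync scan-isi --start 8 --stop 12 --step 0.5
pbc-sync sweep --param g_c --start -0.5 --stop 0.5 --points 21
pbc-sync hopf
pbc-sync mle --g-c 0.4 --tau 10
```

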