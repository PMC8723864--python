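# Canonical biophysical parameter set for the modified Toporikova-Butera
# pre-Botzinger-complex burster (somatic subsystem + elliptic calcium drive).
# Note: tau_n_bar / tau_h_bar follow the canonical Butera assignment (fast n,
# slow NaP inactivation h), which is the assignment consistent with the
# model's linear-stability data; see docs/methods.md.
C_m: 21.0        # membrane capacitance
g_Na: 28.0       # nS, fast sodium
g_K: 11.2        # nS, delayed rectifier
g_L: 2.3         # nS, leak
g_NaP: 2.0       # nS, persistent sodium
g_CAN: 0.7       # nS, calcium-activated nonspecific cation
V_Na: 50.0       # mV
V_K: -85.0       # mV
V_L: -58.0       # mV
V_m: -34.0       # mV, fast-Na activation half-voltage
V_n: -29.0       # mV, K activation half-voltage
V_p: -40.0       # mV, persistent-Na activation half-voltage
V_h: -48.0       # mV, persistent-Na inactivation half-voltage
s_m: -5.0        # mV
s_n: -4.0        # mV
s_h: 5.0         # mV
s_mp: -6.0       # mV
tau_n_bar: 10.0      # ms, maximal K-gate time constant
tau_h_bar: 10000.0   # ms, maximal NaP-inactivation time constant
n_CAN: 0.97      # Hill exponent of CAN calcium activation
K_CAN: 0.74      # uM, CAN half-activation calcium
eps: 0.09        # 1/ms, calcium-ellipse angular speed
d: 0.5           # ellipse aspect ratio
Ca_c: 0.1        # uM, ellipse center calcium
l_c: 0.9         # ellipse center IP3 fraction
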