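# Eight-population cortical microcircuit parameterization (transcribed from
# the published model description; see README).  Loaded by the
# `microcircuit8` model flavor: the signed weight matrix is derived from the
# post-synaptic current amplitude w, the ratio g, and tau_s/C; in-degrees
# are derived from the pairwise connection probabilities under the
# fixed-total-number connectivity rule.
flavor: microcircuit8

populations: [2/3E, 2/3I, 4E, 4I, 5E, 5I, 6E, 6I]
N: [20683, 5834, 21915, 5479, 4850, 1065, 14395, 2948]

C: {val: 250, unit: pF}
tau_m: {val: 10, unit: ms}
tau_s: {val: 0.5, unit: ms}
tau_r: {val: 2, unit: ms}
E_L: {val: -65, unit: mV}
V_th_abs: {val: -50, unit: mV}
V_0_abs: {val: -65, unit: mV}

w: {val: 87.8, unit: pA}
w_ext: {val: 87.8, unit: pA}
g: 4
# the 4E -> 2/3E projection carries twice the reference weight
weight_scale:
  - [0, 2, 2.0]

conn_probs:
  - [0.1009, 0.1689, 0.0437, 0.0818, 0.0323, 0.0,    0.0076, 0.0]
  - [0.1346, 0.1371, 0.0316, 0.0515, 0.0755, 0.0,    0.0042, 0.0]
  - [0.0077, 0.0059, 0.0497, 0.1350, 0.0067, 0.0003, 0.0453, 0.0]
  - [0.0691, 0.0029, 0.0794, 0.1597, 0.0033, 0.0,    0.1057, 0.0]
  - [0.1004, 0.0622, 0.0505, 0.0057, 0.0831, 0.3726, 0.0204, 0.0]
  - [0.0548, 0.0269, 0.0257, 0.0022, 0.0600, 0.3158, 0.0086, 0.0]
  - [0.0156, 0.0066, 0.0211, 0.0166, 0.0572, 0.0197, 0.0396, 0.2252]
  - [0.0364, 0.0010, 0.0034, 0.0005, 0.0277, 0.0080, 0.0658, 0.1443]

K_ext: [1600, 1500, 2100, 1900, 2000, 1900, 2900, 2100]
nu_ext: {val: 8, unit: Hz}

d_e: {val: 1.5, unit: ms}
d_i: {val: 0.75, unit: ms}
d_e_sd: {val: 0.75, unit: ms}
d_i_sd: {val: 0.375, unit: ms}
delay_dist: truncated_gaussian
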