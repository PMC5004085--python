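# Surrogate two-cell model: a minimal conductance-based bursting cell
# (fast Na / delayed-rectifier K spiking core, slowly inactivating
# persistent Na as burst driver, leak) extended with an h-like
# hyperpolarization-activated current, a slow low-threshold inward (CaS-like)
# current, a slow persistent K (K2-like) current, and graded plus
# spike-mediated inhibitory synapses.  All kinetics are stated here; the
# engine hard-codes nothing.
#
# Sigmoid convention: x_inf(V) = 1 / (1 + exp((V - vhalf)/k)); k < 0 means
# the gate opens with depolarization.  tau forms: constant, or
# bell: base + amp / cosh((V - vhalf)/width).  Units: mV, nS, pF, ms.
name: surrogate-hco-v1
capacitance_pF: 21.0
init_v_mV: [-45.0, -65.0]
currents:
  - name: Na
    conductance_nS: 28.0
    reversal_mV: 50.0
    gates:
      - {power: 3, vhalf_mV: -34.0, k_mV: -5.0, instantaneous: true}
      - power: 1
        vhalf_mV: -29.0
        k_mV: 4.0
        tau: {form: bell, base_ms: 0.2, amp_ms: 10.0, vhalf_mV: -29.0, width_mV: 8.0}
  - name: K1
    conductance_nS: 11.2
    reversal_mV: -85.0
    gates:
      - power: 4
        vhalf_mV: -29.0
        k_mV: -4.0
        tau: {form: bell, base_ms: 0.2, amp_ms: 10.0, vhalf_mV: -29.0, width_mV: 8.0}
  - name: P
    conductance_nS: 2.8
    reversal_mV: 50.0
    scale: x_P
    gates:
      - {power: 1, vhalf_mV: -40.0, k_mV: -6.0, instantaneous: true}
      - power: 1
        vhalf_mV: -48.0
        k_mV: 6.0
        tau: {form: bell, base_ms: 100.0, amp_ms: 10000.0, vhalf_mV: -48.0, width_mV: 12.0}
  - name: K2
    conductance_nS: 1.0
    reversal_mV: -85.0
    scale: x_K2
    gates:
      - power: 1
        vhalf_mV: -40.0
        k_mV: -5.0
        tau: {form: constant, base_ms: 1500.0}
  - name: CaS
    conductance_nS: 0.3
    reversal_mV: 80.0
    scale: x_CaS
    gates:
      - power: 1
        vhalf_mV: -50.0
        k_mV: -4.0
        tau: {form: constant, base_ms: 200.0}
      - power: 1
        vhalf_mV: -55.0
        k_mV: 4.0
        tau: {form: constant, base_ms: 1500.0}
  - name: h
    conductance_nS: 1.5
    reversal_mV: -21.0
    scale: x_h
    gates:
      - power: 1
        vhalf_mV: -70.0
        k_mV: 5.0
        tau: {form: constant, base_ms: 1000.0}
  - name: Leak
    conductance_nS: 2.8
    reversal_param: e_leak
    scale: x_Leak
synapses:
  - name: SynS
    kind: spike_mediated
    conductance_nS: 6.0
    reversal_mV: -80.0
    scale: x_SynS
    threshold_mV: -20.0
    rise_ms: 1.0
    decay_ms: 150.0
  - name: SynG
    kind: graded
    conductance_nS: 1.0
    reversal_mV: -80.0
    scale: x_SynG
    vhalf_mV: -48.0
    k_mV: -2.0
    tau_ms: 150.0
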