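# Two-compartment model of the LP (lateral pyloric) neuron: a soma/neurite
# compartment carrying the slow currents and the modulator-activated currents,
# and an axon compartment carrying the spike generator, coupled by a fixed
# conductance and driven by periodic triangular synaptic inhibition.
#
# Conductances are densities (uS/mm^2); capacitances uF/cm^2; voltages mV;
# time constants ms; concentrations mM. The modulator-current gating here is
# the space-clamp-shifted parameterization (receptors sit electrotonically
# distal to the soma): every I_MI_T gating scale is 2.5x narrower and the
# half-voltages are shifted relative to the clamp-model parameterization.
model:
  kind: neuron
  coupling_us: 0.15
  v_init_mv: -55.0
  compartments:
    soma_neurite:
      diameter_um: 200.0
      length_um: 200.0
      cm_uf_per_cm2: 3.183
    axon:
      diameter_um: 200.0
      length_um: 200.0
      cm_uf_per_cm2: 0.795
  channels:
    - name: I_leak_s
      compartment: soma_neurite
      gbar_us_per_mm2: 0.795
      e_rev_mv: -55.0
      a: 1
      b: 0
    - name: I_A
      compartment: soma_neurite
      gbar_us_per_mm2: 0.059
      e_rev_mv: -80.0
      a: 2
      b: 1
      m_inf: {form: logistic, v_half: -54.0, k: 10.0}
      tau_m: {base: 15.0}
      h_inf: {form: logistic, v_half: -60.0, k: -5.0}
      tau_h: {base: 100.0}
    - name: I_h
      compartment: soma_neurite
      gbar_us_per_mm2: 0.318
      e_rev_mv: -10.0
      a: 2
      b: 0
      # hyperpolarization-activated: positive part of a falling tanh
      m_inf: {form: tanh_plus, v_half: -58.0, k: -10.0}
      tau_m: {base: 200.0}
    - name: I_Ca
      compartment: soma_neurite
      ghk: true
      ca_permeable: true
      gbar_us_per_mm2: 0.0
      e_rev_mv: 0.0
      a: 2
      b: 1
      m_inf: {form: logistic, v_half: -45.0, k: 15.0}
      tau_m: {base: 2.0, log_amp: 2.0, log_v0: -40.0, log_scale: 20.0}
      # calcium-dependent inactivation, S(-([Ca]-12.5)/7); nearly constant
      # over the model's working calcium range
      h_inf: {form: logistic, depends: ca, v_half: 12.5, k: -7.0}
      tau_h: {base: 100.0}
    - name: I_KCa
      compartment: soma_neurite
      gbar_us_per_mm2: 0.159
      e_rev_mv: -80.0
      a: 1
      b: 1
      # S((v+45.5)/2) * [Ca]/([Ca] + 0.00715)
      m_inf: {form: logistic, v_half: -45.5, k: 2.0, ca_gain_kd: 0.00715}
      tau_m: {base: 100.0}
      # calcium-activated: 1/(1+(0.03/[Ca])^1.25), rises with [Ca] -- the
      # gate that lets calcium entry terminate the burst
      h_inf: {form: hill, ca_half: 0.03, hill: -1.25}
      tau_h: {base: 10.0}
    - name: I_MI
      compartment: soma_neurite
      gbar_us_per_mm2: 0.283
      e_rev_mv: -10.0
      a: 1
      b: 0
      m_inf: {form: logistic, v_half: -19.0, k: 18.0}
      tau_m: {base: 2.0}
    - name: I_MI_T
      compartment: soma_neurite
      gbar_us_per_mm2: 2.83
      e_rev_mv: -16.0
      a: 3
      b: 1
      m_inf: {form: logistic, v_half: -52.5, k: 4.8}
      tau_m: {base: 2.0, sech_amp: 150.0, sech_v0: -56.0, sech_scale: 1.6}
      # rectified: [S(-(v+61)/2.8) - 0.1]+
      h_inf: {form: logistic, v_half: -61.0, k: -2.8, floor_offset: 0.1}
      # 100 + 600*sech(0.25(v+60)) + 200*S(0.5(v+60))
      tau_h:
        base: 100.0
        sech_amp: 600.0
        sech_v0: -60.0
        sech_scale: 4.0
        log_amp: 200.0
        log_v0: -60.0
        log_scale: 2.0
    - name: I_leak_a
      compartment: axon
      gbar_us_per_mm2: 0.199
      e_rev_mv: -55.0
      a: 1
      b: 0
    - name: I_Na
      compartment: axon
      gbar_us_per_mm2: 59.68
      e_rev_mv: 50.0
      a: 3
      b: 1
      m_inf: {form: logistic, v_half: -18.0, k: 12.25}
      tau_m: {base: 2.0}
      h_inf: {form: logistic, v_half: -28.0, k: -7.7}
      tau_h: {base: 5.0}
    - name: I_K
      compartment: axon
      gbar_us_per_mm2: 17.9
      e_rev_mv: -80.0
      a: 4
      b: 0
      m_inf: {form: logistic, v_half: -23.0, k: 5.0}
      tau_m: {base: 2.0, log_amp: 14.0, log_v0: -23.0, log_scale: -5.0}
  ghk:
    p_ca: 0.00187
    p_unit: nm/ms
    z: 2
    temperature_k: 283.15
    ca_out_mm: 13.0
    prefactor: zf_zeta   # conventional z*F*zeta form
  calcium_pool:
    ca_inf_mm: 0.02
    tau_ca_ms: 12000.0
    vol_um3: 6.49
    p1_um3_per_s: 1.168
    p_total: 0.0467
    p_total_unit: nm/ms
    floor_mm: 1.0e-06
    # dimensionless calibration of the microdomain flux coefficient (see
    # methods note): sets burst-driven calcium excursions onto the working
    # range of the calcium-dependent gates (ca_half 0.015-0.03 mM)
    flux_scale: 0.045
  synapse:
    gmax_us_per_mm2: 1.0
    e_rev_mv: -80.0
    duty: 0.5
  # modulator-conductance overrides (uS/mm^2) for the comparison models,
  # spike-matched at 1 Hz drive (to within one spike in this reconstruction).
  variants:
    mi_plus_mit_ca: {g_mi: 0.227, g_mit: 2.27, mit_ca_permeable: true}
    mi_plus_mit_noca: {g_mi: 0.227, g_mit: 2.27, mit_ca_permeable: false}
    mi_only: {g_mi: 0.995, g_mit: 0.0, mit_ca_permeable: true}
    mit_ca_only: {g_mi: 0.0, g_mit: 3.63, mit_ca_permeable: true}
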