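# Clamp model of the modulator-activated difference current: a fast
# persistent inward current (I_MI) plus a transient, inactivating inward
# current (I_MI_T). Conductances are absolute (nS); voltages in mV; time
# constants in ms; concentrations in mM.
#
# Gating expressions are parameterized as data so that any alternative
# reading of the published typeset fractions is a config edit, not a code
# change. Sigmoids are S((v - v_half)/k); time constants are
# base + sech_amp*sech((v-sech_v0)/sech_scale) + log_amp*S((v-log_v0)/log_scale).
model:
  kind: clamp
  mi_t_mode: ohmic          # "ohmic" or "ghk_ca"
  channels:
    - name: I_MI
      gbar_ns: 0.125
      e_rev_mv: 35.0
      a: 1
      b: 0
      m_inf: {form: logistic, v_half: -19.0, k: 18.0}
      tau_m: {base: 2.0}
    - name: I_MI_T
      gbar_ns: 1.0
      e_rev_mv: 24.0
      a: 3
      b: 1
      m_inf: {form: logistic, v_half: -11.8, k: 12.0}
      # slow activation inside the slow-wave voltage range, fast outside:
      # 2 + 150*sech((v+20)/4)
      tau_m: {base: 2.0, sech_amp: 150.0, sech_v0: -20.0, sech_scale: 4.0}
      h_inf: {form: logistic, v_half: -40.0, k: -7.0}
      # 100 + 600*sech(0.1(v+30)) + 200*S(0.2(v+30))
      tau_h:
        base: 100.0
        sech_amp: 600.0
        sech_v0: -30.0
        sech_scale: 10.0
        log_amp: 200.0
        log_v0: -30.0
        log_scale: 5.0
  # GHK calcium parameterization of I_MI_T (used when mi_t_mode == ghk_ca).
  ghk:
    p_ca: 0.014
    p_unit: cm/s
    z: 2
    temperature_k: 283.15
    ca_out_mm: 13.0
    prefactor: f_zeta        # printed form; "zf_zeta" for the conventional one
    # Effective cluster-membrane area converting flux density to a total
    # current. Amplitude normalization: chosen so the GHK variant's
    # initial-sweep peak matches the ohmic variant under the 400 mV/s
    # ramp-and-hold protocol.
    area_um2: 562.0
    # instantaneous calcium-dependent inactivation h_inf([Ca]) = 1/(1+([Ca]/0.015)^4)
    ca_h_inf: {ca_half: 0.015, hill: 4.0}
  calcium_pool:
    ca_inf_mm: 0.02
    tau_ca_ms: 12000.0
    vol_um3: 6.49
    p1_um3_per_s: 1.1675
    p_total: 0.0369
    p_total_unit: cm/s
    floor_mm: 1.0e-06
    # dimensionless calibration of the microdomain flux coefficient: puts the
    # calcium accumulation on a multi-second timescale (slow relative to one
    # stimulus cycle) so the repeated-stimulus decay rides on the pool's
    # intrinsic 12 s clearance
    flux_scale: 0.1
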