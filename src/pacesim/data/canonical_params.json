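{
  "G_Leak": 0.0541188,
  "G_Ca": 0.15,
  "G_Na": 3.19392269,
  "G_K": 3.1773795,
  "E_Leak": -70.0,
  "E_Ca": 100.0,
  "E_Na": 58.0,
  "E_K": -88.0,
  "b_half_voltage": -45.0,
  "b_slope": 6.0,
  "b_tau_base": 0.3,
  "b_tau_amp": 0.3,
  "b_tau_vmid": -55.0,
  "b_tau_width": 20.0,
  "g_half_voltage": -45.0,
  "g_slope": -8.0,
  "g_tau_base": 2.0,
  "g_tau_amp": 2.0,
  "g_tau_vmid": -60.0,
  "g_tau_width": 20.0,
  "m_half_voltage": -52.00918376,
  "m_slope": 5.0,
  "m_tau_base": 0.02,
  "m_tau_amp": 0.05,
  "m_tau_vmid": -55.0,
  "m_tau_width": 15.0,
  "h_half_voltage": -57.97960759,
  "h_slope": -5.0,
  "h_tau_base": 0.41929025600000003,
  "h_tau_amp": 1.04822564,
  "h_tau_vmid": -60.0,
  "h_tau_width": 15.0,
  "n_half_voltage": -54.97960759,
  "n_slope": 8.0,
  "n_tau_base": 0.17017764800000001,
  "n_tau_amp": 0.42544412,
  "n_tau_vmid": -60.0,
  "n_tau_width": 20.0,
  "q_half_voltage": -20.0,
  "q_slope": -8.0,
  "q_tau_base": 2.0,
  "q_tau_amp": 2.0,
  "q_tau_vmid": -60.0,
  "q_tau_width": 20.0
}
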