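{
  "capacity2": {
    "exc": {
      "membrane_capacitance": 0.5,
      "leak_conductance": 25.0,
      "leak_reversal": -70.0,
      "spike_threshold": -50.0,
      "reset_potential": -60.0,
      "refractory_period": 2.0
    },
    "inh": {
      "membrane_capacitance": 0.2,
      "leak_conductance": 20.0,
      "leak_reversal": -70.0,
      "spike_threshold": -50.0,
      "reset_potential": -60.0,
      "refractory_period": 1.0
    },
    "synapses": {
      "tau_ampa": 2.0,
      "tau_gaba": 10.0,
      "tau_nmda_decay": 100.0,
      "tau_nmda_rise": 2.0,
      "nmda_saturation_rate": 0.5,
      "mg_concentration": 1.0,
      "exc_reversal": 0.0,
      "inh_reversal": -70.0
    },
    "topology": {
      "n_exc": 2048,
      "n_inh": 512,
      "j_plus_ee": 10.0,
      "sigma_ee": 9.0,
      "j_plus_ei": 2.4,
      "j_plus_ie": 2.4,
      "sigma_ei": 18.0,
      "sigma_ie": 18.0
    },
    "conductances": {
      "g_ee_ampa": 0.09,
      "g_ei_ampa": 0.256,
      "g_ee_nmda": 0.24,
      "g_ei_nmda": 0.11,
      "g_ii_gaba": 2.0,
      "g_ie_gaba": 3.0,
      "g_ext_e": 3.5,
      "g_ext_i": 2.74,
      "g_ee_ampa_across": 0.45,
      "g_ei_ampa_across": 0.18,
      "g_ee_nmda_across": 0.0,
      "g_ei_nmda_across": 0.0
    },
    "scale_factor": 1.0,
    "capacity_profile": "capacity2",
    "networks": [
      "color",
      "location"
    ]
  },
  "capacity3": {
    "exc": {
      "membrane_capacitance": 0.5,
      "leak_conductance": 25.0,
      "leak_reversal": -70.0,
      "spike_threshold": -50.0,
      "reset_potential": -60.0,
      "refractory_period": 2.0
    },
    "inh": {
      "membrane_capacitance": 0.2,
      "leak_conductance": 20.0,
      "leak_reversal": -70.0,
      "spike_threshold": -50.0,
      "reset_potential": -60.0,
      "refractory_period": 1.0
    },
    "synapses": {
      "tau_ampa": 2.0,
      "tau_gaba": 10.0,
      "tau_nmda_decay": 100.0,
      "tau_nmda_rise": 2.0,
      "nmda_saturation_rate": 0.5,
      "mg_concentration": 1.0,
      "exc_reversal": 0.0,
      "inh_reversal": -70.0
    },
    "topology": {
      "n_exc": 2048,
      "n_inh": 512,
      "j_plus_ee": 11.0,
      "sigma_ee": 9.0,
      "j_plus_ei": 2.6,
      "j_plus_ie": 2.6,
      "sigma_ei": 30.0,
      "sigma_ie": 30.0
    },
    "conductances": {
      "g_ee_ampa": 0.126,
      "g_ei_ampa": 0.256,
      "g_ee_nmda": 0.2,
      "g_ei_nmda": 0.11,
      "g_ii_gaba": 2.0,
      "g_ie_gaba": 3.0,
      "g_ext_e": 3.58,
      "g_ext_i": 2.8,
      "g_ee_ampa_across": 0.45,
      "g_ei_ampa_across": 0.18,
      "g_ee_nmda_across": 0.0,
      "g_ei_nmda_across": 0.0
    },
    "scale_factor": 1.0,
    "capacity_profile": "capacity3",
    "networks": [
      "color",
      "location"
    ]
  }
}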