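{
  "michaelis_menten": {
    "description": "Saturable boric acid dose-response of the transporter at Vh = +60 mV, pH 7.5.",
    "doses_mM": [1, 3, 5, 10, 20],
    "K_m_mM": {"mean": 6.5, "se": 0.6},
    "I_max_uA": {"mean": 1.5, "se": 0.05}
  },
  "nmdg_inhibition": {
    "description": "Single-site inhibition of the 20 mM boric acid current by NMDG at Vh = +60 mV.",
    "doses_mM": [0, 40, 80, 96],
    "ic50_mM": 67
  },
  "worked_example": {
    "description": "Compartment states of the thermodynamic worked example: an oocyte a few minutes into 20 mM boric acid exposure.",
    "inside": {"total_mM": 1.4, "pH": 7.1},
    "outside": {"total_mM": 20.0, "pH": 7.5},
    "temperature_K": 291.15,
    "printed": {
      "b_oh3_out_mM": 19.6,
      "b_oh4_out_mM": 0.4,
      "b_oh3_in_mM": 1.39,
      "b_oh4_in_mM": 0.01,
      "concentration_ratio": 0.03,
      "equilibrium_potential_mV": -89
    }
  }
}
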