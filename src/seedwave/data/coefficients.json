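{
  "description": "Published optimal coefficients of the loss-factor and effective moisture diffusivity models for red lentil under six microwave drying treatments (2 nominal powers x 3 tempering moistures), plus the printed Average and Standard Deviation rows.",
  "loss_factor": {
    "columns": ["g0", "g1", "g2", "g3", "g4", "g5", "g6", "g7"],
    "treatments": {
      "0.70kW-20": {"power_kW": 0.70, "imc_db": 0.20, "g0": 2.100, "g1": -0.111, "g2": 2.81e-04, "g3": -1.37e-03, "g4": 1.00e-03, "g5": 2.966, "g6": -1.670, "g7": 0.0461},
      "0.70kW-35": {"power_kW": 0.70, "imc_db": 0.35, "g0": 2.100, "g1": -0.100, "g2": 4.62e-04, "g3": -1.00e-02, "g4": 9.34e-04, "g5": 2.964, "g6": -1.674, "g7": 0.0329},
      "0.70kW-50": {"power_kW": 0.70, "imc_db": 0.50, "g0": 2.119, "g1": -0.040, "g2": 5.07e-05, "g3": -1.99e-02, "g4": 4.58e-04, "g5": 2.853, "g6": -1.709, "g7": 0.0300},
      "0.35kW-20": {"power_kW": 0.35, "imc_db": 0.20, "g0": 2.100, "g1": -0.151, "g2": 1.01e-04, "g3": -1.00e-02, "g4": 1.00e-05, "g5": 2.686, "g6": -1.264, "g7": 0.0700},
      "0.35kW-35": {"power_kW": 0.35, "imc_db": 0.35, "g0": 2.160, "g1": -0.112, "g2": 5.00e-05, "g3": -1.00e-04, "g4": 5.93e-05, "g5": 2.820, "g6": -1.476, "g7": 0.0580},
      "0.35kW-50": {"power_kW": 0.35, "imc_db": 0.50, "g0": 2.161, "g1": -0.100, "g2": 6.02e-05, "g3": -1.00e-02, "g4": 5.88e-04, "g5": 2.964, "g6": -1.602, "g7": 0.0506}
    },
    "average": {"g0": 2.123, "g1": -0.102, "g2": 1.68e-04, "g3": -8.56e-03, "g4": 5.08e-04, "g5": 2.876, "g6": -1.566, "g7": 0.0479},
    "std": {"g0": 0.030, "g1": 0.036, "g2": 1.69e-04, "g3": 7.17e-03, "g4": 4.20e-04, "g5": 0.113, "g6": 0.169, "g7": 0.0151}
  },
  "diffusivity": {
    "columns": ["D0", "Ea", "a0", "a1"],
    "treatments": {
      "0.70kW-20": {"power_kW": 0.70, "imc_db": 0.20, "D0": 3.56e-03, "Ea": 30.315, "a0": 1.00e-06, "a1": 0.397},
      "0.70kW-35": {"power_kW": 0.70, "imc_db": 0.35, "D0": 3.46e-03, "Ea": 30.314, "a0": 1.00e-06, "a1": 0.397},
      "0.70kW-50": {"power_kW": 0.70, "imc_db": 0.50, "D0": 2.36e-03, "Ea": 29.026, "a0": 1.00e-06, "a1": 0.500},
      "0.35kW-20": {"power_kW": 0.35, "imc_db": 0.20, "D0": 1.32e-03, "Ea": 29.000, "a0": 1.00e-03, "a1": 0.300},
      "0.35kW-35": {"power_kW": 0.35, "imc_db": 0.35, "D0": 2.45e-03, "Ea": 30.300, "a0": 1.00e-03, "a1": 0.300},
      "0.35kW-50": {"power_kW": 0.35, "imc_db": 0.50, "D0": 1.48e-03, "Ea": 29.011, "a0": 1.00e-03, "a1": 0.300}
    },
    "average": {"D0": 2.44e-03, "Ea": 29.66, "a0": 5.01e-04, "a1": 0.366},
    "std": {"D0": 9.45e-04, "Ea": 0.71, "a0": 5.47e-04, "a1": 0.081}
  },
  "biot": {
    "heat": {"0.70kW-20": 0.043, "0.70kW-35": 0.043, "0.70kW-50": 0.038, "0.35kW-20": 0.043, "0.35kW-35": 0.043, "0.35kW-50": 0.043},
    "mass": {"0.70kW-20": 0.015, "0.70kW-35": 0.015, "0.70kW-50": 0.016, "0.35kW-20": 0.015, "0.35kW-35": 0.015, "0.35kW-50": 0.016}
  },
  "source_power": {
    "0.70": {"pav_watts": 616.0, "s11": 0.421},
    "0.35": {"pav_watts": 308.0, "s11": 0.694}
  }
}
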