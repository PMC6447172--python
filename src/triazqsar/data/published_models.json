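{
  "model_1": {
    "system": "S2",
    "intercept": 23.68,
    "coefficients": {
      "ES_Count_sssCH": 0.985,
      "Mulliken_Charge_C4": -64.66,
      "Solvation_E": 0.056
    }
  },
  "model_2": {
    "system": "S2",
    "intercept": 12.43,
    "coefficients": {
      "ES_Sum_sssCH": 4.393,
      "Jurs_FPSA_3": -107.3
    }
  },
  "model_3": {
    "system": "S2",
    "intercept": 11.92,
    "coefficients": {
      "CHI_2": -0.910,
      "CHI_V_2": 1.932,
      "Jurs_FPSA_3": -100.3
    }
  },
  "model_4": {
    "system": "S2",
    "intercept": 8.807,
    "coefficients": {
      "ES_Sum_sssCH": 5.366,
      "IC2": 0.828,
      "Jurs_FPSA_3": -104.0
    }
  },
  "model_5": {
    "system": "S2",
    "intercept": 6.302,
    "coefficients": {
      "ES_Sum_sssCH": 6.182,
      "IC2": 0.946,
      "Solvation_E": 0.062
    }
  },
  "model_6": {
    "system": "K4E7",
    "intercept": 7.142,
    "coefficients": {
      "Mor21v": -9.584,
      "NPlusO_Count": -0.561,
      "R6m_plus": 33.83
    }
  },
  "model_7": {
    "system": "K4E7",
    "intercept": 5.859,
    "coefficients": {
      "Jurs_TPSA": -0.018,
      "Mor21v": -7.118,
      "R6m_plus": 27.20
    }
  },
  "model_8": {
    "system": "K4E7",
    "intercept": -3.941,
    "coefficients": {
      "ES_Count_sssCH": 1.291,
      "IC2": 5.271,
      "Jurs_DPSA_3": -0.216
    }
  },
  "model_9": {
    "system": "K4E7",
    "intercept": 7.173,
    "coefficients": {
      "Mor21v": -8.061,
      "TPSA_NO": -0.0385,
      "R6m_plus": 34.56
    }
  },
  "model_10": {
    "system": "K4E7",
    "intercept": 7.369,
    "coefficients": {
      "ES_Count_sssCH": 1.637,
      "ES_Sum_sCl": 0.287,
      "Num_H_Donors_Lipinski": -0.791
    }
  }
}
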