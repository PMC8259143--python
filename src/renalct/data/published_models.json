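{
  "version": "1.0",
  "description": "Published per-phase logistic models differentiating ccRCC (coded 1) from AML.wovf (coded 0). Coding: male=1/female=0; morphology flag present=1. printed_odds_ratios and printed_or_ci are retained verbatim for consistency checks; the NP odds-ratio column is internally inconsistent with its coefficients (its CIs side with the coefficients).",
  "positive_class": "ccRCC",
  "threshold": 0.5,
  "coding": {
    "gender": {"male": 1, "female": 0},
    "pseudocapsule": {"present": 1, "absent": 0},
    "cystic": {"present": 1, "absent": 0},
    "angular": {"present": 1, "absent": 0}
  },
  "models": {
    "PCP": {
      "intercept": 5.257,
      "coefficients": {
        "gender": 3.137,
        "pseudocapsule": 2.549,
        "angular": 2.155,
        "AVT_PCP_1": -0.215
      },
      "printed_odds_ratios": {
        "gender": 23.028,
        "pseudocapsule": 12.801,
        "angular": 8.628,
        "AVT_PCP_1": 0.806
      },
      "printed_or_ci": {
        "gender": [4.892, 108.408],
        "pseudocapsule": [1.453, 112.806],
        "angular": [1.956, 38.059],
        "AVT_PCP_1": [0.720, 0.903]
      }
    },
    "CMP": {
      "intercept": -35.318,
      "coefficients": {
        "gender": 6.796,
        "cystic": 3.361,
        "RER_CMP_2": 0.185,
        "SHR_CMP": 0.038
      },
      "printed_odds_ratios": {
        "gender": 894.054,
        "cystic": 28.816,
        "RER_CMP_2": 1.203,
        "SHR_CMP": 1.039
      },
      "printed_or_ci": {
        "gender": [11.272, 70915.930],
        "cystic": [1.803, 460.581],
        "RER_CMP_2": [1.075, 1.347],
        "SHR_CMP": [1.011, 1.066]
      }
    },
    "NP": {
      "intercept": -17.114,
      "coefficients": {
        "gender": 2.203,
        "pseudocapsule": 2.038,
        "RER_NP_2": 0.157,
        "HDT_NP": 0.195
      },
      "printed_odds_ratios": {
        "gender": 7.403,
        "pseudocapsule": 11.703,
        "RER_NP_2": 1.177,
        "HDT_NP": 1.345
      },
      "printed_or_ci": {
        "gender": [2.326, 35.233],
        "pseudocapsule": [0.981, 75.477],
        "RER_NP_2": [1.081, 1.266],
        "HDT_NP": [1.052, 1.405]
      }
    },
    "EP": {
      "intercept": -12.019,
      "coefficients": {
        "gender": 2.773,
        "angular": 2.059,
        "RER_EP_2": 0.088,
        "SHR_EP": 1.788
      },
      "printed_odds_ratios": {
        "gender": 16.005,
        "angular": 7.840,
        "RER_EP_2": 1.092,
        "SHR_EP": 5.978
      },
      "printed_or_ci": {
        "gender": [4.033, 65.523],
        "angular": [1.883, 32.643],
        "RER_EP_2": [1.027, 1.162],
        "SHR_EP": [2.066, 17.292]
      }
    }
  }
}
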