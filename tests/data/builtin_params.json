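{
  "cohort": {
    "age_mean": 46.0,
    "age_sd": 8.5,
    "baseline_nrs": 8,
    "months_since_injury_mean": 68.0,
    "months_since_injury_sd": 37.7,
    "n": 1000,
    "percent_male": 66.0
  },
  "long_term_costs_annual": {
    "healthcare": {
      "mild": 2000.0,
      "moderate": 4500.0,
      "severe": 9000.0
    },
    "productivity": {
      "mild": 2500.0,
      "moderate": 6000.0,
      "severe": 11500.0
    },
    "sd_fraction": 0.2
  },
  "patients_per_year": 20.0,
  "productivity": {
    "average_hourly_wage": 29.75,
    "minimum_hourly_wage": 14.25,
    "paid_hours_per_month": {
      "mild": 8.0,
      "moderate": 18.0,
      "severe": 30.0
    },
    "unpaid_hours_per_month": {
      "mild": 5.0,
      "moderate": 12.0,
      "severe": 20.0
    }
  },
  "states": [
    "mild",
    "moderate",
    "severe"
  ],
  "strategies": {
    "standard_care": {
      "intervention_cost_components": [],
      "transitions": {
        "induction": {
          "means": {
            "mild": [
              1.0,
              0.0,
              0.0
            ],
            "moderate": [
              0.0,
              1.0,
              0.0
            ],
            "severe": [
              0.0,
              0.0,
              1.0
            ]
          },
          "row_sds": {
            "mild": 0.0,
            "moderate": 0.0,
            "severe": 0.0
          }
        },
        "maintenance": {
          "means": {
            "mild": [
              1.0,
              0.0,
              0.0
            ],
            "moderate": [
              0.0,
              1.0,
              0.0
            ],
            "severe": [
              0.0,
              0.0,
              1.0
            ]
          },
          "row_sds": {
            "mild": 0.0,
            "moderate": 0.0,
            "severe": 0.0
          }
        }
      }
    },
    "tdcs": {
      "intervention_cost_components": [
        {
          "dist": "gamma",
          "mean": 70.0,
          "name": "tDCS equipment",
          "sd": 5.0
        },
        {
          "dist": "fixed",
          "mean": 1228.0,
          "name": "Physician",
          "sd": null
        },
        {
          "dist": "fixed",
          "mean": 370.23,
          "name": "Nurse",
          "sd": null
        },
        {
          "dist": "gamma",
          "mean": 91.83,
          "name": "Drugs",
          "sd": 95.0
        }
      ],
      "transitions": {
        "induction": {
          "means": {
            "mild": [
              1.0,
              0.0,
              0.0
            ],
            "moderate": [
              0.0,
              1.0,
              0.0
            ],
            "severe": [
              0.1,
              0.5,
              0.4
            ]
          },
          "row_sds": {
            "mild": 0.0,
            "moderate": 0.0,
            "severe": 0.1
          }
        },
        "maintenance": {
          "means": {
            "mild": [
              0.5,
              0.5,
              0.0
            ],
            "moderate": [
              0.0,
              0.4,
              0.6
            ],
            "severe": [
              0.0,
              0.33,
              0.67
            ]
          },
          "row_sds": {
            "mild": 0.1,
            "moderate": 0.1,
            "severe": 0.1
          }
        }
      }
    },
    "vi_tdcs": {
      "intervention_cost_components": [
        {
          "dist": "gamma",
          "mean": 70.0,
          "name": "tDCS equipment",
          "sd": 5.0
        },
        {
          "dist": "fixed",
          "mean": 1228.0,
          "name": "Physician",
          "sd": null
        },
        {
          "dist": "fixed",
          "mean": 370.23,
          "name": "Nurse",
          "sd": null
        },
        {
          "dist": "gamma",
          "mean": 91.83,
          "name": "Drugs",
          "sd": 95.0
        },
        {
          "dist": "gamma",
          "mean": 8.0,
          "name": "Projector",
          "sd": 2.0
        },
        {
          "dist": "gamma",
          "mean": 1.9,
          "name": "Screen",
          "sd": 1.0
        },
        {
          "dist": "gamma",
          "mean": 30.0,
          "name": "Video",
          "sd": 8.0
        },
        {
          "dist": "gamma",
          "mean": 9.67,
          "name": "Portable computer",
          "sd": 3.0
        },
        {
          "dist": "gamma",
          "mean": 1.8,
          "name": "Vertical mirror",
          "sd": 1.0
        },
        {
          "dist": "gamma",
          "mean": 2.5,
          "name": "Loudspeakers",
          "sd": 1.0
        },
        {
          "dist": "fixed",
          "mean": 922.71,
          "name": "Physiotherapist",
          "sd": null
        }
      ],
      "transitions": {
        "induction": {
          "means": {
            "mild": [
              1.0,
              0.0,
              0.0
            ],
            "moderate": [
              0.0,
              1.0,
              0.0
            ],
            "severe": [
              0.19,
              0.63,
              0.19
            ]
          },
          "row_sds": {
            "mild": 0.0,
            "moderate": 0.0,
            "severe": 0.1
          }
        },
        "maintenance": {
          "means": {
            "mild": [
              0.95,
              0.05,
              0.0
            ],
            "moderate": [
              0.05,
              0.95,
              0.0
            ],
            "severe": [
              0.0,
              0.05,
              0.95
            ]
          },
          "row_sds": {
            "mild": 0.1,
            "moderate": 0.1,
            "severe": 0.1
          }
        }
      }
    }
  },
  "synthetic_fields": [
    "utilization",
    "productivity",
    "long_term"
  ],
  "uncertainty": {
    "drug_cost_sd_fraction": 0.3,
    "hours_sd_fraction": 0.25,
    "p_sd": 0.05,
    "unit_cost_sd_fraction": 0.15
  },
  "utilities": {
    "base": {
      "mild": {
        "mean": 0.77,
        "sd": 0.1
      },
      "moderate": {
        "mean": 0.63,
        "sd": 0.1
      },
      "severe": {
        "mean": 0.44,
        "sd": 0.1
      }
    },
    "dixon": {
      "mild": {
        "mean": 0.93,
        "sd": 0.1
      },
      "moderate": {
        "mean": 0.8,
        "sd": 0.1
      },
      "severe": {
        "mean": 0.34,
        "sd": 0.1
      }
    },
    "gordon": {
      "mild": {
        "mean": 0.71,
        "sd": 0.1
      },
      "moderate": {
        "mean": 0.47,
        "sd": 0.1
      },
      "severe": {
        "mean": 0.2,
        "sd": 0.1
      }
    }
  },
  "utilization": {
    "drug_cost_per_cycle": {
      "mild": 40.0,
      "moderate": 80.0,
      "severe": 120.0
    },
    "p_diagnostic_test": {
      "mild": 0.3,
      "moderate": 0.4,
      "severe": 0.5
    },
    "p_physician_visit": {
      "mild": 0.3,
      "moderate": 0.55,
      "severe": 0.85
    },
    "p_specialist_referral": {
      "mild": 0.1,
      "moderate": 0.25,
      "severe": 0.45
    },
    "test_rule": "additive",
    "unit_costs": {
      "diagnostic_test": 150.0,
      "physician_visit": 120.0,
      "specialist_visit": 200.0
    }
  }
}
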