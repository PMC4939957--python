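{
  "version": "1.0.0",
  "horizon_years": 7,
  "description": "Published sex-specific subdistribution hazard ratios and reference-profile (age 50-59, BMI 18.5-22.9, no clinical risk factors) 7-year absolute fracture risks of the Korean Fracture Risk Score.",
  "male": {
    "anchor_risk": 0.0214,
    "shr": {
      "age_60_69": 2.02,
      "age_70_79": 3.94,
      "age_80_89": 5.66,
      "bmi_lt_18_5": 1.65,
      "bmi_23_24_9": 0.82,
      "bmi_ge_25": 0.79,
      "recent_fracture": 3.53,
      "current_smoking": 1.08,
      "high_alcohol": 1.37,
      "weekly_exercise": 0.76,
      "recent_glucocorticoid": 1.87,
      "rheumatoid_arthritis": 1.29,
      "secondary_osteoporosis": 1.10
    }
  },
  "female": {
    "anchor_risk": 0.0749,
    "shr": {
      "age_60_69": 2.15,
      "age_70_79": 3.61,
      "age_80_89": 4.72,
      "bmi_lt_18_5": 1.12,
      "bmi_23_24_9": 0.95,
      "bmi_ge_25": 0.89,
      "recent_fracture": 1.83,
      "current_smoking": 1.15,
      "high_alcohol": 1.20,
      "weekly_exercise": 0.87,
      "recent_glucocorticoid": 1.51,
      "rheumatoid_arthritis": 1.06,
      "secondary_osteoporosis": 1.07
    }
  }
}
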