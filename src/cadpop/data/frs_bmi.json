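{
  "name": "frs_bmi",
  "description": "Sex-stratified general cardiovascular disease 10-year risk (office-based BMI model): published Cox proportional-hazards coefficients with ln BMI replacing the lipid terms; otherwise the same structure as the lipid model.",
  "sex": {
    "F": {
      "terms": [
        {"variable": "age", "transform": "ln", "beta": 2.72107},
        {"variable": "bmi", "transform": "ln", "beta": 0.51125},
        {"variable": "sbp", "transform": "ln", "beta": 2.81291, "condition": {"antihypertensive": false}},
        {"variable": "sbp", "transform": "ln", "beta": 2.88267, "condition": {"antihypertensive": true}},
        {"variable": "smoker", "beta": 0.61868},
        {"variable": "diabetic", "beta": 0.77763}
      ],
      "s0": 0.94833,
      "mean_lp": 26.0145
    },
    "M": {
      "terms": [
        {"variable": "age", "transform": "ln", "beta": 3.11296},
        {"variable": "bmi", "transform": "ln", "beta": 0.79277},
        {"variable": "sbp", "transform": "ln", "beta": 1.85508, "condition": {"antihypertensive": false}},
        {"variable": "sbp", "transform": "ln", "beta": 1.92672, "condition": {"antihypertensive": true}},
        {"variable": "smoker", "beta": 0.70953},
        {"variable": "diabetic", "beta": 0.53160}
      ],
      "s0": 0.88431,
      "mean_lp": 23.9388
    }
  }
}
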