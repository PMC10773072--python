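# Default synthetic scenario: a second-line type 2 diabetes-like cohort.
# Three latent patient subgroups over four continuous biomarkers
# (baseline HbA1c mmol/mol, eGFR mL/min/1.73m2, logged ALT, BMI kg/m2)
# and two ordinal drug-count covariates; binary therapy indicator
# (arm 1 = SGLT2i-like, arm 0 = DPP4i-like); continuous 6-month HbA1c
# outcome with a dominant treatment-by-baseline-HbA1c interaction.
# 20% MAR missingness on eGFR and logged ALT, driven by the always-
# observed baseline HbA1c and BMI columns.
n_individuals: 1000
seed: 42
columns:
  continuous: [hba1c_base, egfr, alt_log, bmi]
  categorical:
    past_drugs: ["2", "3", "4", "5+"]
    current_drugs: ["0", "1", "2", "3+"]
  treatment: therapy
  outcome: hba1c_outcome
  units:
    hba1c_base: mmol/mol
    egfr: mL/min/1.73m2
    alt_log: log IU/L
    bmi: kg/m2
    hba1c_outcome: mmol/mol
components:
  weights: [0.5, 0.3, 0.2]
  means:
    - [66.0, 92.0, 3.2, 30.0]
    - [80.0, 78.0, 3.6, 38.0]
    - [86.0, 62.0, 2.9, 26.0]
  covariances:
    - [[49.0, 0.0, 0.0, 7.35],
       [0.0, 100.0, 0.6, 0.0],
       [0.0, 0.6, 0.09, 0.0],
       [7.35, 0.0, 0.0, 12.25]]
    - [[64.0, 0.0, 0.0, 9.6],
       [0.0, 100.0, 0.7, 0.0],
       [0.0, 0.7, 0.1225, 0.0],
       [9.6, 0.0, 0.0, 16.0]]
    - [[64.0, 0.0, 0.0, -5.6],
       [0.0, 121.0, 0.66, 0.0],
       [0.0, 0.66, 0.09, 0.0],
       [-5.6, 0.0, 0.0, 12.25]]
  category_probs:
    past_drugs:
      - [0.60, 0.30, 0.08, 0.02]
      - [0.15, 0.35, 0.35, 0.15]
      - [0.05, 0.20, 0.35, 0.40]
    current_drugs:
      - [0.15, 0.60, 0.20, 0.05]
      - [0.05, 0.25, 0.50, 0.20]
      - [0.30, 0.40, 0.20, 0.10]
treatment_assignment_prob: 0.4
true_beta:
  intercept: 2.0
  treatment: 8.0
  continuous: {hba1c_base: 0.75, egfr: -0.05, alt_log: 2.0, bmi: 0.1}
  categorical:
    past_drugs: [1.5, 3.0, 4.5]
    current_drugs: [0.8, 1.6, 2.4]
  treat_continuous: {hba1c_base: -0.15, egfr: 0.03, alt_log: 0.5, bmi: -0.08}
  treat_categorical:
    past_drugs: [-0.3, -0.6, -0.9]
    current_drugs: [0.2, 0.4, 0.6]
true_sigma: 8.0
missingness:
  mechanism: mar
  rates: {egfr: 0.2, alt_log: 0.2}
  drivers:
    egfr: {hba1c_base: 0.08}
    alt_log: {bmi: 0.12}
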