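# Default typical-value and variability parameters for the CD19 CAR-T QSP model.
#
# Units:
#   Vmax1_*   (cells·µL⁻¹)·day⁻¹·mL⁻¹     maximum expansion rate per mL tumor volume
#   KM1       cells·µL⁻¹                   T-cell concentration at half-maximum expansion
#   kp*, k12, k23, k34, ke*, k5   day⁻¹    first-order rate constants
#   Vmax5_*   mL·day⁻¹·(cells·µL⁻¹)⁻¹      maximum tumor killing rates per phenotype
#   KM5, K0   mL                           half-maximum killing volume / carrying capacity
#   MIXP      –                            proportion of patients in the reference population
# Variability entries are coefficients of variation in percent (log-normal convention).
structural:
  Vmax1_base_ref: 0.00846
  Vmax1_base_low: 0.000700
  ASCT_Vmax1: 2.53
  CD4CD8_exp: -0.385
  KM1: 1.13
  kp1: 0.0005
  kp2: 0.007
  kp3: 0.007
  k12: 0.140
  k23: 0.191
  k34: 0.355
  ke1: 0.0104
  ke2: 0.0104
  ke3: 0.0104
  ke4: 0.518
  Vmax5_1: 2.57
  Vmax5_2: 4.04
  Vmax5_3: 3.78
  Vmax5_4: 4.24
  KM5: 276.0
  K0: 5000.0
  k5: 0.0023
  MIXP: 0.803
variability:
  iiv_cv:
    Vmax1: 150.0
    Vmax5_2: 307.0
  ruv_cv:
    TN: 59.1
    TCM: 85.9
    TEM: 120.0
    TEFF: 70.6
    CD19: 115.0
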