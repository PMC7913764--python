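{
  "description": "Per-generation airway morphometry for an adult human lung (symmetric-average Weibel-type dichotomous tree; generation 1 = trachea). Median diameters and lengths in cm at a reference lung volume; the loader rescales them isotropically to the requested functional residual capacity. sigma_g is the geometric SD of the lognormal diameter/length randomization; angle ranges are uniform-sampling bounds in degrees (branching = angle between parent flow and airway axis, gravity = inclination of the airway axis from horizontal).",
  "reference_note": "synthetic average morphometry; full individual-airway databases are not redistributed here",
  "n_bronchial": 16,
  "generations": [
    {"generation": 1,  "region": "bronchial", "diameter_cm": 1.80,  "length_cm": 12.00, "sigma_g": 1.10, "branch_angle_deg": [0, 0],   "gravity_angle_deg": [60, 90]},
    {"generation": 2,  "region": "bronchial", "diameter_cm": 1.22,  "length_cm": 4.76,  "sigma_g": 1.12, "branch_angle_deg": [25, 45], "gravity_angle_deg": [30, 90]},
    {"generation": 3,  "region": "bronchial", "diameter_cm": 0.83,  "length_cm": 1.90,  "sigma_g": 1.15, "branch_angle_deg": [20, 50], "gravity_angle_deg": [0, 90]},
    {"generation": 4,  "region": "bronchial", "diameter_cm": 0.56,  "length_cm": 0.76,  "sigma_g": 1.15, "branch_angle_deg": [20, 55], "gravity_angle_deg": [0, 90]},
    {"generation": 5,  "region": "bronchial", "diameter_cm": 0.45,  "length_cm": 1.27,  "sigma_g": 1.15, "branch_angle_deg": [20, 55], "gravity_angle_deg": [0, 90]},
    {"generation": 6,  "region": "bronchial", "diameter_cm": 0.35,  "length_cm": 1.07,  "sigma_g": 1.15, "branch_angle_deg": [20, 55], "gravity_angle_deg": [0, 90]},
    {"generation": 7,  "region": "bronchial", "diameter_cm": 0.28,  "length_cm": 0.90,  "sigma_g": 1.15, "branch_angle_deg": [20, 55], "gravity_angle_deg": [0, 90]},
    {"generation": 8,  "region": "bronchial", "diameter_cm": 0.23,  "length_cm": 0.76,  "sigma_g": 1.15, "branch_angle_deg": [20, 55], "gravity_angle_deg": [0, 90]},
    {"generation": 9,  "region": "bronchial", "diameter_cm": 0.186, "length_cm": 0.64,  "sigma_g": 1.15, "branch_angle_deg": [20, 55], "gravity_angle_deg": [0, 90]},
    {"generation": 10, "region": "bronchial", "diameter_cm": 0.154, "length_cm": 0.54,  "sigma_g": 1.15, "branch_angle_deg": [20, 55], "gravity_angle_deg": [0, 90]},
    {"generation": 11, "region": "bronchial", "diameter_cm": 0.130, "length_cm": 0.46,  "sigma_g": 1.15, "branch_angle_deg": [20, 55], "gravity_angle_deg": [0, 90]},
    {"generation": 12, "region": "bronchial", "diameter_cm": 0.109, "length_cm": 0.39,  "sigma_g": 1.15, "branch_angle_deg": [20, 55], "gravity_angle_deg": [0, 90]},
    {"generation": 13, "region": "bronchial", "diameter_cm": 0.095, "length_cm": 0.33,  "sigma_g": 1.15, "branch_angle_deg": [20, 55], "gravity_angle_deg": [0, 90]},
    {"generation": 14, "region": "bronchial", "diameter_cm": 0.082, "length_cm": 0.27,  "sigma_g": 1.15, "branch_angle_deg": [20, 55], "gravity_angle_deg": [0, 90]},
    {"generation": 15, "region": "bronchial", "diameter_cm": 0.074, "length_cm": 0.23,  "sigma_g": 1.15, "branch_angle_deg": [20, 55], "gravity_angle_deg": [0, 90]},
    {"generation": 16, "region": "bronchial", "diameter_cm": 0.066, "length_cm": 0.20,  "sigma_g": 1.15, "branch_angle_deg": [20, 55], "gravity_angle_deg": [0, 90]},
    {"generation": 17, "region": "acinar",    "diameter_cm": 0.060, "length_cm": 0.165, "sigma_g": 1.15, "branch_angle_deg": [30, 60], "gravity_angle_deg": [0, 90]},
    {"generation": 18, "region": "acinar",    "diameter_cm": 0.054, "length_cm": 0.141, "sigma_g": 1.15, "branch_angle_deg": [30, 60], "gravity_angle_deg": [0, 90]},
    {"generation": 19, "region": "acinar",    "diameter_cm": 0.050, "length_cm": 0.117, "sigma_g": 1.15, "branch_angle_deg": [30, 60], "gravity_angle_deg": [0, 90]},
    {"generation": 20, "region": "acinar",    "diameter_cm": 0.047, "length_cm": 0.099, "sigma_g": 1.15, "branch_angle_deg": [30, 60], "gravity_angle_deg": [0, 90]},
    {"generation": 21, "region": "acinar",    "diameter_cm": 0.045, "length_cm": 0.083, "sigma_g": 1.15, "branch_angle_deg": [30, 60], "gravity_angle_deg": [0, 90]},
    {"generation": 22, "region": "acinar",    "diameter_cm": 0.043, "length_cm": 0.070, "sigma_g": 1.15, "branch_angle_deg": [30, 60], "gravity_angle_deg": [0, 90]},
    {"generation": 23, "region": "acinar",    "diameter_cm": 0.041, "length_cm": 0.059, "sigma_g": 1.15, "branch_angle_deg": [30, 60], "gravity_angle_deg": [0, 90]},
    {"generation": 24, "region": "acinar",    "diameter_cm": 0.041, "length_cm": 0.050, "sigma_g": 1.15, "branch_angle_deg": [30, 60], "gravity_angle_deg": [0, 90]}
  ]
}
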