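{
  "comment": "Named feature sets as ordered descriptor-table column selections. TS columns are dG_dft plus every column suffixed _TS.",
  "columns_ground_state": [
    "Vs_C", "Vs_N", "Is_min_N", "Es_min_C", "P_int",
    "omega", "N_global", "omega_loc_C", "N_loc_N",
    "q_C", "q_N", "q_L",
    "V_N_C", "V_N_N", "V_N_L",
    "SASA_r_C", "SASA_r_N", "SASA_r_L",
    "BO_CN", "BO_CL",
    "PC1", "PC2", "PC3", "PC4", "PC5"
  ],
  "columns_ts": [
    "dG_dft",
    "q_C_TS", "q_N_TS", "q_L_TS",
    "V_N_C_TS", "V_N_N_TS", "V_N_L_TS",
    "BO_CN_TS", "BO_CL_TS"
  ],
  "surface_descriptors": ["Vs_C", "Vs_N", "Is_min_N", "Es_min_C", "P_int"],
  "traditional_descriptors": [
    "omega", "N_global", "omega_loc_C", "N_loc_N",
    "q_C", "q_N", "q_L",
    "V_N_C", "V_N_N", "V_N_L",
    "BO_CN", "BO_CL"
  ],
  "feature_sets": {
    "X_full": [
      "Vs_C", "Vs_N", "Is_min_N", "Es_min_C", "P_int",
      "omega", "N_global", "omega_loc_C", "N_loc_N",
      "q_C", "q_N", "q_L",
      "V_N_C", "V_N_N", "V_N_L",
      "SASA_r_C", "SASA_r_N", "SASA_r_L",
      "BO_CN", "BO_CL",
      "PC1", "PC2", "PC3", "PC4", "PC5",
      "dG_dft",
      "q_C_TS", "q_N_TS", "q_L_TS",
      "V_N_C_TS", "V_N_N_TS", "V_N_L_TS",
      "BO_CN_TS", "BO_CL_TS"
    ],
    "X_noTS": [
      "Vs_C", "Vs_N", "Is_min_N", "Es_min_C", "P_int",
      "omega", "N_global", "omega_loc_C", "N_loc_N",
      "q_C", "q_N", "q_L",
      "V_N_C", "V_N_N", "V_N_L",
      "SASA_r_C", "SASA_r_N", "SASA_r_L",
      "BO_CN", "BO_CL",
      "PC1", "PC2", "PC3", "PC4", "PC5"
    ],
    "X_small": [
      "dG_dft",
      "Es_min_C", "Is_min_N", "Vs_C", "Vs_N",
      "omega", "N_global", "P_int",
      "SASA_r_C", "BO_CL",
      "PC1", "PC2"
    ],
    "X_trad": [
      "omega", "N_global", "omega_loc_C", "N_loc_N",
      "q_C", "q_N", "q_L",
      "V_N_C", "V_N_N", "V_N_L",
      "SASA_r_C", "SASA_r_N", "SASA_r_L",
      "BO_CN", "BO_CL",
      "PC1", "PC2", "PC3", "PC4", "PC5"
    ],
    "X_surf": [
      "Vs_C", "Vs_N", "Is_min_N", "Es_min_C", "P_int",
      "SASA_r_C", "SASA_r_N", "SASA_r_L",
      "PC1", "PC2", "PC3", "PC4", "PC5"
    ]
  }
}
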