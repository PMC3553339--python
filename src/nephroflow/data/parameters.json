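{
  "nephrons": {
    "total_count": 76000,
    "fraction_long_loops": 0.30
  },
  "hemodynamics": {
    "renal_plasma_flow_ml_min": 5.06,
    "fraction_peritubular_plasma_flow": 0.85,
    "gfr0_ml_min": 1.31,
    "collecting_duct_end_pressure_mmHg": 3,
    "glomerular_resistance_mmHg_min_L": 2205000000.0,
    "glomerular_pressure_short_mmHg": 44.2,
    "glomerular_pressure_long_mmHg": 47.2,
    "water_viscosity_mPa_s": 0.6913
  },
  "hematocrit": {
    "cortex_outer_medulla": 0.38,
    "inner_medulla": 0.23
  },
  "systemic": {
    "sodium_mmol_L": 150,
    "urea_mmol_L": 6
  },
  "collecting_ducts_per_nephron": {
    "cortex": "1/4",
    "outer_medulla": "1/6",
    "inner_medulla_1": "1/12",
    "inner_medulla_2": "1/310"
  },
  "vascular": {
    "avr_permeability_cm_s": 0.0012,
    "dvr_permeability_cm_s": 0.00076,
    "dvr_urea_permeability_outer_medulla_cm_s": 0.0036,
    "peritubular_permeability_cm_s": 0.0012,
    "peritubular_surface_cm2": 1360.0,
    "dvr_surface_cm2": {
      "outer_medulla": 0.001,
      "inner_medulla_1": 0.0001,
      "inner_medulla_2": 0.0001
    },
    "dvr_water_conductivity_L2_min_umol": {
      "outer_medulla": 2.2e-08,
      "inner_medulla_1": 2.2e-08,
      "inner_medulla_2": 3.8e-09
    }
  },
  "volumes_ml": {
    "cortex": {
      "glomerular_plasma": 0.0772,
      "peritubular_capillaries": 0.206,
      "interstitial_space": 0.0664,
      "proximal_tubule_short": 0.172,
      "proximal_tubule_long": 0.0737,
      "distal_tubule_short": 0.0383,
      "distal_tubule_long": 0.0164,
      "collecting_duct": 0.0548,
      "cellular_space": 1.03
    },
    "outer_medulla": {
      "vasa_descendens": 0.0442,
      "vasa_ascendens": 0.0442,
      "interstitial_space": 0.0392,
      "descending_henle_short": 0.0787,
      "ascending_henle_short": 0.0392,
      "descending_henle_long": 0.0337,
      "ascending_henle_long": 0.0168,
      "collecting_duct": 0.0488,
      "cellular_space": 0.50
    },
    "inner_medulla_1": {
      "vasa_descendens": 0.00318,
      "vasa_ascendens": 0.00318,
      "interstitial_space": 0.00467,
      "descending_henle": 0.00553,
      "ascending_henle": 0.00553,
      "collecting_duct": 0.00213,
      "cellular_space": 0.0139
    },
    "inner_medulla_2": {
      "vasa_descendens": 0.00287,
      "vasa_ascendens": 0.00287,
      "interstitial_space": 0.0076,
      "descending_henle": 0.0038,
      "ascending_henle": 0.0038,
      "collecting_duct": 0.0016,
      "cellular_space": 0.0157
    }
  },
  "tubular_transport": {
    "water_conductivity_L2_min_umol": {
      "proximal_tubule": 1.2e-07,
      "descending_henle_outer_medulla": 2.7e-11,
      "descending_henle_inner_medulla_1": 2.35e-10,
      "descending_henle_inner_medulla_2": 1.0e-12,
      "distal_tubule": 6.77e-08,
      "collecting_duct_cortex": 7.406e-09,
      "collecting_duct_outer_medulla": 5.078e-09,
      "collecting_duct_inner_medulla_1": 1.164e-09,
      "collecting_duct_inner_medulla_2": 4.443e-11
    },
    "sodium_active_L_min": {
      "proximal_tubule": 0.000248,
      "ascending_henle_outer_medulla": 0.000787,
      "distal_tubule": 0.000511
    },
    "sodium_passive_L_min": {
      "ascending_henle_inner_medulla_2": 0.0025,
      "ascending_henle_inner_medulla_1": 0.0025
    },
    "urea_passive_L_min": {
      "proximal_tubule": 8.2e-09,
      "ascending_henle_inner_medulla_2": 4.89e-06,
      "collecting_duct_inner_medulla_1": 1.39e-06,
      "collecting_duct_inner_medulla_2": 4.45e-05
    }
  },
  "segment_geometry": {
    "proximal_tubule": {"radius_um": 10.5, "length_mm": 6.2},
    "descending_henle_outer_medulla": {"radius_um": 8.75, "length_mm": 2},
    "descending_henle_inner_medulla_1": {"radius_um": 8, "length_mm": 2},
    "descending_henle_inner_medulla_2": {"radius_um": 8, "length_mm": 2},
    "ascending_henle_inner_medulla_2": {"radius_um": 8, "length_mm": 2},
    "ascending_henle_inner_medulla_1": {"radius_um": 8, "length_mm": 2},
    "ascending_henle_outer_medulla": {"radius_um": 9.5, "length_mm": 2},
    "distal_tubule": {"radius_um": 9.5, "length_mm": 2},
    "collecting_duct_cortex": {"radius_um": 10, "length_mm": 1},
    "collecting_duct_outer_medulla": {"radius_um": 10.5, "length_mm": 2},
    "collecting_duct_inner_medulla_1": {"radius_um": 12, "length_mm": 2.5},
    "collecting_duct_inner_medulla_2": {"radius_um": 14, "length_mm": 2.5}
  },
  "cellular_sodium_mmol_L": {
    "inner_medulla_2": 25,
    "elsewhere": 15
  },
  "body": {
    "plasma_volume_ml": 2.41,
    "residual_extracellular_volume_ml": 44.6,
    "total_plasma_flow_L_min": 0.02365,
    "exchange_clearance_L_min": null
  },
  "numerics": {
    "relaxation_time_min": 0.1,
    "short_loop_split": 0.7,
    "long_loop_split": 0.3,
    "pair_allocation_gain": 3.35
  }
}
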