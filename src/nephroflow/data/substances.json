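{
  "_comment": "Substance library. Viscosity points are (mg iodine/ml, mPa.s at 37 C) from vendor product brochures; exponents are refit from these points at load time and may be overridden by editing this file. Molar masses from standard chemical references.",
  "mannitol": {
    "n_osmotic": 1,
    "iodine_atoms": 0,
    "molar_mass_g_mol": 182.17,
    "viscosity_exponent_L_umol": 0.0
  },
  "iopromide_300": {
    "n_osmotic": 1,
    "iodine_atoms": 3,
    "molar_mass_g_mol": 791.11,
    "formulation_mg_iodine_ml": 300,
    "viscosity_points_mgI_ml_mPa_s": [[300, 4.7]]
  },
  "iomeprol_400": {
    "n_osmotic": 1,
    "iodine_atoms": 3,
    "molar_mass_g_mol": 777.09,
    "formulation_mg_iodine_ml": 400,
    "viscosity_points_mgI_ml_mPa_s": [[400, 12.6]]
  },
  "iodixanol_320": {
    "n_osmotic": 1,
    "iodine_atoms": 6,
    "molar_mass_g_mol": 1550.18,
    "formulation_mg_iodine_ml": 320,
    "viscosity_points_mgI_ml_mPa_s": [[320, 11.8]]
  },
  "iothalamate_400": {
    "n_osmotic": 2,
    "iodine_atoms": 3,
    "molar_mass_g_mol": 635.89,
    "formulation_mg_iodine_ml": 400,
    "viscosity_points_mgI_ml_mPa_s": [[400, 4.5]]
  },
  "perfect_dimer": {
    "n_osmotic": 1,
    "iodine_atoms": 6,
    "molar_mass_g_mol": 1550.18,
    "formulation_mg_iodine_ml": 320,
    "viscosity_iodine_curve_from": "iopromide_300"
  }
}
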