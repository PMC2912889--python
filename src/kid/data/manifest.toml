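# Default resource manifest: one term file per category plus settings.
# Paths are relative to this file.

[lexicons]
enzyme_name = "lexicons/enzymes.txt"
ec_number = "lexicons/ec_numbers.txt"
ligand = "lexicons/ligands.txt"
organism = "lexicons/organisms.txt"
localisation = "lexicons/tissues.txt"
"K_M" = "lexicons/expr_km.txt"
"K_i" = "lexicons/expr_ki.txt"
"k_cat" = "lexicons/expr_kcat.txt"
"k_cat/K_M" = "lexicons/expr_kcat_km.txt"
"V_max" = "lexicons/expr_vmax.txt"
"IC_50" = "lexicons/expr_ic50.txt"
"S_0.5" = "lexicons/expr_s05.txt"
"K_d" = "lexicons/expr_kd.txt"
"K_a" = "lexicons/expr_ka.txt"
"t_1/2" = "lexicons/expr_thalf.txt"
"pI" = "lexicons/expr_pi.txt"
"n_H" = "lexicons/expr_nh.txt"
"specific_activity" = "lexicons/expr_sa.txt"
"V_max/K_M" = "lexicons/expr_vmax_km.txt"
"pH" = "lexicons/expr_ph.txt"
"temperature" = "lexicons/expr_temperature.txt"
binding_phrase = "lexicons/binding_phrases.txt"
negation_phrase = "lexicons/negation_phrases.txt"

[units]
unit_concentration = "lexicons/units_concentration.txt"
"unit_k_cat" = "lexicons/units_kcat.txt"
"unit_k_cat/K_M" = "lexicons/units_kcat_km.txt"
"unit_t_1/2" = "lexicons/units_thalf.txt"
"unit_V_max" = "lexicons/units_vmax.txt"
unit_specific_activity = "lexicons/units_sa.txt"
"unit_V_max/K_M" = "lexicons/units_vmax_km.txt"
"unit_K_a" = "lexicons/units_ka.txt"
unit_temperature = "lexicons/units_temperature.txt"
unit_other = "lexicons/units_other.txt"

[settings]
abbreviations = ["e.g.", "i.e.", "i.v.", "et al.", "vs.", "approx.", "fig.", "spp."]
continuation_keywords = ["which", "that"]
ph_bounds = [0.0, 14.0]
temperature_bounds = [-80.0, 150.0]
ec_map = "ec_map.tsv"

[ambiguity]
exclusions = ["ipp", "ka", "ki", "km"]
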