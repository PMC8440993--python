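# Species physiology constants for the three study species.
# tlc: mass-specific total lung capacity, ml/kg.  For the loggerhead TLC is
#   allometric: (113.6 * M^0.923) / M with M in kg; encoded as coefficients.
# o2 stores are mass-specific reference values (ml O2/kg) for the lung (l),
#   blood (b) and muscle (m); they are used as order-of-magnitude checks on the
#   initialized state, not as hard initial conditions.
# hb: hemoglobin concentration, g per ml whole blood (0.156 g/ml = 15.6 g/dl).
# pcv: packed cell volume, %.  mb: myoglobin, g per kg muscle.
# p50: half-saturation O2 pressure of hemoglobin, mmHg.
version: 1
hill_coefficient: 2.7
dead_space_fraction_of_tlc: 0.07
species:
  loggerhead:
    tlc_allometric: {coefficient: 113.6, exponent: 0.923}
    o2_store_lung: 16.4
    o2_store_blood: 7.84
    o2_store_muscle: 3.93
    hb_g_per_ml: 0.088
    pcv_pct: 30
    mb_g_per_kg: 2.9
    p50_mmhg: 25
  leatherback:
    tlc_ml_per_kg: 64
    o2_store_lung: 9.25
    o2_store_blood: 13.8
    o2_store_muscle: 4.50
    hb_g_per_ml: 0.156
    pcv_pct: 39
    mb_g_per_kg: 4.9
    p50_mmhg: 40
  green:
    tlc_ml_per_kg: 115
    o2_store_lung: 16.6
    o2_store_blood: 8.72
    o2_store_muscle: 3.93
    hb_g_per_ml: 0.098
    pcv_pct: 29
    mb_g_per_kg: 2.9
    p50_mmhg: 47
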