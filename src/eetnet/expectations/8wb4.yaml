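# Published reference values for PDB entry 8WB4 (PSII-ACPII supercomplex).
#
# Selectors use pigment labels "a<resnum>_<subunit>"; subunit labels require a
# populated naming_map in the 8wb4 profile (chain id -> ACPII-1..6, CCPII-S,
# CP43, CP47, Unk3, ...).  "_*" matches any subunit (the minimum over matches
# is reported for min_distance; the closest match for rates/distances, which
# also absorbs the two C2-related monomer copies).
#
# Rates are ps^-1 (tolerance 0.01, values printed to 3 decimals); Mg-Mg
# distances are angstrom (tolerance 0.02); shortest-contact distances have
# tolerance 0.1.  Counts are exact.
expectations:
  # --- pigment / lipid census (whole dimer) ---
  - {id: census-chl-a,  quantity: census_count, selector: {kind: CHL_A}, expected: 208, tolerance: 0}
  - {id: census-chl-c,  quantity: census_count, selector: {kind: CHL_C}, expected: 12, tolerance: 0}
  - {id: census-alx,    quantity: census_count, selector: {kind: ALX},  expected: 42, tolerance: 0}
  - {id: census-acar,   quantity: census_count, selector: {kind: ACAR}, expected: 24, tolerance: 0}
  - {id: census-cro,    quantity: census_count, selector: {kind: CRO},  expected: 10, tolerance: 0}
  - {id: census-mon,    quantity: census_count, selector: {kind: MON},  expected: 4,  tolerance: 0}
  - {id: census-lmg,    quantity: census_count, selector: {kind: LMG},  expected: 20, tolerance: 0}
  - {id: census-sqd,    quantity: census_count, selector: {kind: SQD},  expected: 8,  tolerance: 0}
  - {id: census-lhg,    quantity: census_count, selector: {kind: LHG},  expected: 18, tolerance: 0}
  - {id: census-pigments-total, quantity: total_pigments, expected: 300, tolerance: 0}
  - {id: census-lipids-total,   quantity: total_lipids,   expected: 46,  tolerance: 0}

  # --- stromal-side antenna belt rates ---
  - {id: rate-a608.1-a601.2, quantity: fret_rate, selector: {a: a608_ACPII-1, b: a601_ACPII-2}, expected: 0.775, tolerance: 0.01}
  - {id: rate-a608.2-a601.3, quantity: fret_rate, selector: {a: a608_ACPII-2, b: a601_ACPII-3}, expected: 0.792, tolerance: 0.01}
  - {id: rate-a608.4-a601.5, quantity: fret_rate, selector: {a: a608_ACPII-4, b: a601_ACPII-5}, expected: 0.589, tolerance: 0.01}
  - {id: rate-a608.5-a601.6, quantity: fret_rate, selector: {a: a608_ACPII-5, b: a601_ACPII-6}, expected: 0.765, tolerance: 0.01}

  # --- lumenal-side antenna rates ---
  - {id: rate-a605.1-a611.2, quantity: fret_rate, selector: {a: a605_ACPII-1, b: a611_ACPII-2}, expected: 0.962, tolerance: 0.01}
  - {id: rate-a605.1-a612.2, quantity: fret_rate, selector: {a: a605_ACPII-1, b: a612_ACPII-2}, expected: 0.509, tolerance: 0.01}
  - {id: rate-a605.2-a611.3, quantity: fret_rate, selector: {a: a605_ACPII-2, b: a611_ACPII-3}, expected: 1.321, tolerance: 0.01}
  - {id: rate-a605.2-a612.3, quantity: fret_rate, selector: {a: a605_ACPII-2, b: a612_ACPII-3}, expected: 0.383, tolerance: 0.01}
  - {id: rate-a606.5-a601.S, quantity: fret_rate, selector: {a: a606_ACPII-5, b: a601_CCPII-S}, expected: 0.350, tolerance: 0.01}
  - {id: rate-a601.S-a612.6, quantity: fret_rate, selector: {a: a601_CCPII-S, b: a612_ACPII-6}, expected: 0.835, tolerance: 0.01}

  # --- outer-to-inner antenna (ACPII-4 -> ACPII-3) ---
  - {id: rate-a603.4-a610.3, quantity: fret_rate, selector: {a: a603_ACPII-4, b: a610_ACPII-3}, expected: 0.163, tolerance: 0.01}
  - {id: rate-a603.4-a609.3, quantity: fret_rate, selector: {a: a603_ACPII-4, b: a609_ACPII-3}, expected: 0.603, tolerance: 0.01}
  - {id: rate-a607.4-a610.3, quantity: fret_rate, selector: {a: a607_ACPII-4, b: a610_ACPII-3}, expected: 0.734, tolerance: 0.01}
  - {id: dist-a603.4-a610.3, quantity: mg_mg_distance, selector: {a: a603_ACPII-4, b: a610_ACPII-3}, expected: 13.70, tolerance: 0.02}
  - {id: dist-a603.4-a609.3, quantity: mg_mg_distance, selector: {a: a603_ACPII-4, b: a609_ACPII-3}, expected: 13.96, tolerance: 0.02}
  - {id: dist-a607.4-a610.3, quantity: mg_mg_distance, selector: {a: a607_ACPII-4, b: a610_ACPII-3}, expected: 13.74, tolerance: 0.02}

  # --- antenna-to-core, stromal side ---
  - {id: rate-a607.2-a602.S, quantity: fret_rate, selector: {a: a607_ACPII-2, b: a602_CCPII-S}, expected: 0.221, tolerance: 0.01}
  - {id: rate-a603.2-a602.S, quantity: fret_rate, selector: {a: a603_ACPII-2, b: a602_CCPII-S}, expected: 0.177, tolerance: 0.01}
  - {id: rate-a602.S-a615.47, quantity: fret_rate, selector: {a: a602_CCPII-S, b: a615_CP47}, expected: 1.291, tolerance: 0.01}
  - {id: dist-a602.S-a607.2, quantity: mg_mg_distance, selector: {a: a602_CCPII-S, b: a607_ACPII-2}, expected: 17.18, tolerance: 0.02}
  - {id: dist-a602.S-a603.2, quantity: mg_mg_distance, selector: {a: a602_CCPII-S, b: a603_ACPII-2}, expected: 21.55, tolerance: 0.02}
  - {id: dist-a602.S-a615.47, quantity: mg_mg_distance, selector: {a: a602_CCPII-S, b: a615_CP47}, expected: 15.81, tolerance: 0.02}
  - {id: rate-a603.6-a101.U3, quantity: fret_rate, selector: {a: a603_ACPII-6, b: a101_Unk3}, expected: 1.083, tolerance: 0.01}
  - {id: rate-a607.6-a101.U3, quantity: fret_rate, selector: {a: a607_ACPII-6, b: a101_Unk3}, expected: 0.421, tolerance: 0.01}
  - {id: rate-a602.6-a101.U3, quantity: fret_rate, selector: {a: a602_ACPII-6, b: a101_Unk3}, expected: 0.185, tolerance: 0.01}
  - {id: rate-a101.U3-a513.43, quantity: fret_rate, selector: {a: a101_Unk3, b: a513_CP43}, expected: 0.419, tolerance: 0.01}
  - {id: rate-a101.U3-a507.43, quantity: fret_rate, selector: {a: a101_Unk3, b: a507_CP43}, expected: 0.152, tolerance: 0.01}
  - {id: rate-a607.3-a506.43, quantity: fret_rate, selector: {a: a607_ACPII-3, b: a506_CP43}, expected: 0.049, tolerance: 0.01}
  - {id: dist-a101.U3-a603.6, quantity: mg_mg_distance, selector: {a: a101_Unk3, b: a603_ACPII-6}, expected: 12.65, tolerance: 0.02}
  - {id: dist-a101.U3-a607.6, quantity: mg_mg_distance, selector: {a: a101_Unk3, b: a607_ACPII-6}, expected: 13.34, tolerance: 0.02}
  - {id: dist-a101.U3-a602.6, quantity: mg_mg_distance, selector: {a: a101_Unk3, b: a602_ACPII-6}, expected: 20.48, tolerance: 0.02}
  - {id: dist-a101.U3-a507.43, quantity: mg_mg_distance, selector: {a: a101_Unk3, b: a507_CP43}, expected: 21.03, tolerance: 0.02}
  - {id: dist-a101.U3-a513.43, quantity: mg_mg_distance, selector: {a: a101_Unk3, b: a513_CP43}, expected: 15.84, tolerance: 0.02}

  # --- antenna-to-core, lumenal side ---
  - {id: rate-a606.1-a601.47, quantity: fret_rate, selector: {a: a606_ACPII-1, b: a601_CP47}, expected: 0.099, tolerance: 0.01}
  - {id: rate-a612.2-a601.47, quantity: fret_rate, selector: {a: a612_ACPII-2, b: a601_CP47}, expected: 0.041, tolerance: 0.01}

  # --- carotenoid-chlorophyll shortest contacts ---
  - {id: contact-alx615-a608, quantity: min_distance, selector: {a: "Alx615_*", b: "a608_*"}, expected: 3.1, tolerance: 0.1}
  - {id: contact-alx618-a614, quantity: min_distance, selector: {a: "Alx618_ACPII-4", b: "a614_ACPII-4"}, expected: 3.2, tolerance: 0.1}

# Not encodable without per-entry chain knowledge (selectors are chain-based):
# the His93/a601 (3.4 A) and Trp163-Leu168/a602 contacts of CCPII-S, the
# CCPII-S/D1 interface pairs (2.5 / 3.0 A) and the per-monomer 62/48 layer
# split (needs the monomer's chain set).  Add them once the naming_map of the
# profile is populated.
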