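# Profile for PDB entry 8WB4 (PSII-ACPII supercomplex dimer).
#
# The carotenoid component codes (alloxanthin, crocoxanthin, monadoxanthin,
# alpha-carotene) are entry-specific and are inferred at run time from the
# chem_comp names inside the mmCIF file (infer_carotenoids: true), so no
# hard-coded guesses are shipped here.
#
# naming_map: the editorial subunit labels (ACPII-1..6, CCPII-S, CP43, CP47,
# D1, D2, Unk1-3, ...) are not recorded in the coordinate file and could not
# be verified offline while this profile was written.  Populate it from the
# entry (chain id -> subunit label) before using label-based selectors; with
# an empty naming_map, subunit labels fall back to raw chain ids.
code_map:
  CLA: CHL_A
  KC1: CHL_C
  KC2: CHL_C
  LMG: LMG
  SQD: SQD
  LHG: LHG
naming_map: {}
infer_carotenoids: true
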