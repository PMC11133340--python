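# Default profile: only component codes that are stable across entries.
# code_map values are PigmentKind names; naming_map maps chain id -> subunit label.
code_map:
  CLA: CHL_A
  KC1: CHL_C
  KC2: CHL_C
  LMG: LMG
  SQD: SQD
  LHG: LHG
naming_map: {}
infer_carotenoids: false
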