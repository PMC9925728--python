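{
  "_comment": "Synthetic position-specific active-site profiles for the three animal PRX subfamilies, over a 15-residue window centred on the peroxidatic cysteine (C_P at window position 8; window = C_P-7 .. C_P+7, so positions 1-8 form a PXXX[TS]XXC instance). Each profile is a consensus string plus a concentration: per position, the consensus residue has probability = concentration and the remaining 19 residues share (1-concentration) evenly. These consensi are synthetic stand-ins distinct enough for benchmark classification; substitute curated profiles for real proteomes.",
  "window_halfwidth": 7,
  "profiles": {
    "AhpC-PRX1": {"consensus": "PVDFTFVCPTEIIAF", "concentration": 0.7},
    "PRX5":      {"consensus": "PGAFTPGCSKTHLPG", "concentration": 0.7},
    "PRX6":      {"consensus": "PNIDTPVCTTELGRA", "concentration": 0.7}
  }
}
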