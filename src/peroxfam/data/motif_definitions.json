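{
  "_comment": "Provisional, user-editable motif definitions. The resolving-cysteine (C_R) context patterns and the hyperoxidation a/b motifs are not printed as scannable patterns in the primary literature (C_R sites are shown only in figures; a/b residue content is deferred to Bolduc et al.), so the residue content below is a synthetic stand-in chosen for the bundled synthetic benchmark. Replace with curated patterns for real proteomes. Grammar: uppercase = fixed residue, X = any, [TS] = alternation, X{m,n} = bounded gap. 'roles' are 1-based element indices; 'expected' gives the canonical residue for wildcard role slots.",
  "CR_AhpC-PRX1": {
    "pattern": "GEVXPAGW",
    "roles": {"CR": 4},
    "expected": {"CR": "C"}
  },
  "CR_PRX5": {
    "pattern": "DSQXGEVR",
    "roles": {"CR": 4},
    "expected": {"CR": "C"}
  },
  "motif_a": {
    "pattern": "FRYXEIA",
    "roles": {"His": 4},
    "expected": {"His": "H"}
  },
  "motif_b": {
    "pattern": "LDXWSVK",
    "roles": {"Asn": 3},
    "expected": {"Asn": "N"}
  }
}
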