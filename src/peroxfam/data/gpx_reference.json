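{
  "_comment": "Synthetic tetrad-annotated GPX reference (not a natural sequence).",
  "sequence": "TANCDDNWDSEYAMSVWAWWWQLPVSSADILYVNLWTYTUIWIQDSVMETLLRSLGMTGAQGRQDFFMCQAFFIDWCPKMRRQDDQGVASKAPQWMYNDNYCAPVENFARHCCMFDFKTM",
  "positions": {
    "UC": 40,
    "Q": 70,
    "W": 95,
    "N": 100
  }
}
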