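{
  "_comment": "Synthetic per-group GPX consensi; tetrad positions as in gpx_reference.json.",
  "GPX1/2": "TANGDDNWDSEMAMSVWAWWWWLAVSWQDIAYVNPWTYTUQFYQVVLMETLFRNLGMTMAQGRQDFFPCQARFIDWCPWMRRQDDQGRAPKAPQWWSNDNICATVETMARHCCMFDFKTM",
  "GPX3/5/6": "RANCDDEWNSEYAMSVWALWRQLLVSSADILVVNLWTYTUIWIQASYVETLYRSEGETGKIGRQDFFMGQAFFIDWCPKMRRSTDDGVMSVAPQWMYNINYCAMVENVARHCPMKDFKTL",
  "GPX4/PHGPX": "TANCCDNEDSNYAMQVWAWWWVLPSSSYDILYMNLTTYTUWWIQDCVVETLSRSLGMTGAVGKQDAFMCQSFNIDRCPKMRWQDDQGVASKAPQWGYADNYCAPVWNWMRRCCMFHAKTM",
  "GPX7/8": "PANCDVVWASEYAMSVWAWWWQGPVSYAWILCVNLWTYTCLWPQDSVMETLLASLGMAGAQMSMDFFMYQAGFLDRLPWFRHQDDQAVAQKAPMWMYNINYWAPVENFARHCCMFDTKTM"
}
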