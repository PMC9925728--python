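>REF_G12_1
TANGDDNWDSEMAMSRWAWWWWLAVSWQDIAYVNPWTYTUQFYQVVGMETLFRNLDMTMAQGAQDFFPCQARFIDWCPWMRRQDDQGRAPKAPQWWSNDNICATVETMARHCCMFDFKTM
>REF_G12_2
TANGDDNWDSEMAMSVWAWWWWLAVSWQDIAYVVPWTYTUQFYQVVLMETLFRNLGMTMAQGRQDFFPCQARFIDWCPWFRRQDDQGRKPKAPQWWSNDNICATVETMAYHCCMFDFKTM
>REF_G12_3
TANGDDNWDSEMAMSVWAWWWWLAVSWQDIAYVNPWTYTUQFYQVVLMETLFRNLGMTMAQGRQDFFPCQARFIDWCPWMRRQDDQHRAPKAPQWWSNDNICATDETMARHCCMFDPKTM
>REF_G12_4
TANGDDNWDSEMAMSVWAWWWWLAVSWQDIAIVNPWTHTUQFYQVVLMETLFRNLGKTMWQGRQDFFPCQARSIDWCPWMRRQDDQGRAPVAPQWWSNDNICATVETMARHCCMFDFKTM
>REF_G12_5
TANGDDNWDSEMAMKVWAWWWWLAVSWQDIAYVNPWTYTUQFYQVVLMETLFRNLGMTMAQGRQDFFPCQARFIDWCPWMRRQDDQGRAPKAPQWWSNDNICATAETMARHCCMFDFKIM
>REF_G12_6
TANGDDNWDSEMAMSVWAWWWWLAVSWQDITYVNPWTYTUQFYQVVLMETLFRNLGMTMAQGRQDFFPCQARFIDNCPWMRRQDDQGRAPKAPQWWSNDNICATVETMARHCCMFDFKTM
>REF_G356_1
RANQDDEWNSEYAMSVWALWRQLLVSSADILVVNLWTYTUIWIQASYVETLYFSEGETGKIGRQDFFMGQAFFIDWCPKMRSSTSDGVMSVAPQWMYNINYCAMVENIARHCPMKDFKTL
>REF_G356_2
RANCDDEWNSEYAMSVWALWRQLLVSSADILVVILWTYTUIWIQASYVETLYRSEGETGKIGRQDFFMGQAFFIDWCPKMRRSTDDGVMSVAPQWMYNINYCAMVENVARHCPMKDFKTL
>REF_G356_3
RANCFDEWNSEYASSVWALCRQLLVSSEDILVVNLWTYTUIWIQASYVETLYRSEGETGKIGRQDFFMGQAFFIDWCPKMRRSTDDGVMSVAPQWMYNINYCAMVENVARHCPMKDFKQL
>REF_G356_4
RANCDDEWNSEYAHSVWALWRQLLVSSADILVVNLWTYTUIWIQGSYVETLYRSELETGKIGRQDFFMGQAFFIDWCPKMRRSTDDGVMSVAPQWMYNINYCAMVENVARHCPMKDFKTL
>REF_G356_5
PANCDDEWNSEYAMSVWALWRQLLVSSADILVVNLWTYTUIWIQASYVETLYRSEGETGKIGRQDFFMGQAFFIDWCPKMRRSTDDGVMSVAPQWMYNINYCAMVENVARHCPMKDFKTL
>REF_G356_6
KANCDDEWNSEYAMSVWALWRQLNVSSADILVVNLWTYTUIWIQASYVETLYRGEGETGKIGRQDFFMGQAFFIDWCPKMRRSTDDGVMSVAPQWFYNINYCAMVENVAFHCPMKDFKTL
>REF_G4PHG_1
TANCCDNEDSNYAMQVWAWWWVLPSSSYDILYMNLTTHTUWWIQDCVVETLSRSLGMTGAVGKQDYFMCQSFNIDRCPKMRWQDDQGVASKAPQWGYADNYCAPVWNWMRRCCMFHAKTM
>REF_G4PHG_2
TANCCDNEDSNYWMQVWAWWAVLPSSSYDILYMNLTTYTUWWIQDCVVETLSRSAGMNGAVGKQDAFMCQSFNIDRCPKMRWQDDQGVASKAPQWGYADNYCAKVWNWMRRCCMFHAKTM
>REF_G4PHG_3
TANKNDNEDSNSAMQVWEWWWVLPSSPYDILYMNLTTYTUWWIQDCVVETLSRSLGYTGAHGKQDAFMCQSFNIDRCPKMRWQDDQGVASKAPQWGYADNYCAPVWNWMRRCCMFHAKTM
>REF_G4PHG_4
TANCCDNEDSNYAMQVWAWWQVLPSSSYDILYMNLTTYTUWWIQDCVVETFSRGLGMTGAVGKQDAFMCQSFNIDRCPKMRWQDDQGVAHKAPQWGYADNYCAPVWNWMRRCCMFHAKTM
>REF_G4PHG_5
TANCCDNEDSNYAMQVWAWWWVLPSSGYDILYMNLTTYTUWWIQDCVVETLSRSLGMTGAVGKQDAFMCQSFNIDRCPKMRWQDWQGRASKAPQWGYADNYCAPVWNWMRRCIMFHAKTA
>REF_G4PHG_6
PANCCDNEDSNYAMQVWAWWWVLPSSSYDILYQNLQTYTUWWIQDCVVETLSRSLGMFGAVGKQDAFMCQSFNIDRAPKMRWQDDQGVASKAPQWGYADNYCAPVWNWMRRCCEFHAKTM
>REF_G78_1
PANCDVVWASEYAMSVWAWWWQGPVSYAWILCVNLWTYTCLWPQISVMETLLASLGMAGAQMSMDFFMYQAGFLDRLPYFRHQDDQAVAQGAPMWMYNINYWAPVENFARHCCMFDTKTM
>REF_G78_2
PANCDVVWAMEYAMSVWAWWWQGPVSYAWILCVNLWTYTCLWPQDSVMETLLASLGMAGAQASMDFFMYQAGFLDRLPWFRPQDDQAVAQKAPMWMYNINYWAPVENLARHCCMFDTKTM
>REF_G78_3
PAMCDVVWASEYAMSVWAWWWQGPVSYAWILCVNLWTYTCLWPQDSVMETLLASLGMAGAQMSMDFFMYQDGFLDRLPWFRHQDDQAVAQKAPMWMYNINYWAPVENVARHCCMFDTKDM
>REF_G78_4
PANCDVVWASEYSMSVWAWWWQAPVSYAWILCVNLWCYTCLWPQDSFMETLLASLGMAGAQMSMDFFMYQAGFLDRLPQFYHRNDVAVAQKAPMWMYNINYWAPVENFARHCCMFDTKTM
>REF_G78_5
PANCDVVWASEYAMSVWAWWWQGGVSYAWILCVNLWTYTCLWPQDSVMETLLASLGMAIAQMSMDFFMYQWGQLDRLPWFRHQDDQAVAQKAPMWMYNINYWAPVENFARHCCMFDTKTM
>REF_G78_6
PGNCDVVWASEYAMSVWAWWWQGPVSYAWILCVNLWTYTCLWPQDSVMETLLASLGMAGAQMSMDFFMYQAGFLDRLPWFRHQDDQSVAQKAPMWMYNINYWAPVENFARHCCMFDTKTM
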