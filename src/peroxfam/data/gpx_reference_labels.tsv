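REF_G12_1	GPX1/2
REF_G12_2	GPX1/2
REF_G12_3	GPX1/2
REF_G12_4	GPX1/2
REF_G12_5	GPX1/2
REF_G12_6	GPX1/2
REF_G356_1	GPX3/5/6
REF_G356_2	GPX3/5/6
REF_G356_3	GPX3/5/6
REF_G356_4	GPX3/5/6
REF_G356_5	GPX3/5/6
REF_G356_6	GPX3/5/6
REF_G4PHG_1	GPX4/PHGPX
REF_G4PHG_2	GPX4/PHGPX
REF_G4PHG_3	GPX4/PHGPX
REF_G4PHG_4	GPX4/PHGPX
REF_G4PHG_5	GPX4/PHGPX
REF_G4PHG_6	GPX4/PHGPX
REF_G78_1	GPX7/8
REF_G78_2	GPX7/8
REF_G78_3	GPX7/8
REF_G78_4	GPX7/8
REF_G78_5	GPX7/8
REF_G78_6	GPX7/8
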