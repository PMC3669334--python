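# GSM-to-tissue roster for the mouse GEO DataSet GDS3142 (3 subjects/tissue,
# 4 for muscle; 19 samples in total).
kidney: [GSM252083, GSM252084, GSM252085]
liver: [GSM252074, GSM252075, GSM252076]
lung: [GSM252080, GSM252081, GSM252082]
heart: [GSM252113, GSM252114, GSM252115]
muscle: [GSM252070, GSM252071, GSM252072, GSM252073]
adipose: [GSM252093, GSM252094, GSM252095]
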