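# GSM-to-tissue roster for the human GEO DataSet GDS596 (2 subjects/tissue).
kidney: [GSM18955, GSM18956]
liver: [GSM18953, GSM18954]
lung: [GSM18949, GSM18950]
heart: [GSM18951, GSM18952]
muscle: [GSM19013, GSM19014]
adipose: [GSM18975, GSM18976]
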