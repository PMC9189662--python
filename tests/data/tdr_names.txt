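tDR-1:30-Glu-CTC-1
tDR-1:32-Asp-GTC-2
tDR-1:32-Glu-CTC-1-M2-D5G
tDR-1:32-Glu-TTC-2
tDR-1:32-Gly-CCC-1-M4
tDR-1:33-Glu-CTC
tDR-1:33-Glu-CTC-1-M2-D5G
tDR-1:33-Glu-TTC
tDR-1:33-Pro-AGG-1-M5
tDR-1:34-Gly-GCC-1
tDR-1:34-Pro-CGG-1-M2
tDR-1:36-Asp-GTC-2
tDR-1:36-Asp-GTC-2-M2
tDR-1:36-Glu-CTC
tDR-1:36-Glu-CTC-1
tDR-1:36-Glu-TTC
tDR-1:36-Gly-CCC-1
tDR-2:31-Glu-CTC-1
tDR-34:74-Met-CAT-3
tDR-37:60-Ala-AGG-4-A1G
tDR-37:74-Asp-GTC-2-M2
tDR-37:74-Glu-CTC-1-M2
tDR-37:75-Glu-TTC-1-M2
tDR-38:74-Arg-TCT-1
tDR-39:55-Glu-CTC-1-M4
tDR-39:72-Asp-GTC-2-M2
tDR-39:72-Glu-TTC-2
tDR-39:74-Glu-TTC-2
tDR-39:74-Leu-AAG-2
tDR-42:74-Arg-CCT-4
tDR-42:74-Ser-GCT-1
tDR-42:74-Ser-GCT-2
tDR-T1:T20-Ser-TGA-1-1
tDR-T1-T31-Arg-CCT-2-1
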