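grade_pct,roi,size_mm,auc_ratio
80,I,10,1.00
80,I,8,1.07
80,I,6,1.18
80,I,4,1.27
80,II,10,1.00
80,II,8,1.04
80,II,6,1.06
80,II,4,1.06
80,III,10,1.00
80,III,8,1.02
80,III,6,1.05
80,III,4,1.12
80,IV,10,1.00
80,IV,8,1.04
80,IV,6,1.05
80,IV,4,1.01
0,I,10,1.00
0,I,8,1.12
0,I,6,1.25
0,I,4,1.48
0,II,10,1.00
0,II,8,1.16
0,II,6,1.34
0,II,4,1.48
0,III,10,1.00
0,III,8,1.18
0,III,6,1.28
0,III,4,1.36
0,IV,10,1.00
0,IV,8,1.18
0,IV,6,1.33
0,IV,4,1.37
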