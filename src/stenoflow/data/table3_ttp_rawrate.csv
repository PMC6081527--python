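roi,grade_pct,mean_s,sd_s,n,printed_p,note
I,0,0.65,0.39,3,0.745,
I,40,0.39,0.20,3,0.745,
I,60,0.52,0.28,3,0.745,
I,80,0.51,0.25,3,0.745,
II,0,0.66,0.37,3,0.495,
II,40,0.35,0.27,3,0.495,
II,60,0.56,0.29,3,0.495,
II,80,0.73,0.26,3,0.495,
III,0,0.66,0.37,3,0.178,
III,40,0.36,0.32,3,0.178,
III,60,0.85,0.26,3,0.178,
III,80,0.87,0.68,3,0.178,
IV,0,0.69,0.42,3,0.105,
IV,40,0.33,0.25,3,0.105,
IV,60,0.93,0.20,3,0.105,
IV,80,0.84,0.05,3,0.105,
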