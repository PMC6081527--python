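roi,grade_pct,mean_s,sd_s,n,printed_p,note
I,0,0.95,0.20,3,0.308,
I,40,0.71,0.08,3,0.308,
I,60,0.75,0.08,3,0.308,
I,80,0.79,0.19,3,0.308,
II,0,1.30,0.14,3,0.011,
II,40,0.69,0.27,3,0.011,
II,60,0.92,0.07,3,0.011,
II,80,0.89,0.04,3,0.011,
III,0,1.30,0.14,3,0.010,
III,40,0.69,0.27,3,0.010,
III,60,1.09,0.12,3,0.010,
III,80,1.20,0.35,3,0.010,
IV,0,1.58,0.19,3,0.263,
IV,40,0.99,0.55,3,0.263,
IV,60,1.27,0.27,3,0.263,
IV,80,1.29,0.07,3,0.263,
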