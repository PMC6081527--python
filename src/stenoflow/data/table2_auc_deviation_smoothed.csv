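roi,window_s,grade_pct,mean_pct,sd_pct,n,printed_p,note
II,1,0,-18.67,17.67,3,0.1264,
II,1,40,-6,9.72,3,0.1264,
II,1,60,5.33,4.51,3,0.1264,
II,1,80,-47,44.19,3,0.1264,
II,3,0,6.67,3.21,3,0.1608,
II,3,40,11,10.54,3,0.1608,
II,3,60,7.67,3.06,3,0.1608,
II,3,80,-10,18.52,3,0.1608,SD printed without percent sign
II,5,0,12.67,2.31,3,0.0061,SD printed without percent sign
II,5,40,6.33,2.52,3,0.0061,
II,5,60,10,4.36,3,0.0061,
II,5,80,-13,12.66,3,0.0061,
II,7,0,15,3,3,0.0013,
II,7,40,5,1.73,3,0.0013,
II,7,60,9,4.36,3,0.0013,
II,7,80,-17.67,11.68,3,0.0013,
III,1,0,-28.67,30.62,3,0.0474,
III,1,40,-5.33,6.11,3,0.0474,
III,1,60,-11,11.79,3,0.0474,
III,1,80,-65.67,39.5,3,0.0474,SD printed without percent sign
III,3,0,8,9.64,3,0.5835,
III,3,40,19.67,26.39,3,0.5835,
III,3,60,12,4.58,3,0.5835,
III,3,80,3.33,17.9,3,0.5835,
III,5,0,18.67,6.65,3,0.02,
III,5,40,11,8.66,3,0.02,
III,5,60,12.67,4.51,3,0.02,
III,5,80,-0.67,12.1,3,0.02,
III,7,0,23.33,5.77,3,0.0012,
III,7,40,5.33,8.39,3,0.0012,
III,7,60,10.33,4.04,3,0.0012,
III,7,80,-15.67,9.45,3,0.0012,
IV,1,0,-73.33,19.63,3,0.0048,
IV,1,40,-13.67,18.9,3,0.0048,
IV,1,60,-4,11.53,3,0.0048,
IV,1,80,-78.33,31.47,3,0.0048,
IV,3,0,-23.67,8.14,3,0.1422,
IV,3,40,26.67,42.4,3,0.1422,
IV,3,60,12.33,13.8,3,0.1422,
IV,3,80,5.33,13.3,3,0.1422,
IV,5,0,-3.67,5.51,3,0.3526,mean printed without closing percent sign
IV,5,40,22.33,31.01,3,0.3526,
IV,5,60,15,15.13,3,0.3526,
IV,5,80,1.67,11.93,3,0.3526,
IV,7,0,4.33,4.93,3,0.4322,
IV,7,40,16,28.51,3,0.4322,
IV,7,60,13,13.45,3,0.4322,
IV,7,80,-5.67,9.71,3,0.4322,
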