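roi,window_s,grade_pct,mean_pct,sd_pct,n,printed_p,note
II,1,0,-2.87,4.85,3,0.71,
II,1,40,0.35,20.6,3,0.71,
II,1,60,-0.71,8.16,3,0.71,
II,1,80,-9.99,6.56,3,0.71,
II,3,0,18.67,3.2,3,0.1,
II,3,40,10.81,14.4,3,0.1,
II,3,60,9.68,4.69,3,0.1,
II,3,80,-2.73,4.09,3,0.1,comma decimal -2.73 and SD printed without percent sign; normalized
II,5,0,21.12,5.34,3,0.06,SD printed without percent sign
II,5,40,11.8,17.03,3,0.06,
II,5,60,10.57,11.93,3,0.06,
II,5,80,-7.87,2.93,3,0.06,
II,7,0,19.88,5.61,3,0.06,
II,7,40,13.59,19.26,3,0.06,
II,7,60,11.17,13.78,3,0.06,
II,7,80,-11.07,2.92,3,0.06,
III,1,0,-7.25,3.11,3,0.62,
III,1,40,-12.64,20.74,3,0.62,
III,1,60,-6.06,19.66,3,0.62,
III,1,80,-20.83,6.13,3,0.62,
III,3,0,26.06,3.41,3,0.0048,
III,3,40,11.73,10.22,3,0.0048,
III,3,60,10.73,4.39,3,0.0048,SD printed without percent sign
III,3,80,0.24,1.87,3,0.0048,
III,5,0,29.75,4.34,3,0.0004,
III,5,40,7.84,11.3,3,0.0004,
III,5,60,8.49,1.37,3,0.0004,
III,5,80,-9.18,1.63,3,0.0004,
III,7,0,28.09,5.65,3,0.0007,
III,7,40,5.5,12.78,3,0.0007,
III,7,60,7.59,0.97,3,0.0007,
III,7,80,-13.79,2.2,3,0.0007,
IV,1,0,-13.39,9.4,3,0.62,
IV,1,40,-16.16,18.65,3,0.62,
IV,1,60,-19.03,26.63,3,0.62,
IV,1,80,-31.68,11.1,3,0.62,
IV,3,0,39.38,5.63,3,0.0094,
IV,3,40,30.32,15.58,3,0.0094,
IV,3,60,12.51,9.96,3,0.0094,
IV,3,80,3.52,6.37,3,0.0094,
IV,5,0,46.78,8.27,3,0.0012,
IV,5,40,25.94,15.81,3,0.0012,
IV,5,60,9.89,6.81,3,0.0012,
IV,5,80,-5.64,6.1,3,0.0012,
IV,7,0,46.75,9.57,3,0.0011,
IV,7,40,23.33,17.65,3,0.0011,
IV,7,60,8.22,4.69,3,0.0011,
IV,7,80,-10.86,6.13,3,0.0011,
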