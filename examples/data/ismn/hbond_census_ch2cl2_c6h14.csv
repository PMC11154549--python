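face,N_HB,N_H1,A_box,A_hkl
1 0 0,22.87,18,2432.21,101.342
1 1 0,40.29,48,3439.66,143.319
1 1 1,20.72,24,6663.03,277.607
1 1 -1,39.87,48,6663.03,277.607
1 0 -1,15.85,18,2326.03,258.448
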