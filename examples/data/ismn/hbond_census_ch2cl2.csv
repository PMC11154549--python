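face,N_HB,N_H1,A_box,A_hkl
1 0 0,24.80,18,2432.21,101.342
1 1 0,47.19,48,3439.66,143.319
1 1 1,20.92,24,6663.03,277.607
1 1 -1,49.50,48,6663.03,277.607
1 0 -1,17.68,18,2326.03,258.448
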