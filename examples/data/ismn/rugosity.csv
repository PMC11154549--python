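face,A_hkl,A_acc
1 0 0,101.342,131.615
1 1 0,143.319,202.505
1 1 1,277.607,392.680
1 1 -1,277.607,391.540
1 0 1,258.448,340.865
1 0 -1,258.448,356.375
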