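face,E_att,Z_cry,Z_hkl,A_hkl,A_box,E_int
1 0 0,-48.81,8,8,101.34,2432.21,-577.44
1 1 0,-61.87,8,8,143.32,3439.66,-919.91
1 1 1,-170.28,8,8,277.61,6663.03,-2211.43
1 1 -1,-170.28,8,8,277.61,6663.03,-2074.29
1 0 1,-177.07,8,8,258.45,2326.03,-805.57
1 0 -1,-177.07,8,8,258.45,2326.03,-840.60
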