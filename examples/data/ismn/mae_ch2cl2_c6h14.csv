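face,E_att,Z_cry,Z_hkl,A_hkl,A_box,E_int
1 0 0,-48.81,8,8,101.34,2432.21,-556.13
1 1 0,-61.87,8,8,143.32,3439.66,-903.67
1 1 1,-170.28,8,8,277.61,6663.03,-2126.07
1 1 -1,-170.28,8,8,277.61,6663.03,-1991.14
1 0 1,-177.07,8,8,258.45,2326.03,-766.75
1 0 -1,-177.07,8,8,258.45,2326.03,-786.70
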