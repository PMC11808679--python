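station,wqi,grade,remark
BS-1,391.18,5,Very poor
BS-2,0.43,1,Excellent
BS-3,0.61,1,Excellent
BS-4,0.64,1,Excellent
BS-5,328.81,5,Very poor
BS-6,0.40,1,Excellent
BS-7,383.26,5,Very poor
BS-8,0.33,1,Excellent
BS-9,0.38,1,Excellent
BS-10,0.32,1,Excellent
BS-11,235.89,4,Poor
BS-12,0.48,1,Excellent
BS-13,277.99,4,Poor
BS-14,0.59,1,Excellent
BS-15,149.19,3,Moderate
BS-16,268.16,4,Poor
BS-17,0.50,1,Excellent
BS-18,194.51,3,Moderate
BS-19,0.51,1,Excellent
BS-20,2247.20,5,Very poor
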