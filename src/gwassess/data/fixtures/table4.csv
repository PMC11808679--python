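station,cd,cu,ni,pb
BS-1,200,0.8,42.5,117.5
BS-5,160,0.9,42.5,135
BS-7,190,0.7,60,135.5
BS-11,110,0.8,55,108.5
BS-13,140,0.8,2.5,108
BS-15,60,0.4,25,120
BS-16,140,2,60,45
BS-18,90,0.1,32.5,99
BS-20,1290,0.3,5,92
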