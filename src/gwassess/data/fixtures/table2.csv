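parameter,unit,min,max,mean,sd,std_WHO,std_USEPA,std_ISDW,std_BDWS,pct_WHO,pct_USEPA,pct_ISDW,pct_BDWS,pct_mean
pH,-,7.24,8.2,7.86,0.26,6.5-8.5,6.5-8.5,6.5-8.5,6.5-8.5,100,100,100,100,100
alkalinity,mg/L,361.9,515,452.1,43.5,200-600,30-400,200,20-200,100,15,,,58
free_co2,mg/L,4,14,8.85,2.86,10,,,,75,100,100,100,94
ec,uS/cm,770,4800,1522,946.8,250,50-1500,,50-1500,0,70,100,70,60
orp,mV,-64.3,-21.5,-42.13,10.62,,,,,,,,,
salinity,ppt,0.15,2.33,0.52,0.50,,1,1,0.6,,90,90,75,85
tds,mg/L,450.6,3072,971.9,607.8,600-1000,500,500,1000,75,5,5,75,40
th,mg/L,45,665,151.9,128.1,300,200,300,200-500,95,90,95,90,93
turbidity,FTU,0.04,7.19,1.17,1.55,4,5,5,10,95,95,95,100,96
nacl,mg/L,140.3,2127.2,472.6,459.7,200-300,500,,600,40,75,,75,64
ca,mg/L,18.04,264.5,60.78,50.88,75,,75,75,100,,100,100,100
cl,mg/L,85.1,1290.4,472.6,278.6,250,250,250,150-600,85,100,85,85,89
cd,mg/L,0.006,0.129,0.026,0.038,0.003,0.005,0.003,0.005,70,70,70,95,76
cu,mg/L,0.003,0.02,0.008,0.005,2.00,1,0.005,1.00,55,55,55,55,55
ni,mg/L,0.02,0.24,0.084,0.089,0.07,,0.02,0.1,100,,75,100,94
pb,mg/L,0.09,0.271,0.213,0.055,0.01,0.015,0.1,0.05,65,100,60,70,74
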