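station,tci,tci_class,tci_aw,mci,mci_class,mci_aw,pli,pli_class,pli_aw,npi,npi_class,npi_aw,mpi,mpi_class,mpi_aw,wci,wci_class
BS-1,17.72,high,4,1.18,very low,1,0.49,low,2,3.43,medium,3,2.21,medium,3,0.19,low
BS-2,7.08,low,2,0.47,very low,1,0.50,low,2,1.32,low,2,0.00,very low,0,0.12,low
BS-3,7.38,low,2,0.49,very low,1,0.46,low,2,1.51,low,2,0.00,very low,0,0.12,low
BS-4,9.38,medium,3,0.63,very low,1,0.63,medium,3,1.66,low,2,0.00,very low,0,0.15,low
BS-5,17.12,high,4,1.14,very low,1,0.48,low,2,3.90,medium,3,1.91,medium,3,0.17,low
BS-6,7.51,low,2,0.50,very low,1,0.47,low,2,1.75,low,2,0.00,very low,0,0.12,low
BS-7,19.63,high,4,1.31,very low,1,0.59,medium,3,3.94,medium,3,2.15,medium,3,0.19,low
BS-8,7.88,low,2,0.53,very low,1,0.51,medium,3,1.81,low,2,0.00,very low,0,0.13,low
BS-9,8.31,medium,3,0.55,very low,1,0.56,medium,3,1.52,low,2,0.00,very low,0,0.15,low
BS-10,8.34,medium,3,0.56,very low,1,0.44,low,2,1.43,low,2,0.00,very low,0,0.13,low
BS-11,16.99,high,4,1.13,very low,1,0.56,medium,3,3.17,medium,3,2.02,medium,3,0.19,low
BS-12,10.22,medium,3,0.68,very low,1,0.66,medium,3,1.80,low,2,0.00,very low,0,0.15,low
BS-13,20.17,high,4,1.34,very low,1,0.98,medium,3,3.20,medium,3,1.65,medium,3,0.19,low
BS-14,12.51,medium,3,0.83,very low,1,0.89,medium,3,1.58,low,2,0.00,very low,0,0.15,low
BS-15,21.30,high,4,1.42,very low,1,0.80,medium,3,3.54,medium,3,1.46,medium,3,0.19,low
BS-16,36.57,very high,5,2.44,medium,3,1.67,high,4,4.04,medium,3,2.51,high,4,0.25,medium
BS-17,14.45,medium,3,0.96,very low,1,0.99,medium,3,1.86,low,2,0.00,very low,0,0.15,low
BS-18,17.00,high,4,1.13,very low,1,0.69,medium,3,2.91,medium,3,1.78,medium,3,0.19,low
BS-19,9.29,medium,3,0.62,very low,1,0.63,medium,3,1.82,low,2,0.00,very low,0,0.15,low
BS-20,36.49,very high,5,2.43,medium,3,1.62,high,4,3.98,medium,3,2.45,medium,3,0.23,medium
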