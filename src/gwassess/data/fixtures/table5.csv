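station,child_hi_ing,child_hi_der,child_ncr,male_hi_ing,male_hi_der,male_ncr,female_hi_ing,female_hi_der,female_ncr
BS-1,6.83E-03,9.46E-06,6.84E-03,3.12E-03,2.76E-05,3.15E-03,3.18E-03,3.16E-05,3.21E-03
BS-5,6.94E-03,7.83E-06,6.94E-03,3.17E-03,2.45E-05,3.20E-03,3.23E-03,2.80E-05,3.26E-03
BS-7,7.52E-03,9.55E-06,7.53E-03,3.44E-03,3.17E-05,3.47E-03,3.50E-03,3.62E-05,3.54E-03
BS-11,5.60E-03,6.15E-06,5.61E-03,2.56E-03,2.41E-05,2.59E-03,2.61E-03,2.75E-05,2.64E-03
BS-13,5.29E-03,5.77E-06,5.29E-03,2.42E-03,1.11E-05,2.43E-03,2.46E-03,1.26E-05,2.47E-03
BS-15,5.02E-03,3.21E-06,5.02E-03,2.30E-03,1.17E-05,2.31E-03,2.34E-03,1.34E-05,2.35E-03
BS-16,3.93E-03,7.62E-06,3.94E-03,1.80E-03,2.80E-05,1.82E-03,1.83E-03,3.20E-05,1.86E-03
BS-18,4.76E-03,4.61E-06,4.77E-03,2.18E-03,1.61E-05,2.19E-03,2.22E-03,1.84E-05,2.24E-03
BS-20,1.86E-02,5.27E-05,1.86E-02,8.50E-03,1.02E-04,8.60E-03,8.65E-03,1.17E-04,8.77E-03
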