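station,child_cd,child_ni,child_pb,child_cr,male_cd,male_ni,male_pb,male_cr,female_cd,female_ni,female_pb,female_cr
BS-1,7.34E-03,1.73E-02,1.20E-04,2.48E-02,3.39E-03,8.03E-03,5.55E-05,1.15E-02,3.46E-03,8.19E-03,5.66E-05,1.17E-02
BS-5,5.87E-03,1.73E-02,1.38E-04,2.33E-02,2.71E-03,8.03E-03,6.38E-05,1.08E-02,2.77E-03,8.19E-03,6.50E-05,1.10E-02
BS-7,6.97E-03,2.45E-02,1.39E-04,3.16E-02,3.22E-03,1.13E-02,6.40E-05,1.46E-02,3.28E-03,1.16E-02,6.53E-05,1.49E-02
BS-11,4.04E-03,2.24E-02,1.11E-04,2.66E-02,1.86E-03,1.04E-02,5.13E-05,1.23E-02,1.90E-03,1.06E-02,5.23E-05,1.26E-02
BS-13,5.14E-03,,1.10E-04,5.25E-03,2.37E-03,,5.10E-05,2.42E-03,2.42E-03,,5.20E-05,2.47E-03
BS-15,2.20E-03,1.02E-02,1.23E-04,1.25E-02,1.02E-03,4.72E-03,5.67E-05,5.80E-03,1.04E-03,4.82E-03,5.78E-05,5.92E-03
BS-16,5.14E-03,2.45E-02,4.60E-05,2.97E-02,2.37E-03,1.13E-02,2.13E-05,1.37E-02,2.42E-03,1.16E-02,2.17E-05,1.40E-02
BS-18,3.30E-03,1.33E-02,1.01E-04,1.67E-02,1.53E-03,6.14E-03,4.68E-05,7.72E-03,1.56E-03,6.26E-03,4.77E-05,7.87E-03
BS-20,4.73E-02,2.04E-03,9.41E-05,4.94E-02,2.19E-02,9.45E-04,4.35E-05,2.29E-02,2.23E-02,9.64E-04,4.43E-05,2.33E-02
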