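# Drinking-water guideline values per authority, in canonical units
# (mg/L for solutes, uS/cm for EC, ppt for salinity, FTU for turbidity,
# unitless pH). A scalar is an upper bound; a two-element list [lo, hi]
# is a two-sided interval; an absent parameter has no standard (e.g. ORP,
# which is negative-valued and carries no guideline anywhere).
WHO:
  pH: [6.5, 8.5]
  alkalinity: [200, 600]
  free_co2: 10
  ec: 250
  tds: [600, 1000]
  th: 300
  turbidity: 4
  nacl: [200, 300]
  ca: 75
  cl: 250
  cd: 0.003
  cu: 2.0
  ni: 0.07
  pb: 0.01
USEPA:
  pH: [6.5, 8.5]
  alkalinity: [30, 400]
  ec: [50, 1500]
  salinity: 1
  tds: 500
  th: 200
  turbidity: 5
  nacl: 500
  cl: 250
  cd: 0.005
  cu: 1.0
  pb: 0.015
ISDW:
  pH: [6.5, 8.5]
  alkalinity: 200
  salinity: 1
  tds: 500
  th: 300
  turbidity: 5
  ca: 75
  cl: 250
  cd: 0.003
  cu: 0.005
  ni: 0.02
  pb: 0.1
BDWS:
  pH: [6.5, 8.5]
  alkalinity: [20, 200]
  ec: [50, 1500]
  salinity: 0.6
  tds: 1000
  th: [200, 500]
  turbidity: 10
  nacl: 600
  ca: 75
  cl: [150, 600]
  cd: 0.005
  cu: 1.0
  ni: 0.1
  pb: 0.05
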