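# Exposure cohorts for the drinking-water pathway.
# ir: water ingestion rate (L/day); ef: exposure frequency (days/year);
# ep: exposure period (years); bw: body weight (kg); sa: exposed skin
# area (cm^2); et: dermal exposure time (h/day); cf: unit conversion
# factor (L/cm^3). Averaging time AT = ep * 365 days for both the
# noncarcinogenic and carcinogenic pathways.
child:
  ir: 1.0
  ef: 350
  ep: 6
  bw: 16
  sa: 6800
  et: 1.0
  cf: 0.0001
adult_male:
  ir: 2.0
  ef: 350
  ep: 30
  bw: 70
  sa: 19000
  et: 0.5
  cf: 0.0001
adult_female:
  ir: 1.6
  ef: 350
  ep: 30
  bw: 55
  sa: 16000
  et: 0.75
  cf: 0.0001
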