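# Classification rubrics for the contamination indices: ordered
# [upper_bound, label, aw] bins forming contiguous half-open intervals
# [lo, hi); the last bin (null upper bound) is unbounded above. A value
# exactly on a printed boundary takes the upper class. aw is the integer
# "arbitrary weight" (0-5) attached to the matched pollution level; the
# weighted contamination index (wci) carries no aw of its own.
tci:
  - [8, low, 2]
  - [16, medium, 3]
  - [32, high, 4]
  - [null, very high, 5]
mci:
  - [1.5, very low, 1]
  - [2, low, 2]
  - [4, medium, 3]
  - [8, high, 4]
  - [null, very high, 5]
pli:
  - [0.5, low, 2]
  - [1, medium, 3]
  - [null, high, 4]
npi:
  - [1, very low, 1]
  - [2.5, low, 2]
  - [7, medium, 3]
  - [null, high, 4]
mpi:
  - [0.3, very low, 1]
  - [1, low, 2]
  - [2.5, medium, 3]
  - [7, high, 4]
  - [null, very high, 5]
wci:
  - [0.07, very low, 0]
  - [0.2, low, 0]
  - [0.4, medium, 0]
  - [0.67, high, 0]
  - [null, very high, 0]
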