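# Methods

## Data model and units

All solutes are held internally in mg/L; EC in μS/cm, salinity in ppt,
turbidity in FTU, the redox potential (ORP) in mV, pH unitless. Unit
conversion happens once, at load time, from a per-column unit map
(e.g. μg/L metals divide by 1000). The health-risk stage performs the
single further documented conversion (mg → μg when forming hazard
quotients, because reference doses are conventionally tabulated in
μg/kg-day). Keeping one conversion point avoids the unit slips that
plague multi-index studies.

Missing measurements stay missing at this layer — excluded from
numerators and denominators alike, never imputed. In the reference
survey only 9 of 20 stations have metal analyses; the `metals_measured`
flag carries that distinction downstream.

Guideline standards are registered per (authority, parameter) for WHO,
USEPA, the Indian standard (ISDW) and the Bangladeshi standard (BDWS),
plus custom sets. A scalar standard is an upper bound; an interval
standard (pH 6.5–8.5, WHO alkalinity 200–600 mg/L, ...) is two-sided.
ORP carries no standard under any authority and is excluded from all
standard-relative indices. The shipped table transcribes the printed
source values without resolving that source's internal inconsistencies
(some compliance percentages there cannot be reproduced from the listed
limits; the compliance stage recomputes rather than copies). The
per-parameter "mean" compliance column averages only the authorities
that publish a standard for that parameter.

## Contamination indices

CF uses the national (BDWS) standards as denominator by default, with
one fallback: BDWS publishes no free-CO₂ limit, so the WHO value
(10 mg/L) fills that slot, keeping the 15-parameter basis (every
measured parameter except ORP) complete — the published sheet's
TCI/MCI pairs divide by 15 on every row, which fixes n. Interval
standards collapse to their upper bound in CF.

Numerical choices:

- PLI replaces zero CF terms by a configurable floor (default 10⁻⁶)
  with a warning; the geometric mean degenerates at zero.
- Class intervals are half-open [lo, hi): a value exactly on a printed
  boundary takes the upper class. The printed rubric leaves gaps
  (e.g. "0.5 ≤ PLI < 1 / PLI > 1"); the implemented bins close them
  into contiguous intervals.
- A station without metal data has an undefined MPI; it is reported
  with class "very low" and weight A_w = 0, mirroring how such rows are
  printed in the source sheet.
- The default WCI aggregator is ΣA_w / (5 × number of indices with
  A_w > 0), a normalized score in [0, 1]. The aggregation behind the
  source's printed WCI column is under-determined — no linear weighting
  of its printed A_w values reproduces it (A_w sums of 13 and 9 map to
  0.19 and 0.15 while 7 maps to 0.12) — so the aggregator is pluggable
  and the default makes no claim to reproduce that column. The printed
  MPI column is likewise not reproducible from any single authority's
  limits; MPI defaults to BDWS metal limits, overridable.

## Ecological risk

ERI = TRF × C/S with TRF Cd 30 and Cu/Ni/Pb 5. The reference set S is
the one consistent with the published per-metal scores and extrema:
Cd 0.003, Pb 0.01, Ni 0.02, Cu 0.05 mg/L — a mixed-authority set whose
Cu value matches no authority in the registry; each entry carries a
provenance note and the set is configurable. PER is the plain sum of
per-metal scores. Class bounds: ERI < 40 low, 40–80 moderate, 80–160
considerable, 160–320 high, ≥ 320 very high; PER < 150 low, 150–300
medium, 300–600 considerable, ≥ 600 extreme.

## Health risk

Cohort defaults (child / adult male / adult female): ingestion rate
1.0 / 2.0 / 1.6 L/day; exposure frequency 350 days/yr; exposure period
6 / 30 / 30 yr; body weight 16 / 70 / 55 kg; skin area 6800 / 19000 /
16000 cm²; exposure time 1.0 / 0.5 / 0.75 h/day; conversion factor
0.0001 L/cm³ (kept as tabulated in the source constants; 0.001 is the
commoner convention elsewhere — configurable). The averaging time is
EP × 365 days for both the noncarcinogenic and carcinogenic pathways
(no 70-year carcinogenic averaging); that definition is what makes the
published carcinogenic-risk table reproducible. The resulting ingestion
dose coefficients IR·EF·EP/(BW·AT) are 0.0599 (child), 0.0279 (female)
and 0.0274 (male) per day, which is why child risks strictly dominate
on identical water.

Slope factors: Cd 6.1, Ni 0.84, Pb 8.5 × 10⁻³ kg·day/mg. The lead
value is stored at the 10⁻³ scale — the conventional magnitude, and the
only one dimensionally consistent with per-metal risks of order 10⁻⁴.
Copper has no slope factor and is excluded from the carcinogenic sheet.

Known non-reproducibilities, carried as documentation rather than
targets: the published noncarcinogenic table sits at the 10⁻³ scale,
which no consistent unit reading of the stated formulas yields (the
literal formulas give child HQs of order 1 at the observed metal
levels — visible in this package's own synthetic runs, where HI > 1);
and the published Ni risk column implies a slope factor near 1.7 rather
than the stated 0.84, which is kept as printed.

## Water quality index

Quality ratings use the absolute-value form Q = 100·|V_m − V_i|/|V_s −
V_i| so sub-ideal pH cannot produce a negative rating; ideal values are
0 everywhere except pH (7). V_s defaults to the WHO column; for an
interval standard the bound farther from the ideal is used (pH → 8.5,
alkalinity → 600). Weights are W = 1/V_s, so trace metals with tiny
standards dominate the index by design. Grades are contiguous:
Excellent [0, 25], Good (25, 50], Poor (50, 75], Very poor (75, 100],
Unsuitable (> 100); the source's own grade labels are internally
inconsistent with these bounds (it labels 149 "Moderate" and 2247
"Very poor"), so the fixture keeps its labels verbatim while the
classifier follows the stated bounds. The source's printed mean WQI
(344.82) also does not equal the mean of its 20 printed station values
(≈ 224); no computation here relies on it.

## Multivariate statistics and interpolation

Correlations are pairwise-complete Pearson. PCA standardizes columns
by default (parameter units differ by orders of magnitude) and
diagonalizes the correlation matrix directly; components carry a
deterministic sign (largest-magnitude loading positive) and explained
variance fractions sum to one. The test suite cross-checks loadings and
variance fractions against an independent library implementation.
Clustering is Ward linkage on Euclidean distances of standardized data,
for stations or parameters.

IDW treats coordinates as planar decimal degrees — the study area spans
under 0.15°, where the metric distortion is irrelevant next to the
interpolator's own smoothing — with power p = 2, all stations as
neighbours, and exact value transfer when a cell centre falls within
10⁻⁹ degrees of a station. Surfaces are written as ESRI ASCII grids.
The source does not state its PCA scaling or IDW power; these defaults
are declared, not inferred, and its reported component percentages are
properties of raw data that were never published, so tests assert
structural properties (variance normalization, convexity,
node-exactness) instead.

## Synthetic generator

Lognormal marginals are moment-matched so the configured mean and SD are
exact: σ² = ln(1 + (sd/mean)²), μ = ln(mean) − σ²/2 — chosen because
every published solute distribution is right-skewed (max ≫ mean). The
salinity block (EC, salinity, NaCl, Cl⁻, TH, turbidity, Ca²⁺) shares a
log-scale equicorrelation ρ = 0.95; TDS is 0.64 × EC times lognormal
noise (0.64 × 1522 ≈ 974 matches the published TDS mean of 971.9),
making r(EC, TDS) ≈ 1 as observed. pH is uniform on the published range
[7.24, 8.2]; ORP is normal (−42.13, 10.62), truncated below zero. Each
metal is lognormal with a 5 % exceedance spike whose factor is the
published max/mean ratio, and the base mean rescaled so the configured
mean is preserved — that is what recreates single-hotspot behaviour
(one station dominating PER and CR) without shifting the moments.

What the generator does not emulate: spatial autocorrelation (station
coordinates are uniform in the bounding box, so IDW maps of synthetic
data show no structured gradients), seasonality, detection limits and
censoring, and the survey's partial metal coverage (synthetic tables
have complete metals unless rows are masked by the caller). Passing
tests on synthetic data therefore validate the computational pipeline
and its invariants, not field-data behaviour.

## Problem sizes

Defaults everywhere are the survey's own scale: 20 stations, 16
parameters, 4 metals, 3 cohorts. Repeated-seed checks (generator
parameter recovery, correlation-structure assertions) use 100 seeds of
20 stations; the PCA block-structure check draws 2000 observations to
separate the eigenvalue band from sampling noise. Everything runs in
seconds on one CPU.
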