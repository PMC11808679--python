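"""Synthetic groundwater chemistry generator.

Emulates the statistical structure of the study area's tube-well data:
right-skewed solute concentrations (lognormal marginals moment-matched
to the published per-parameter mean +/- SD), a near-collinear salinity
block (EC, salinity, NaCl, Cl-, TH, turbidity, Ca2+ share a common
log-scale correlation, with TDS a fixed fraction of EC plus noise),
slightly alkaline pH, negative redox potential, and weakly coupled
heavy metals with occasional exceedance spikes that create the
hotspot-station behaviour driving the risk indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import METALS, PARAMETERS, SampleTable
from .fixtures import paper_fixture

#: Parameters drawn jointly on the log scale (TDS is derived from EC).
SALINITY_BLOCK = ("ec", "salinity", "nacl", "cl", "th", "turbidity", "ca")

#: Independently lognormal parameters.
INDEPENDENT = ("alkalinity", "free_co2")


def _default_targets() -> dict[str, tuple[float, float]]:
    """(mean, sd) targets per parameter, from the published descriptives."""
    t2 = paper_fixture("table2")
    out = {}
    for p in SALINITY_BLOCK + INDEPENDENT + METALS + ("tds",):
        out[p] = (float(t2.loc[p, "mean"]), float(t2.loc[p, "sd"]))
    return out


def _default_spikes() -> dict[str, tuple[float, float]]:
    """Per-metal (probability, factor) of an exceedance spike.

    The factor is the ratio of the published maximum to the published
    mean, so that spiked draws land near the observed hotspot maxima.
    """
    t2 = paper_fixture("table2")
    return {m: (0.05, float(t2.loc[m, "max"]) / float(t2.loc[m, "mean"])) for m in METALS}


@dataclass
class SynthConfig:
    """Generator settings; defaults reproduce the study conditions."""

    n_stations: int = 20
    #: lon_min, lon_max, lat_min, lat_max of the sampling area
    bbox: tuple[float, float, float, float] = (90.18, 90.23, 22.63, 22.75)
    #: per-parameter (mean, sd) targets on the natural scale
    targets: dict[str, tuple[float, float]] = field(default_factory=_default_targets)
    #: common pairwise correlation of the salinity block on the log scale
    rho: float = 0.95
    #: TDS = tds_ratio * EC * exp(N(0, tds_noise_sd))
    tds_ratio: float = 0.64
    tds_noise_sd: float = 0.02
    ph_band: tuple[float, float] = (7.24, 8.2)
    orp_mean: float = -42.13
    orp_sd: float = 10.62
    #: per-metal (spike probability, spike factor)
    metal_spikes: dict[str, tuple[float, float]] = field(default_factory=_default_spikes)

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if self.n_stations < 4:
            raise ValueError("need at least 4 stations")
        for p, (mean, sd) in self.targets.items():
            if mean <= 0 or sd <= 0:
                raise ValueError(f"non-positive scale for {p}: mean={mean}, sd={sd}")
        for m, (prob, factor) in self.metal_spikes.items():
            if not 0 <= prob <= 1 or factor <= 0:
                raise ValueError(f"invalid spike settings for {m}")

    def with_rho(self, rho: float) -> "SynthConfig":
        return replace(self, rho=rho)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a lognormal: E[X] = mean and SD[X] = sd exactly."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def generate(config: SynthConfig, seed: int) -> SampleTable:
    """Draw a deterministic synthetic sample table.

    Raises ``ValueError`` if the implied log-scale covariance of the
    salinity block is not positive definite.
    """
    rng = np.random.default_rng(seed)
    n = config.n_stations
    cols: dict[str, np.ndarray] = {}

    lon_min, lon_max, lat_min, lat_max = config.bbox
    cols["longitude"] = rng.uniform(lon_min, lon_max, n)
    cols["latitude"] = rng.uniform(lat_min, lat_max, n)

    # correlated salinity block on the log scale
    mus, sigmas = zip(*(_lognormal_params(*config.targets[p]) for p in SALINITY_BLOCK))
    sigmas = np.asarray(sigmas)
    cov = config.rho * np.outer(sigmas, sigmas)
    np.fill_diagonal(cov, sigmas**2)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("implied log-scale covariance is not positive definite") from exc
    z = rng.standard_normal((n, len(SALINITY_BLOCK)))
    block = np.exp(np.asarray(mus) + z @ chol.T)
    for j, p in enumerate(SALINITY_BLOCK):
        cols[p] = block[:, j]

    cols["tds"] = config.tds_ratio * cols["ec"] * np.exp(
        rng.normal(0.0, config.tds_noise_sd, n)
    )

    for p in INDEPENDENT:
        mu, sigma = _lognormal_params(*config.targets[p])
        cols[p] = rng.lognormal(mu, sigma, n)

    cols["pH"] = rng.uniform(*config.ph_band, n)
    # truncated-above-zero redox potential
    orp = rng.normal(config.orp_mean, config.orp_sd, n)
    cols["orp"] = np.minimum(orp, -1e-3)

    for m in METALS:
        prob, factor = config.metal_spikes[m]
        mean, sd = config.targets[m]
        # rescale the base mean so spikes leave the configured mean intact
        base_mean = mean / (1.0 + prob * (factor - 1.0))
        mu, sigma = _lognormal_params(base_mean, sd * base_mean / mean)
        draws = rng.lognormal(mu, sigma, n)
        spikes = rng.random(n) < prob
        cols[m] = np.where(spikes, draws * factor, draws)

    index = pd.Index([f"SYN-{i + 1}" for i in range(n)], name="station_id")
    order = ["longitude", "latitude"] + list(PARAMETERS)
    return SampleTable(pd.DataFrame(cols, index=index)[order])
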