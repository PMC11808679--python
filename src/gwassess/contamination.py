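"""Contamination factor and the six aggregate contamination indices.

Per station, the contamination factor CF_i = M_i / S_i compares each
measured parameter against its guideline value. The aggregates are

* TCI, the sum of the CFs;
* MCI = TCI / n, the per-parameter mean (n = 15 parameters with a
  standard: every measured parameter except the redox potential);
* PLI, the geometric mean of the CFs;
* NPI = sqrt((CF_max^2 + CF_mean^2) / 2), the Nemerow form emphasising
  the single worst contaminant;
* MPI, the sum of metal concentration / maximum-allowed ratios over the
  four heavy metals; and
* WCI, which folds the integer class weights (Aw) of the five indices
  above into a single [0, 1] score.

Each index maps to a pollution level ("very low" ... "very high") and
an integer weight Aw via the classification rubric. The default WCI
aggregator is sum(Aw) / (5 * number of indices with Aw > 0); the exact
aggregator behind the published WCI column is under-determined (no
linear weighting of the printed Aw values reproduces it), so the
aggregator is pluggable and the default makes no claim to reproduce
that column.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .data_model import METALS, GuidelineRegistry, SampleTable, Standard

logger = logging.getLogger(__name__)

#: Parameters entering the CF basis: all measured parameters but ORP.
CF_PARAMETERS = tuple(
    p for p in ("pH", "alkalinity", "free_co2", "ec", "salinity", "tds", "th",
                "turbidity", "nacl", "ca", "cl", "cd", "cu", "ni", "pb")
)

INDEX_IDS = ("tci", "mci", "pli", "npi", "mpi")

#: Floor substituted for zero CF terms inside the geometric mean.
PLI_ZERO_FLOOR = 1e-6


@dataclass(frozen=True)
class Rubric:
    """Ordered half-open class bins [lo, hi) for one index."""

    uppers: tuple[float, ...]   # finite upper bounds; one fewer than labels
    labels: tuple[str, ...]
    aw: tuple[int, ...]

    def classify(self, value: float) -> tuple[str, int]:
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return "not assessed", 0
        i = int(np.searchsorted(self.uppers, value, side="right"))
        return self.labels[i], self.aw[i]


class RubricSet:
    """Classification rubrics for every index, loadable from YAML."""

    def __init__(self, rubrics: Mapping[str, Rubric]):
        self._rubrics = dict(rubrics)

    @classmethod
    def default(cls) -> "RubricSet":
        raw = yaml.safe_load(
            resources.files("gwassess.data").joinpath("rubrics.yaml").read_text()
        )
        rubrics = {}
        for index, bins in raw.items():
            uppers = tuple(float(b[0]) for b in bins[:-1])
            if bins[-1][0] is not None:
                raise ValueError(f"last bin of {index} must be unbounded")
            if any(a >= b for a, b in zip(uppers, uppers[1:])):
                raise ValueError(f"bounds for {index} not strictly increasing")
            rubrics[index] = Rubric(
                uppers=uppers,
                labels=tuple(str(b[1]) for b in bins),
                aw=tuple(int(b[2]) for b in bins),
            )
        return cls(rubrics)

    def classify(self, value: float, index: str) -> tuple[str, int]:
        if index not in self._rubrics:
            raise KeyError(f"no rubric for index {index!r}")
        return self._rubrics[index].classify(value)


def contamination_factor(value: float, standard: Standard | float) -> float:
    """CF = measured / standard; an interval standard uses its upper bound."""
    limit = standard.upper if isinstance(standard, Standard) else float(standard)
    if limit <= 0:
        raise ValueError(f"standard must be positive, got {limit}")
    if value < 0:
        raise ValueError(f"concentration must be non-negative, got {value}")
    return value / limit


def tci(cf: Sequence[float]) -> float:
    """Total contamination index: sum of the contamination factors."""
    cf = np.asarray(cf, dtype=float)
    if cf.size == 0:
        raise ValueError("empty CF vector")
    return float(cf.sum())


def mci(cf: Sequence[float], n: int | None = None) -> float:
    """Modified contamination index: TCI / n (n defaults to len(cf))."""
    cf = np.asarray(cf, dtype=float)
    if cf.size == 0:
        raise ValueError("empty CF vector")
    return float(cf.sum() / (n if n is not None else cf.size))


def pli(cf: Sequence[float], zero_floor: float = PLI_ZERO_FLOOR) -> float:
    """Pollution load index: geometric mean of the CFs.

    Zero terms would annihilate the geometric mean, so they are replaced
    by ``zero_floor`` with a warning.
    """
    cf = np.asarray(cf, dtype=float)
    if cf.size == 0:
        raise ValueError("empty CF vector")
    if (cf == 0).any():
        warnings.warn(f"zero CF terms replaced by floor {zero_floor} in PLI", stacklevel=2)
        cf = np.where(cf == 0, zero_floor, cf)
    return float(np.exp(np.mean(np.log(cf))))


def npi(cf: Sequence[float]) -> float:
    """Nemerow pollution index: sqrt((CF_max^2 + CF_mean^2) / 2)."""
    cf = np.asarray(cf, dtype=float)
    if cf.size == 0:
        raise ValueError("empty CF vector")
    return float(np.sqrt((cf.max() ** 2 + cf.mean() ** 2) / 2.0))


def mpi(metals: Mapping[str, float], cmax: Mapping[str, float]) -> float:
    """Metal pollution index: sum of C_i / C_max over the heavy metals.

    Metals missing from ``metals`` (or NaN) are skipped with a warning;
    an empty intersection yields NaN (undefined).
    """
    terms = []
    for metal, conc in metals.items():
        if conc is None or (isinstance(conc, float) and np.isnan(conc)):
            continue
        if metal not in cmax:
            raise KeyError(f"no maximum-allowed concentration for {metal!r}")
        if cmax[metal] <= 0:
            raise ValueError(f"limit for {metal!r} must be positive")
        terms.append(conc / cmax[metal])
    if not terms:
        return float("nan")
    if len(terms) < len(cmax):
        logger.warning("MPI computed over %d of %d metals", len(terms), len(cmax))
    return float(sum(terms))


def wci(aw: Sequence[int],
        aggregator: Callable[[Sequence[int]], float] | None = None) -> float:
    """Weighted contamination index over the five per-index Aw weights.

    Default: sum(Aw) / (5 * number of active indices), where an index is
    active when its Aw > 0; all-zero weights leave the WCI undefined
    (NaN). Supply ``aggregator`` to use a different weighting.
    """
    aw = list(aw)
    if len(aw) != len(INDEX_IDS):
        raise ValueError(f"expected {len(INDEX_IDS)} Aw values, got {len(aw)}")
    if aggregator is not None:
        return float(aggregator(aw))
    active = sum(1 for a in aw if a > 0)
    if active == 0:
        return float("nan")
    return float(sum(aw) / (5.0 * active))


def classify(value: float, index: str, rubric: RubricSet | None = None) -> tuple[str, int]:
    """Pollution level label and Aw weight for one index value."""
    return (rubric or RubricSet.default()).classify(value, index)


def cf_standards(registry: GuidelineRegistry, authority: str = "BDWS",
                 fallback: str = "WHO") -> dict[str, float]:
    """Scalar CF denominators for the 15-parameter basis.

    The national (BDWS) standards are the default denominator set;
    free CO2, which BDWS does not regulate, falls back to the WHO value
    so the 15-parameter basis stays complete. Interval standards
    collapse to their upper bound.
    """
    limits = registry.upper_limits(authority, CF_PARAMETERS, fallback=fallback)
    missing = [p for p in CF_PARAMETERS if p not in limits]
    if missing:
        raise ValueError(f"no standard available for {missing} under {authority} (+{fallback})")
    return limits


def assess(samples: SampleTable, registry: GuidelineRegistry | None = None,
           authority: str = "BDWS", rubric: RubricSet | None = None,
           wci_aggregator: Callable[[Sequence[int]], float] | None = None,
           mpi_authority: str = "BDWS") -> pd.DataFrame:
    """Full contamination sheet: CFs, six indices, classes and weights.

    One row per station; stations without metal measurements get an
    undefined MPI carrying Aw 0 (reported as pollution level "very low",
    mirroring how the study prints such rows).
    """
    registry = registry or GuidelineRegistry.default()
    rubric = rubric or RubricSet.default()
    limits = cf_standards(registry, authority)
    cmax = registry.upper_limits(mpi_authority, METALS)

    rows = []
    for station in samples.station_ids:
        values = samples.data.loc[station]
        cf_vec: dict[str, float] = {}
        for p in CF_PARAMETERS:
            v = values.get(p)
            if v is None or pd.isna(v):
                continue
            cf_vec[f"cf_{p}"] = contamination_factor(float(v), limits[p])
        cf = list(cf_vec.values())
        row: dict[str, object] = {"station": station, **cf_vec}
        row["tci"] = tci(cf)
        row["mci"] = mci(cf)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            row["pli"] = pli(cf)
        row["npi"] = npi(cf)
        metal_values = {m: float(values[m]) for m in METALS
                        if m in values.index and not pd.isna(values[m])}
        row["mpi"] = mpi(metal_values, cmax) if metal_values else float("nan")
        aw = []
        for idx in INDEX_IDS:
            label, weight = rubric.classify(row[idx], idx)
            if idx == "mpi" and np.isnan(row["mpi"]):
                label, weight = "very low", 0
            row[f"{idx}_class"], row[f"{idx}_aw"] = label, weight
            aw.append(weight)
        row["wci"] = wci(aw, aggregator=wci_aggregator)
        row["wci_class"], _ = rubric.classify(row["wci"], "wci")
        rows.append(row)
    return pd.DataFrame(rows).set_index("station")
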