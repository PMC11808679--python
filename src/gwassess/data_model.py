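"""Domain types for per-station groundwater chemistry.

The central container is :class:`SampleTable`, a thin validated wrapper
around a :class:`pandas.DataFrame` holding one row per sampling station
(tube well) with coordinates and measured parameters in canonical units:
mg/L for every solute, μS/cm for electrical conductivity, ppt for
salinity, FTU for turbidity, mV for the oxidation-reduction potential,
and unitless pH. Guideline values (WHO / USEPA / Indian / Bangladeshi
drinking-water standards) live in :class:`GuidelineRegistry`; a scalar
standard is an upper bound, an interval standard (pH, alkalinity, ...)
is two-sided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Canonical parameter catalogue: name -> canonical unit.
PARAMETERS: dict[str, str] = {
    "pH": "-",
    "alkalinity": "mg/L",
    "free_co2": "mg/L",
    "ec": "uS/cm",
    "orp": "mV",
    "salinity": "ppt",
    "tds": "mg/L",
    "th": "mg/L",
    "turbidity": "FTU",
    "nacl": "mg/L",
    "ca": "mg/L",
    "cl": "mg/L",
    "cd": "mg/L",
    "cu": "mg/L",
    "ni": "mg/L",
    "pb": "mg/L",
}

#: The four heavy metals measured by atomic absorption.
METALS: tuple[str, ...] = ("cd", "cu", "ni", "pb")

#: Multiplicative factors into the canonical unit of each dimension.
UNIT_FACTORS: dict[str, float] = {
    "mg/L": 1.0,
    "ug/L": 1e-3,
    "g/L": 1e3,
    "uS/cm": 1.0,
    "mS/cm": 1e3,
    "ppt": 1.0,
    "FTU": 1.0,
    "NTU": 1.0,
    "mV": 1.0,
    "-": 1.0,
}

AUTHORITIES: tuple[str, ...] = ("WHO", "USEPA", "ISDW", "BDWS")


class DataModelError(ValueError):
    """Raised on invalid samples, units or standards."""


@dataclass(frozen=True)
class Standard:
    """A guideline value: scalar upper bound or closed interval."""

    lo: float | None
    hi: float

    @property
    def is_interval(self) -> bool:
        return self.lo is not None

    @property
    def upper(self) -> float:
        return self.hi

    def contains(self, value: float) -> bool:
        """True when ``value`` complies with this standard."""
        if self.is_interval:
            return self.lo <= value <= self.hi
        return value <= self.hi

    def __post_init__(self) -> None:
        if self.is_interval:
            if not self.lo < self.hi:
                raise DataModelError(f"interval standard needs lo < hi, got [{self.lo}, {self.hi}]")
        elif self.hi <= 0:
            raise DataModelError(f"scalar standard must be positive, got {self.hi}")


class GuidelineRegistry:
    """Standards per (authority, parameter), with explicit 'no standard'.

    ``get`` returns ``None`` where an authority publishes no value for a
    parameter (the oxidation-reduction potential has no standard under
    any authority). Custom authorities can be registered at run time.
    """

    def __init__(self, table: Mapping[str, Mapping[str, Standard]], provenance: str = ""):
        self._table = {a: dict(p) for a, p in table.items()}
        self.provenance = provenance

    @classmethod
    def default(cls) -> "GuidelineRegistry":
        """Registry transcribing the four shipped authorities."""
        raw = yaml.safe_load(_read_data("standards.yaml"))
        table: dict[str, dict[str, Standard]] = {}
        for authority, params in raw.items():
            table[authority] = {}
            for param, value in params.items():
                if param not in PARAMETERS:
                    raise DataModelError(f"unknown parameter {param!r} in standards file")
                if isinstance(value, list):
                    table[authority][param] = Standard(float(value[0]), float(value[1]))
                else:
                    table[authority][param] = Standard(None, float(value))
        return cls(table, provenance="shipped defaults (WHO/USEPA/ISDW/BDWS)")

    @property
    def authorities(self) -> list[str]:
        return list(self._table)

    def get(self, authority: str, parameter: str) -> Standard | None:
        if authority not in self._table:
            raise DataModelError(f"unknown authority {authority!r}")
        return self._table[authority].get(parameter)

    def set(self, authority: str, parameter: str, standard: Standard | None) -> None:
        self._table.setdefault(authority, {})
        if standard is None:
            self._table[authority].pop(parameter, None)
        else:
            self._table[authority][parameter] = standard

    def upper_limits(self, authority: str, parameters: Iterable[str] | None = None,
                     fallback: str | None = None) -> dict[str, float]:
        """Scalar limits (interval standards collapse to their upper bound).

        Parameters without a standard under ``authority`` fall back to
        ``fallback`` when given, else are omitted.
        """
        params = list(parameters) if parameters is not None else list(PARAMETERS)
        out: dict[str, float] = {}
        for p in params:
            std = self.get(authority, p)
            if std is None and fallback is not None:
                std = self.get(fallback, p)
            if std is not None:
                out[p] = std.upper
        return out


def _read_data(name: str) -> str:
    return resources.files("gwassess.data").joinpath(name).read_text()


META_COLUMNS = ("longitude", "latitude")


class SampleTable:
    """Validated per-station concentrations plus coordinates.

    ``data`` is indexed by unique station id with ``longitude`` and
    ``latitude`` columns followed by parameter columns in canonical
    units; missing measurements are NaN. ``metals_measured`` flags the
    stations where at least one of the four metals was analysed (in the
    study only 9 of 20 stations have metal data).
    """

    def __init__(self, data: pd.DataFrame):
        self.data = self._validate(data.copy())

    @staticmethod
    def _validate(df: pd.DataFrame) -> pd.DataFrame:
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise DataModelError(f"duplicate station ids: {dupes}")
        unknown = [c for c in df.columns if c not in PARAMETERS and c not in META_COLUMNS]
        if unknown:
            raise DataModelError(f"unknown parameter columns: {unknown}")
        for col in df.columns:
            if col in ("pH",) or col in META_COLUMNS:
                continue
            if col == "orp":  # redox potential is legitimately negative
                continue
            if col in PARAMETERS:
                bad = df.index[df[col] < 0]
                if len(bad):
                    raise DataModelError(
                        f"negative concentration in column {col!r} at station(s) {bad.tolist()}"
                    )
        if "pH" in df.columns:
            bad = df.index[(df["pH"] <= 0) | (df["pH"] >= 14)]
            if len(bad):
                raise DataModelError(f"pH out of (0, 14) at station(s) {bad.tolist()}")
        return df

    @property
    def station_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def parameters(self) -> list[str]:
        return [c for c in self.data.columns if c in PARAMETERS]

    @property
    def coordinates(self) -> pd.DataFrame:
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise DataModelError(f"spatial operation requested but columns missing: {missing}")
        coords = self.data[list(META_COLUMNS)]
        if not np.isfinite(coords.to_numpy(dtype=float)).all():
            raise DataModelError("non-finite coordinates")
        return coords

    @property
    def metals_measured(self) -> pd.Series:
        present = [m for m in METALS if m in self.data.columns]
        if not present:
            return pd.Series(False, index=self.data.index, name="metals_measured")
        return self.data[present].notna().any(axis=1).rename("metals_measured")

    def values_of(self, parameter: str) -> pd.Series:
        if parameter not in self.data.columns:
            raise DataModelError(f"parameter {parameter!r} not in table")
        return self.data[parameter]

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SampleTable) and self.data.equals(other.data)


def load_samples(path: str | Path, unit_map: Mapping[str, str] | None = None) -> SampleTable:
    """Read a one-row-per-station CSV and convert to canonical units.

    The header is ``station_id,longitude,latitude,<param>,...``; an empty
    cell is a missing measurement. ``unit_map`` declares the unit of any
    column not already canonical (e.g. ``{"cd": "ug/L"}``).
    """
    df = pd.read_csv(path, dtype={"station_id": str})
    if "station_id" not in df.columns:
        raise DataModelError("CSV must have a station_id column")
    df = df.set_index("station_id")
    for col, unit in (unit_map or {}).items():
        if col not in df.columns:
            raise DataModelError(f"unit declared for absent column {col!r}")
        if unit not in UNIT_FACTORS:
            raise DataModelError(f"unknown unit {unit!r} for column {col!r}")
        df[col] = df[col] * UNIT_FACTORS[unit]
    return SampleTable(df)


def write_samples(samples: SampleTable, path: str | Path, float_format: str = "%.6g") -> None:
    samples.data.to_csv(path, index_label="station_id", float_format=float_format)


def describe(samples: SampleTable) -> pd.DataFrame:
    """Min / max / mean / sample SD / n per parameter (missing excluded).

    A parameter with fewer than one non-missing value yields NaN summary
    entries rather than zeros; SD uses the n-1 denominator and is 0 for
    a single observation only if pandas defines it (NaN otherwise).
    """
    rows = {}
    for p in samples.parameters:
        s = samples.values_of(p).dropna().astype(float)
        rows[p] = {
            "min": s.min() if len(s) else np.nan,
            "max": s.max() if len(s) else np.nan,
            "mean": s.mean() if len(s) else np.nan,
            "sd": s.std(ddof=1) if len(s) > 1 else (0.0 if len(s) == 1 else np.nan),
            "n": len(s),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "parameter"
    return out


def compliance(samples: SampleTable, registry: GuidelineRegistry,
               authorities: Iterable[str] | None = None, decimals: int | None = None) -> pd.DataFrame:
    """Percent of samples within each authority's standard, per parameter.

    Missing measurements are excluded from numerator and denominator.
    The ``mean`` column averages only over authorities that publish a
    standard for the parameter; a parameter with no standard anywhere
    (ORP) has an all-NaN row.
    """
    auths = list(authorities) if authorities is not None else list(registry.authorities)
    out = pd.DataFrame(index=pd.Index(samples.parameters, name="parameter"),
                       columns=auths + ["mean"], dtype=float)
    for p in samples.parameters:
        values = samples.values_of(p).dropna().astype(float)
        if values.empty:
            logger.warning("compliance: no data for parameter %s", p)
        pcts = []
        for a in auths:
            std = registry.get(a, p)
            if std is None or values.empty:
                continue
            pct = 100.0 * sum(std.contains(v) for v in values) / len(values)
            if decimals is not None:
                pct = round(pct, decimals)
            out.loc[p, a] = pct
            pcts.append(pct)
        if pcts:
            m = float(np.mean(pcts))
            out.loc[p, "mean"] = round(m, decimals) if decimals is not None else m
    return out
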