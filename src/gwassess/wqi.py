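"""Weighted-arithmetic water quality index.

Each parameter gets a quality rating

    Q_i = 100 * |V_m - V_i| / |V_s - V_i|

relative to its guideline value V_s (WHO by default) and ideal value
V_i (0 for every parameter except pH, whose ideal is the neutral 7),
and a relative weight W_i = 1 / V_s inversely proportional to the
standard. The station index is the weighted mean

    WQI = sum(W_i * Q_i) / sum(W_i)

graded Excellent [0, 25], Good (25, 50], Poor (50, 75], Very poor
(75, 100] and Unsuitable (> 100). The absolute-value form keeps Q_i
non-negative for sub-ideal pH.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data_model import GuidelineRegistry, SampleTable

GRADE_UPPERS = (25.0, 50.0, 75.0, 100.0)
GRADE_LABELS = ("Excellent", "Good", "Poor", "Very poor", "Unsuitable")

#: Ideal values V_i; every parameter not listed has ideal 0.
IDEAL_VALUES: dict[str, float] = {"pH": 7.0}


def quality_rating(vm: float, vs: float, vi: float = 0.0) -> float:
    """Q_i = 100 |V_m - V_i| / |V_s - V_i|; errors when V_s == V_i."""
    if vs == vi:
        raise ValueError("standard equals ideal value; rating undefined")
    return 100.0 * abs(vm - vi) / abs(vs - vi)


def relative_weight(vs: float) -> float:
    """W_i = 1 / V_s."""
    if vs <= 0:
        raise ValueError(f"standard must be positive, got {vs}")
    return 1.0 / vs


def grade(value: float) -> tuple[int, str]:
    """Integer grade 1-5 and label; uppers are inclusive ([0,25] is grade 1)."""
    if value < 0 or np.isnan(value):
        raise ValueError(f"WQI must be a non-negative number, got {value}")
    i = int(np.searchsorted(GRADE_UPPERS, value, side="left"))
    return i + 1, GRADE_LABELS[i]


def wqi_standards(registry: GuidelineRegistry, authority: str = "WHO") -> dict[str, float]:
    """Per-parameter V_s values for the index.

    For an interval standard the bound farther from the ideal value is
    used (pH -> 8.5, alkalinity -> 600); parameters without a standard
    under the authority (e.g. the redox potential) are excluded.
    """
    out: dict[str, float] = {}
    for p in registry_parameters(registry, authority):
        std = registry.get(authority, p)
        vi = IDEAL_VALUES.get(p, 0.0)
        if std.is_interval:
            out[p] = max((std.lo, std.hi), key=lambda b: abs(b - vi))
        else:
            out[p] = std.hi
    return out


def registry_parameters(registry: GuidelineRegistry, authority: str) -> list[str]:
    from .data_model import PARAMETERS

    return [p for p in PARAMETERS if registry.get(authority, p) is not None]


def compute(samples: SampleTable, registry: GuidelineRegistry | None = None,
            authority: str = "WHO", detail: bool = False) -> pd.DataFrame:
    """Station WQI table: index value, grade and label per station.

    With ``detail=True`` the per-parameter ratings Q_i and weights W_i
    are appended as ``qi_*`` / ``wi_*`` columns. Missing measurements
    drop out of both sums; a station with no usable parameter raises.
    """
    registry = registry or GuidelineRegistry.default()
    vs = wqi_standards(registry, authority)
    rows = []
    for station in samples.station_ids:
        values = samples.data.loc[station]
        num = den = 0.0
        row: dict[str, object] = {"station": station}
        used = 0
        for p, std in vs.items():
            v = values.get(p)
            if v is None or pd.isna(v):
                continue
            vi = IDEAL_VALUES.get(p, 0.0)
            qi = quality_rating(float(v), std, vi)
            wi = relative_weight(std)
            num += wi * qi
            den += wi
            used += 1
            if detail:
                row[f"qi_{p}"] = qi
                row[f"wi_{p}"] = wi
        if used == 0:
            raise ValueError(f"station {station} has no parameter with a {authority} standard")
        value = num / den
        g, label = grade(value)
        row.update(wqi=value, grade=g, label=label)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("station")
    front = ["wqi", "grade", "label"]
    return out[front + [c for c in out.columns if c not in front]]


def grade_distribution(values: Iterable[float] | Mapping[str, float]) -> pd.Series:
    """Percentage of stations in each grade class."""
    if isinstance(values, Mapping):
        values = list(values.values())
    values = list(values)
    if not values:
        raise ValueError("no WQI values")
    labels = [grade(v)[1] for v in values]
    counts = pd.Series(labels).value_counts()
    pct = 100.0 * counts.reindex(GRADE_LABELS, fill_value=0) / len(values)
    pct.index.name = "class"
    return pct.rename("percent")
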