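"""Hakanson-style potential ecological risk of heavy metals in water.

Per metal, the ecological risk score is ERI = TRF * C / S, where TRF is
the metal's toxic response factor (Cd 30; Cu, Ni, Pb 5), C the measured
concentration and S a reference concentration. The station-level
potential ecological risk PER is the sum of the per-metal scores.

Class bounds (half-open, a boundary value takes the upper class):
ERI  < 40 low, 40-80 moderate, 80-160 considerable, 160-320 high,
>= 320 very high; PER < 150 low, 150-300 medium, 300-600 considerable,
>= 600 extreme.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .data_model import METALS, SampleTable

ERI_BOUNDS = (40.0, 80.0, 160.0, 320.0)
ERI_LABELS = ("low", "moderate", "considerable", "high", "very high")
PER_BOUNDS = (150.0, 300.0, 600.0)
PER_LABELS = ("low", "medium", "considerable", "extreme")


@dataclass(frozen=True)
class ToxicityRegistry:
    """Metal toxicity constants shared by the ecological and health stages.

    ``eri_reference`` is the per-metal reference concentration S (mg/L)
    of the ecological-risk ratio — a mixed-authority set (see the
    shipped YAML's provenance note; Cu's 0.05 mg/L matches no authority
    in the guideline registry). ``rfd_*`` are reference doses in
    μg/kg-day, ``csf`` cancer slope factors in kg·day/mg and ``kp``
    dermal permeability coefficients in cm/h.
    """

    trf: dict[str, float]
    eri_reference: dict[str, float]
    rfd_ingestion: dict[str, float]
    rfd_dermal: dict[str, float]
    csf: dict[str, float]
    kp: dict[str, float]

    @classmethod
    def default(cls) -> "ToxicityRegistry":
        raw = yaml.safe_load(
            resources.files("gwassess.data").joinpath("toxicity.yaml").read_text()
        )
        reg = cls(**{k: {m: float(v) for m, v in tab.items()} for k, tab in raw.items()})
        for table_name in ("trf", "eri_reference", "rfd_ingestion", "rfd_dermal", "kp"):
            table = getattr(reg, table_name)
            for metal in METALS:
                if metal not in table or table[metal] <= 0:
                    raise ValueError(f"{table_name} missing or non-positive for {metal}")
        return reg


def eri(conc: float, metal: str, registry: ToxicityRegistry | None = None) -> float:
    """Per-metal ecological risk score TRF * C / S."""
    registry = registry or ToxicityRegistry.default()
    if metal not in registry.trf or metal not in registry.eri_reference:
        raise KeyError(f"no toxicity entry for metal {metal!r}")
    if conc < 0:
        raise ValueError(f"concentration must be non-negative, got {conc}")
    return registry.trf[metal] * conc / registry.eri_reference[metal]


def per(eri_values) -> float:
    """Potential ecological risk: sum of per-metal scores."""
    values = np.asarray(list(eri_values), dtype=float)
    if values.size == 0:
        raise ValueError("empty ERI vector")
    return float(values.sum())


def _classify(value: float, bounds, labels) -> str:
    if value < 0:
        raise ValueError(f"risk score must be non-negative, got {value}")
    return labels[int(np.searchsorted(bounds, value, side="right"))]


def classify_eri(value: float) -> str:
    return _classify(value, ERI_BOUNDS, ERI_LABELS)


def classify_per(value: float) -> str:
    return _classify(value, PER_BOUNDS, PER_LABELS)


def assess(samples: SampleTable, registry: ToxicityRegistry | None = None) -> pd.DataFrame:
    """Per-station ERI per metal, PER and class labels.

    Stations without any metal measurement are omitted; metals missing
    at a station contribute nothing to its PER.
    """
    registry = registry or ToxicityRegistry.default()
    rows = []
    for station in samples.station_ids:
        values = samples.data.loc[station]
        scores = {}
        for m in METALS:
            if m in values.index and not pd.isna(values[m]):
                scores[m] = eri(float(values[m]), m, registry)
        if not scores:
            continue
        row: dict[str, object] = {"station": station}
        for m, s in scores.items():
            row[f"eri_{m}"] = s
            row[f"eri_{m}_class"] = classify_eri(s)
        row["per"] = per(scores.values())
        row["per_class"] = classify_per(row["per"])
        rows.append(row)
    return pd.DataFrame(rows).set_index("station")


def assess_eri_table(eri_table: pd.DataFrame) -> pd.DataFrame:
    """PER and classes from an already-computed per-metal ERI table."""
    out = eri_table.copy().astype(float)
    out["per"] = out.sum(axis=1, skipna=True)
    out["per_class"] = [classify_per(v) for v in out["per"]]
    return out
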