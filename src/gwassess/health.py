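"""USEPA-framework drinking-water health risk.

Exposure runs through two pathways. Ingestion:

    ADI_ing = C * IR * EF * EP / (BW * AT)          [mg/kg-day]

and dermal contact during bathing/washing:

    ADI_der = C * SA * Kp * ET * EF * EP * CF / (BW * AT)

with C the concentration in mg/L, IR the ingestion rate (L/day), EF the
exposure frequency (days/year), EP the exposure period (years), BW body
weight (kg), AT = EP * 365 the averaging time (days) for both the
noncarcinogenic and carcinogenic pathways, SA exposed skin (cm^2), Kp
the dermal permeability (cm/h), ET the exposure time (h/day) and CF a
unit conversion (0.0001 L/cm^3 as tabulated in the source constants;
common practice elsewhere is 0.001 — configurable).

Noncarcinogenic risk: HQ = ADI / RfD with the reference doses tabulated
in μg/kg-day, so the dose is converted mg -> μg once, explicitly;
HI = sum over metals of (HQ_ing + HQ_der), acceptable below 1.
Carcinogenic risk: CRI = ADI_ing * CSF, CRD = ADI_der * CSF,
CR = CRI + CRD; 1e-6 flags a single element, 1e-4 bounds the
multi-element total. Copper carries no slope factor and is excluded
from the carcinogenic sheet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

from .data_model import METALS, SampleTable
from .ecological import ToxicityRegistry

logger = logging.getLogger(__name__)

SINGLE_ELEMENT_LIMIT = 1e-6
TOTAL_CR_LIMIT = 1e-4

COHORT_NAMES = ("child", "adult_male", "adult_female")


@dataclass(frozen=True)
class ExposureCohort:
    """One exposure population (units in the module docstring)."""

    name: str
    ir: float
    ef: float
    ep: float
    bw: float
    sa: float
    et: float
    cf: float = 0.0001
    at: float | None = None  # days; EP*365 unless overridden

    def __post_init__(self) -> None:
        for f in ("ir", "ef", "ep", "bw", "sa", "et", "cf"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive for cohort {self.name}")

    @property
    def averaging_time(self) -> float:
        return self.at if self.at is not None else self.ep * 365.0

    @property
    def dose_coefficient(self) -> float:
        """IR*EF*EP/(BW*AT), the ingestion dose per unit concentration (1/day · L/kg)."""
        return self.ir * self.ef * self.ep / (self.bw * self.averaging_time)


def default_cohorts() -> dict[str, ExposureCohort]:
    raw = yaml.safe_load(
        resources.files("gwassess.data").joinpath("cohorts.yaml").read_text()
    )
    return {name: ExposureCohort(name=name, **params) for name, params in raw.items()}


def adi_ingestion(conc: float, cohort: ExposureCohort) -> float:
    """Average daily intake via ingestion, mg/kg-day (conc in mg/L)."""
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    return conc * cohort.dose_coefficient


def adi_dermal(conc: float, metal: str, cohort: ExposureCohort,
               registry: ToxicityRegistry | None = None) -> float:
    """Average daily intake via dermal absorption, mg/kg-day."""
    registry = registry or ToxicityRegistry.default()
    if metal not in registry.kp:
        raise KeyError(f"no dermal permeability coefficient for {metal!r}")
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    kp = registry.kp[metal]
    return (conc * cohort.sa * kp * cohort.et * cohort.ef * cohort.ep * cohort.cf
            / (cohort.bw * cohort.averaging_time))


def hazard_quotient(adi: float, rfd: float) -> float:
    """HQ = dose / reference dose; ``adi`` in mg/kg-day, ``rfd`` in μg/kg-day."""
    if rfd <= 0:
        raise ValueError("reference dose must be positive")
    return (adi * 1000.0) / rfd


def hazard_index(hq_values) -> float:
    """HI: sum of hazard quotients over metals and pathways."""
    return float(sum(hq_values))


def carcinogenic_risk(conc: float, metal: str, cohort: ExposureCohort,
                      registry: ToxicityRegistry | None = None) -> tuple[float, float, float]:
    """(CRI, CRD, CR) for one metal; raises KeyError without a slope factor."""
    registry = registry or ToxicityRegistry.default()
    if metal not in registry.csf:
        raise KeyError(f"no cancer slope factor for {metal!r}")
    csf = registry.csf[metal]
    cri = adi_ingestion(conc, cohort) * csf
    crd = adi_dermal(conc, metal, cohort, registry) * csf
    return cri, crd, cri + crd


def assess(samples: SampleTable, cohorts: dict[str, ExposureCohort] | None = None,
           registry: ToxicityRegistry | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format per-metal doses/risks plus per-station-cohort totals.

    Returns ``(detail, totals)``: ``detail`` has one row per station x
    cohort x measured metal with ADIs, HQs and (where a slope factor
    exists) CRI/CRD/CR; ``totals`` aggregates HI and total CR per
    station and cohort with acceptability labels.
    """
    registry = registry or ToxicityRegistry.default()
    cohorts = cohorts or default_cohorts()
    detail_rows, total_rows = [], []
    for station in samples.station_ids:
        values = samples.data.loc[station]
        measured = {m: float(values[m]) for m in METALS
                    if m in values.index and not pd.isna(values[m])}
        if not measured:
            continue
        for cname, cohort in cohorts.items():
            hq_sum = 0.0
            cr_sum = 0.0
            any_cr = False
            for metal, conc in measured.items():
                ing = adi_ingestion(conc, cohort)
                der = adi_dermal(conc, metal, cohort, registry)
                hq_ing = hazard_quotient(ing, registry.rfd_ingestion[metal])
                hq_der = hazard_quotient(der, registry.rfd_dermal[metal])
                hq_sum += hq_ing + hq_der
                row = {"station": station, "cohort": cname, "metal": metal,
                       "adi_ing": ing, "adi_der": der,
                       "hq_ing": hq_ing, "hq_der": hq_der}
                if metal in registry.csf:
                    cri, crd, cr = carcinogenic_risk(conc, metal, cohort, registry)
                    row.update(cri=cri, crd=crd, cr=cr,
                               cr_flagged=cr >= SINGLE_ELEMENT_LIMIT)
                    cr_sum += cr
                    any_cr = True
                else:
                    logger.info("metal %s has no slope factor; excluded from CR", metal)
                detail_rows.append(row)
            total_rows.append({
                "station": station, "cohort": cname,
                "hi": hq_sum, "hi_label": "acceptable" if hq_sum < 1 else "unacceptable",
                "total_cr": cr_sum if any_cr else float("nan"),
                "cr_label": ("acceptable" if cr_sum < TOTAL_CR_LIMIT else "unacceptable")
                            if any_cr else "not assessed",
            })
    detail = pd.DataFrame(detail_rows)
    totals = pd.DataFrame(total_rows)
    return detail, totals
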