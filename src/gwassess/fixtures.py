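"""Embedded study tables.

The published study prints its results as six tables: descriptive
statistics with guideline compliance, the contamination-index sheet,
per-metal ecological risk scores, noncarcinogenic and carcinogenic
health risks for three cohorts, and station water-quality-index values
with grades. These are shipped verbatim as small CSVs so every
downstream stage can be exercised and cross-checked without any
download. Station-level raw concentrations for the 11 stations without
metal analyses were never published, so the fixtures cover only what is
printed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

FIXTURE_NAMES = ("table2", "table3", "table4", "table5", "table6", "table7")

#: Printed summary rows of the ecological-risk table (not recomputed).
TABLE4_PRINTED_SUMMARY = {
    "minimum": {"cd": 60, "cu": 0.1, "ni": 2.5, "pb": 45},
    "maximum": {"cd": 1290, "cu": 2, "ni": 60, "pb": 135.5},
    "mean": {"cd": 264.4, "cu": 0.76, "ni": 36.1, "pb": 106.7},
}

#: Printed summary rows of the carcinogenic-risk table (child cohort).
TABLE6_PRINTED_CHILD_SUMMARY = {
    "minimum": {"cd": 2.20e-3, "ni": 2.04e-3, "pb": 4.60e-5, "cr": 5.25e-3},
    "maximum": {"cd": 4.73e-2, "ni": 2.45e-2, "pb": 1.39e-4, "cr": 4.94e-2},
    "mean": {"cd": 9.70e-3, "ni": 1.64e-2, "pb": 1.09e-4, "cr": 2.44e-2},
}


def paper_fixture(name: str) -> pd.DataFrame:
    """Return one of the printed study tables, values verbatim.

    ``table2`` is indexed by parameter; the others by station id.
    Interval standards in ``table2`` appear as ``"lo-hi"`` strings, and
    an empty cell means the value was not printed (no standard, or a
    metal excluded from a column).
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    path = resources.files("gwassess.data.fixtures").joinpath(f"{name}.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    index_col = "parameter" if name == "table2" else "station"
    return df.set_index(index_col)


def table4_concentrations(registry=None) -> pd.DataFrame:
    """Metal concentrations (mg/L) implied by the ecological-risk table.

    The study prints per-metal risk scores ERI = TRF * C / Si rather than
    the raw concentrations for the nine metal stations; inverting with
    the shipped toxic response factors and reference standards recovers
    C = ERI * Si / TRF. The recovered extrema and means agree with the
    printed descriptive statistics (e.g. Cd 0.006-0.129 mg/L, mean
    0.026 +/- 0.038).
    """
    from .ecological import ToxicityRegistry

    reg = registry or ToxicityRegistry.default()
    eri = paper_fixture("table4")
    conc = eri.copy().astype(float)
    for metal in conc.columns:
        conc[metal] = eri[metal] * reg.eri_reference[metal] / reg.trf[metal]
    return conc
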