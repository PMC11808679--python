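"""Contamination factor and aggregate indices."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwassess.contamination import (
    RubricSet,
    assess,
    cf_standards,
    classify,
    contamination_factor,
    mci,
    mpi,
    npi,
    pli,
    tci,
    wci,
)
from gwassess.data_model import Standard
from gwassess.fixtures import paper_fixture

cf_vectors = st.lists(st.floats(0.01, 50.0), min_size=1, max_size=6)


class TestElementaryIndices:
    def test_contamination_factor_is_the_ratio(self):
        assert contamination_factor(0.129, 0.005) == pytest.approx(25.8)
        assert contamination_factor(3.0, 3.0) == 1.0
        assert contamination_factor(0.0, 5.0) == 0.0
        # interval standards collapse to their upper bound
        assert contamination_factor(8.2, Standard(6.5, 8.5)) == pytest.approx(8.2 / 8.5)
        with pytest.raises(ValueError):
            contamination_factor(1.0, 0.0)

    def test_tci_mci_published_rows(self):
        # the sheet's total / modified pair is linked by the 15-parameter basis
        assert 36.57 / 15 == pytest.approx(2.438, abs=5e-4)
        assert round(mci([36.57 / 15] * 15, n=15), 2) == 2.44
        assert mci([17.72 / 15] * 15) == pytest.approx(1.181, abs=5e-4)
        assert tci([1.0] * 15) == 15.0 and mci([1.0] * 15) == 1.0

    def test_pli_geometric_mean(self):
        assert pli([4.0, 1.0]) == pytest.approx(2.0)
        assert pli([1.0] * 15) == pytest.approx(1.0)
        assert pli([0.5, 2.0, 1.0]) == pytest.approx(1.0)
        with pytest.warns(UserWarning):
            assert pli([0.0, 1.0]) == pytest.approx(1e-3, rel=1e-6)

    def test_npi_nemerow_form(self):
        assert npi([1.0, 1.0]) == pytest.approx(1.0)
        # max 5.17 with mean 2.438 reproduces the published BS-16 value
        assert math.sqrt((5.17**2 + 2.438**2) / 2) == pytest.approx(4.04, abs=5e-3)
        assert npi([3.0]) == pytest.approx(3.0)

    def test_mpi_ratio_sum(self, registry):
        cmax = {"cd": 0.005, "cu": 1.0, "ni": 0.1, "pb": 0.05}
        at_limits = {m: c for m, c in cmax.items()}
        assert mpi(at_limits, cmax) == pytest.approx(4.0)
        assert mpi({"cd": 0.01, "cu": 0.0, "ni": 0.0, "pb": 0.0},
                   {"cd": 0.005, "cu": 1.0, "ni": 0.1, "pb": 0.05}) == pytest.approx(2.0)
        assert np.isnan(mpi({}, cmax))

    def test_wci_default_aggregator(self):
        assert wci([5, 5, 5, 5, 5]) == pytest.approx(1.0)
        assert wci([1, 1, 1, 1, 1]) == pytest.approx(0.2)
        assert wci([2, 1, 2, 2, 0]) == pytest.approx(7 / 20)
        assert np.isnan(wci([0, 0, 0, 0, 0]))
        assert wci([1, 1, 1, 1, 1], aggregator=sum) == 5


class TestClassification:
    @pytest.mark.parametrize("value,index,expected", [
        (7.08, "tci", ("low", 2)),
        (1.67, "pli", ("high", 4)),
        (0.99, "npi", ("very low", 1)),
        (8.0, "tci", ("medium", 3)),      # boundary takes the upper class
        (0.2, "wci", ("medium", 0)),
        (float("nan"), "mpi", ("not assessed", 0)),
    ])
    def test_half_open_lookup(self, value, index, expected):
        assert classify(value, index) == expected

    def test_published_sheet_classes_reproduced(self):
        """Labels and weights recomputed from the printed index values."""
        rubric = RubricSet.default()
        t3 = paper_fixture("table3")
        for idx in ("tci", "npi"):
            for station, row in t3.iterrows():
                label, aw = rubric.classify(float(row[idx]), idx)
                assert label == row[f"{idx}_class"], (station, idx)
                assert aw == row[f"{idx}_aw"], (station, idx)


class TestProperties:
    @given(cf_vectors)
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_oracle_equivalence(self, cf):
        """Brute-force recomputation of every aggregate index."""
        assert tci(cf) == pytest.approx(sum(cf))
        assert mci(cf) == pytest.approx(sum(cf) / len(cf))
        product = 1.0
        for v in cf:
            product *= v
        assert pli(cf) == pytest.approx(product ** (1 / len(cf)), rel=1e-9)
        mx, mean = max(cf), sum(cf) / len(cf)
        assert npi(cf) == pytest.approx(math.sqrt((mx**2 + mean**2) / 2))

    @given(cf_vectors)
    @settings(deadline=None, derandomize=True)
    def test_am_gm_and_nemerow_bounds(self, cf):
        assert pli(cf) <= mci(cf) + 1e-9
        mx, mean = max(cf), sum(cf) / len(cf)
        assert mx / math.sqrt(2) - 1e-9 <= npi(cf) <= mx + 1e-9

    @given(cf_vectors, st.floats(0.1, 10.0))
    @settings(deadline=None, derandomize=True)
    def test_scale_invariance(self, cf, k):
        """Scaling every concentration and standard together changes nothing."""
        scaled = [contamination_factor(v * k, k) for v in cf]
        assert tci(scaled) == pytest.approx(tci([contamination_factor(v, 1.0) for v in cf]))

    @given(cf_vectors, st.integers(0, 5), st.floats(0.01, 5.0))
    @settings(deadline=None, derandomize=True)
    def test_monotone_in_any_concentration(self, cf, pos, bump):
        i = pos % len(cf)
        bigger = list(cf)
        bigger[i] += bump
        for f in (tci, mci, npi):
            assert f(bigger) >= f(cf) - 1e-12


class TestAssess:
    def test_station_sheet_structure(self, synthetic_samples, registry):
        sheet = assess(synthetic_samples, registry)
        assert len(sheet) == 20
        np.testing.assert_allclose(sheet["tci"], sheet["mci"] * 15, rtol=1e-12)
        assert (sheet["pli"] <= sheet["mci"] + 1e-9).all()
        assert sheet["wci"].between(0, 1).all()

    def test_fifteen_parameter_basis(self, registry):
        limits = cf_standards(registry)
        assert len(limits) == 15 and "orp" not in limits
        assert limits["free_co2"] == 10.0  # national set lacks it; WHO fills in

    def test_station_without_metals_gets_zero_weight_mpi(self, tiny_samples, registry):
        sheet = assess(tiny_samples, registry)
        row = sheet.loc["C"]  # no metal measurements at this station
        assert np.isnan(row["mpi"])
        assert row["mpi_class"] == "very low" and row["mpi_aw"] == 0
        assert not np.isnan(row["wci"])
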