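"""Correlation, PCA, Ward clustering and IDW interpolation."""

import numpy as np
import pandas as pd
import pytest

from gwassess import SampleTable
from gwassess.spatial import (
    RasterGrid,
    correlation_matrix,
    hierarchical_clusters,
    idw_interpolate,
    pca,
)


def _table(arrays: dict, coords=True) -> SampleTable:
    n = len(next(iter(arrays.values())))
    df = pd.DataFrame(arrays, index=pd.Index([f"S{i}" for i in range(n)], name="station_id"))
    if coords:
        rng = np.random.default_rng(0)
        df["longitude"] = rng.uniform(90.18, 90.23, n)
        df["latitude"] = rng.uniform(22.63, 22.75, n)
    return SampleTable(df)


class TestCorrelation:
    def test_exact_linear_dependence(self):
        rng = np.random.default_rng(3)
        ec = rng.lognormal(7, 0.5, 20)
        t = _table({"ec": ec, "tds": 0.64 * ec}, coords=False)
        corr = correlation_matrix(t)
        assert corr.loc["ec", "tds"] == pytest.approx(1.0)
        assert (np.diag(corr) == 1).all()
        pd.testing.assert_frame_equal(corr, corr.T)

    def test_independent_noise_nearly_uncorrelated(self):
        rng = np.random.default_rng(4)
        t = _table({"cd": rng.lognormal(0, 1, 1000), "ni": rng.lognormal(0, 1, 1000)},
                   coords=False)
        assert abs(correlation_matrix(t).loc["cd", "ni"]) < 0.1

    def test_anticorrelation_and_constant_column(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t = _table({"ec": x, "tds": 10 - x, "turbidity": np.ones(4)}, coords=False)
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = correlation_matrix(t)
        assert corr.loc["ec", "tds"] == pytest.approx(-1.0)
        assert np.isnan(corr.loc["turbidity", "ec"])


class TestPCA:
    def test_rank_one_pair(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 30)
        res = pca(_table({"ec": 100 + 10 * x, "tds": 50 + 3 * x}, coords=False))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_independent_variables_split_evenly(self):
        rng = np.random.default_rng(6)
        t = _table({p: rng.normal(100, 5, 3000) for p in ("ec", "cd", "pb")}, coords=False)
        res = pca(t)
        np.testing.assert_allclose(res.explained_variance_ratio, [1 / 3] * 3, atol=0.05)

    def test_block_equicorrelation_band(self):
        """8 variables at rho=0.95 among 15: leading eigenvalue of the
        block-equicorrelation matrix is 1 + 7*0.95 = 7.65, so PC1 should
        explain about 7.65/15 = 51 % of standardized variance."""
        rng = np.random.default_rng(7)
        n, rho, p_block = 2000, 0.95, 8
        cov = np.eye(15)
        cov[:p_block, :p_block] = rho
        np.fill_diagonal(cov, 1.0)
        x = rng.multivariate_normal(np.zeros(15), cov, size=n)
        from gwassess.data_model import PARAMETERS

        names = list(PARAMETERS)[:15]
        df = pd.DataFrame(np.abs(x) + 0.1, columns=names,
                          index=pd.Index([f"S{i}" for i in range(n)], name="station_id"))
        df["pH"] = rng.uniform(7, 8, n)  # keep pH in range
        res = pca(SampleTable(df), parameters=[c for c in names if c != "pH"])
        # |x| weakens but preserves the block structure; generous band
        assert 0.25 < res.explained_variance_ratio[0] < 0.65

    def test_matches_sklearn(self, synthetic_samples):
        """Independent cross-check against a library implementation."""
        from sklearn.decomposition import PCA as SkPCA
        from sklearn.preprocessing import StandardScaler

        params = [p for p in synthetic_samples.parameters]
        x = synthetic_samples.data[params].to_numpy()
        xs = StandardScaler().fit_transform(x) * np.sqrt(len(x) / (len(x) - 1))
        sk = SkPCA().fit(xs)
        res = pca(synthetic_samples)
        np.testing.assert_allclose(res.explained_variance_ratio,
                                   sk.explained_variance_ratio_, atol=1e-8)
        for j in range(3):
            np.testing.assert_allclose(np.abs(res.loadings.iloc[:, j]),
                                       np.abs(sk.components_[j]), atol=1e-6)

    def test_variance_fractions_sum_to_one(self, synthetic_samples):
        res = pca(synthetic_samples)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)
        assert (res.explained_variance_ratio >= 0).all()
        assert (np.diff(res.explained_variance_ratio) <= 1e-12).all()


class TestClustering:
    def test_two_separated_clouds(self):
        rng = np.random.default_rng(8)
        a = rng.normal(5, 0.1, (5, 2))
        b = rng.normal(50, 0.1, (5, 2))
        df = pd.DataFrame(np.vstack([a, b]), columns=["ec", "tds"],
                          index=pd.Index([f"S{i}" for i in range(10)], name="station_id"))
        labels = hierarchical_clusters(SampleTable(df), "stations", 2, standardize=False)
        assert labels.iloc[:5].nunique() == 1 and labels.iloc[5:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[9]

    def test_line_points_split_at_the_gap(self):
        df = pd.DataFrame({"ec": [0.0, 1.0, 10.0, 11.0], "tds": [0.0] * 4},
                          index=pd.Index(list("abcd"), name="station_id"))
        labels = hierarchical_clusters(SampleTable(df), "stations", 2, standardize=False)
        assert labels["a"] == labels["b"] and labels["c"] == labels["d"]
        assert labels["a"] != labels["c"]

    def test_singletons_and_permutation_invariance(self, synthetic_samples):
        n = len(synthetic_samples)
        singles = hierarchical_clusters(synthetic_samples, "stations", n)
        assert singles.nunique() == n
        base = hierarchical_clusters(synthetic_samples, "stations", 3)
        shuffled = SampleTable(synthetic_samples.data.iloc[::-1])
        perm = hierarchical_clusters(shuffled, "stations", 3).reindex(base.index)
        # same partition up to label renaming
        pairs = {(base[a] == base[b]) == (perm[a] == perm[b])
                 for a in base.index for b in base.index}
        assert pairs == {True}


class TestIDW:
    def _samples(self, values, lons, lats):
        df = pd.DataFrame({"longitude": lons, "latitude": lats, "ec": values},
                          index=pd.Index([f"S{i}" for i in range(len(values))],
                                         name="station_id"))
        return SampleTable(df)

    def test_constant_field(self):
        s = self._samples([7.0, 7.0, 7.0], [90.18, 90.2, 90.22], [22.64, 22.7, 22.74])
        grid = RasterGrid.empty_covering([90.18, 90.22], [22.64, 22.74], 0.01)
        out = idw_interpolate(s, "ec", grid)
        np.testing.assert_allclose(out.values, 7.0)

    def test_equidistant_midpoint_any_power(self):
        s = self._samples([0.0, 10.0], [90.0, 90.2], [22.0, 22.0])
        grid = RasterGrid(90.095, 21.995, 0.01, np.zeros((1, 1)))
        for p in (1.0, 2.0, 3.5):
            out = idw_interpolate(s, "ec", grid, power=p)
            assert out.values[0, 0] == pytest.approx(5.0)

    def test_hand_computed_three_stations(self):
        lons, lats, z = [0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 2.0, 4.0]
        s = self._samples(z, lons, lats)
        grid = RasterGrid(0.245, 0.245, 0.01, np.zeros((1, 1)))  # probe at (0.25, 0.25)
        d = np.sqrt((np.array(lons) - 0.25) ** 2 + (np.array(lats) - 0.25) ** 2)
        w = d ** -2.0
        expected = (w * np.array(z)).sum() / w.sum()
        out = idw_interpolate(s, "ec", grid, power=2.0)
        assert out.values[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_convexity_and_node_exactness(self, synthetic_samples):
        coords = synthetic_samples.coordinates
        grid = RasterGrid.empty_covering(coords["longitude"], coords["latitude"], 0.005)
        out = idw_interpolate(synthetic_samples, "ec", grid)
        z = synthetic_samples.values_of("ec")
        assert out.values.min() >= z.min() - 1e-9
        assert out.values.max() <= z.max() + 1e-9
        # a grid whose cell centre coincides with a station is exact there
        lon0, lat0 = coords.iloc[0]
        exact = RasterGrid(lon0 - 0.0005, lat0 - 0.0005, 0.001, np.zeros((1, 1)))
        hit = idw_interpolate(synthetic_samples, "ec", exact)
        assert hit.values[0, 0] == pytest.approx(z.iloc[0])

    def test_ascii_grid_header(self, tmp_path, synthetic_samples):
        coords = synthetic_samples.coordinates
        grid = RasterGrid.empty_covering(coords["longitude"], coords["latitude"], 0.01)
        out = idw_interpolate(synthetic_samples, "ec", grid)
        path = tmp_path / "ec.asc"
        out.write_ascii(path)
        lines = path.read_text().splitlines()
        keys = [ln.split()[0] for ln in lines[:6]]
        assert keys == ["ncols", "nrows", "xllcorner", "yllcorner",
                        "cellsize", "NODATA_value"]
        assert len(lines) == 6 + out.nrows
        assert len(lines[6].split()) == out.ncols
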