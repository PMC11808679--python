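"""Multivariate statistics and inverse-distance-weighted interpolation.

Supporting stages for source apportionment and mapping: a Pearson
correlation matrix with pairwise-complete handling, PCA on standardized
columns (eigendecomposition of the correlation matrix, deterministic
sign convention), Ward-linkage hierarchical clustering on Euclidean
distances, and IDW interpolation of station values onto a regular
lon/lat raster written as an ESRI ASCII grid. Coordinates are treated
as planar decimal degrees; the study area spans well under a sixth of a
degree, so no projection machinery is warranted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .data_model import SampleTable


def correlation_matrix(samples: SampleTable, parameters: list[str] | None = None,
                       min_periods: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between parameters.

    Pairs with fewer than ``min_periods`` complete observations, and any
    zero-variance column, yield NaN entries (flagged with a warning).
    """
    params = parameters or samples.parameters
    df = samples.data[params].astype(float)
    constant = [c for c in params if df[c].dropna().nunique() <= 1]
    if constant:
        warnings.warn(f"zero-variance columns yield undefined correlations: {constant}",
                      stacklevel=2)
    return df.corr(method="pearson", min_periods=min_periods)


@dataclass
class PCAResult:
    """Loadings (parameter x component), station scores and variance split."""

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray


def pca(samples: SampleTable, parameters: list[str] | None = None,
        standardize: bool = True) -> PCAResult:
    """PCA of the (standardized) parameter table.

    Standardized PCA diagonalizes the correlation matrix, so explained
    variance fractions sum to one over all components. Components are
    ordered by decreasing eigenvalue with a deterministic sign: the
    largest-magnitude loading of each component is positive. Stations
    with any missing value among the selected parameters are dropped
    from the scores (complete-case).
    """
    params = parameters or samples.parameters
    df = samples.data[params].astype(float).dropna()
    x = df.to_numpy()
    if x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("PCA needs at least 3 complete stations and 2 parameters")
    if x.shape[1] > x.shape[0]:
        warnings.warn("more parameters than stations: rank-deficient PCA", stacklevel=2)
    center = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("zero-variance column; cannot standardize")
        center = center / sd
    cov = (center.T @ center) / (x.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    for j in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    comp_names = [f"PC{i + 1}" for i in range(len(eigval))]
    return PCAResult(
        loadings=pd.DataFrame(eigvec, index=params, columns=comp_names),
        scores=pd.DataFrame(center @ eigvec, index=df.index, columns=comp_names),
        explained_variance_ratio=eigval / eigval.sum(),
    )


def hierarchical_clusters(samples: SampleTable, axis: str = "stations", k: int = 2,
                          parameters: list[str] | None = None,
                          standardize: bool = True) -> pd.Series:
    """Ward-linkage clusters of stations or parameters, labelled 1..k.

    Euclidean distances on (optionally) column-standardized data;
    complete-case over the selected parameters. Ties are broken by
    input order through the deterministic linkage implementation.
    """
    params = parameters or samples.parameters
    df = samples.data[params].astype(float).dropna()
    x = df.to_numpy()
    if standardize:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    if axis == "parameters":
        x = x.T
        index = pd.Index(params, name="parameter")
    elif axis == "stations":
        index = df.index
    else:
        raise ValueError("axis must be 'stations' or 'parameters'")
    if not 1 <= k <= x.shape[0]:
        raise ValueError(f"k={k} out of range for {x.shape[0]} items")
    if k == x.shape[0]:
        labels = np.arange(1, k + 1)
    else:
        labels = fcluster(linkage(x, method="ward"), t=k, criterion="maxclust")
    return pd.Series(labels, index=index, name="cluster")


@dataclass
class RasterGrid:
    """Regular lon/lat raster with ESRI ASCII grid georeferencing.

    ``values`` is (nrows, ncols) with row 0 the northernmost; cell
    centres are at ``xllcorner + (j + 0.5) * cellsize`` and
    ``yllcorner + (nrows - 1 - i + 0.5) * cellsize``.
    """

    xllcorner: float
    yllcorner: float
    cellsize: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("values must be a non-empty 2-D array")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        x = self.xllcorner + (np.arange(self.ncols) + 0.5) * self.cellsize
        y = self.yllcorner + (self.nrows - 1 - np.arange(self.nrows) + 0.5) * self.cellsize
        return np.meshgrid(x, y)

    def write_ascii(self, path: str | Path, fmt: str = "%.6g") -> None:
        """Write the grid as an ESRI ASCII raster."""
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {self.xllcorner:.10g}\n")
            fh.write(f"yllcorner {self.yllcorner:.10g}\n")
            fh.write(f"cellsize {self.cellsize:.10g}\n")
            fh.write(f"NODATA_value {self.nodata:.10g}\n")
            vals = np.where(np.isnan(self.values), self.nodata, self.values)
            for row in vals:
                fh.write(" ".join(fmt % v for v in row) + "\n")

    @classmethod
    def empty_covering(cls, lon, lat, cellsize: float, pad: float = 0.0) -> "RasterGrid":
        """Smallest grid of ``cellsize`` cells covering the given points."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        x0, y0 = lon.min() - pad, lat.min() - pad
        ncols = max(1, int(np.ceil((lon.max() + pad - x0) / cellsize)))
        nrows = max(1, int(np.ceil((lat.max() + pad - y0) / cellsize)))
        return cls(x0, y0, cellsize, np.full((nrows, ncols), np.nan))


def idw_interpolate(samples: SampleTable, parameter: str, grid: RasterGrid,
                    power: float = 2.0, coincidence_tol: float = 1e-9) -> RasterGrid:
    """Inverse-distance-weighted surface of one parameter.

    Cell value = sum(w_i z_i) / sum(w_i) with w_i = d_i^-p over all
    stations (no neighbour cutoff); a cell within ``coincidence_tol``
    degrees of a station takes that station's value exactly. Stations
    missing the parameter are ignored; the output is always a convex
    combination of station values.
    """
    if power <= 0:
        raise ValueError("power must be positive")
    coords = samples.coordinates
    z = samples.values_of(parameter).astype(float)
    keep = z.notna()
    if not keep.any():
        raise ValueError(f"no station has a value for {parameter!r}")
    lon = coords.loc[keep, "longitude"].to_numpy()
    lat = coords.loc[keep, "latitude"].to_numpy()
    zv = z[keep].to_numpy()

    gx, gy = grid.cell_centers()
    d = np.sqrt((gx[..., None] - lon) ** 2 + (gy[..., None] - lat) ** 2)
    coincident = d < coincidence_tol
    with np.errstate(divide="ignore"):
        w = d ** -power
    out = np.empty(gx.shape)
    hit = coincident.any(axis=-1)
    if hit.any():
        first = np.argmax(coincident, axis=-1)
        out[hit] = zv[first[hit]]
    rest = ~hit
    if rest.any():
        wr = w[rest]
        out[rest] = (wr * zv).sum(axis=-1) / wr.sum(axis=-1)
    return RasterGrid(grid.xllcorner, grid.yllcorner, grid.cellsize, out, grid.nodata)
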