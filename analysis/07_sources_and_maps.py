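#!/usr/bin/env python
"""Source apportionment (correlation, PCA, clustering) and IDW maps.

The salinity block should dominate PC1 and cluster together, mirroring a
common saline-intrusion origin; heavy metals load elsewhere.
"""

from pathlib import Path

import pandas as pd

from gwassess import load_samples
from gwassess.spatial import (
    RasterGrid,
    correlation_matrix,
    hierarchical_clusters,
    idw_interpolate,
    pca,
)

OUT = Path("results")


def main() -> None:
    samples = load_samples(OUT / "samples.csv")

    corr = correlation_matrix(samples)
    corr.to_csv(OUT / "07_correlation.csv")
    print(f"r(EC, TDS) = {corr.loc['ec', 'tds']:.3f}; "
          f"r(EC, salinity) = {corr.loc['ec', 'salinity']:.3f}; "
          f"r(cd, ec) = {corr.loc['cd', 'ec']:.3f}")

    res = pca(samples)
    res.loadings.to_csv(OUT / "07_pca_loadings.csv")
    pd.Series(res.explained_variance_ratio, index=res.loadings.columns,
              name="fraction").to_csv(OUT / "07_pca_variance.csv")
    print(f"PC1 explains {100 * res.explained_variance_ratio[0]:.1f} % "
          f"(salinity block), PC2 {100 * res.explained_variance_ratio[1]:.1f} %")

    clusters = hierarchical_clusters(samples, axis="parameters", k=3)
    clusters.to_csv(OUT / "07_parameter_clusters.csv")
    print("\nparameter clusters (Ward/Euclidean, k=3):")
    for label, members in clusters.groupby(clusters):
        print(f"  cluster {label}: {', '.join(members.index)}")

    coords = samples.coordinates
    for param in ("ec", "cd"):
        grid = RasterGrid.empty_covering(coords["longitude"], coords["latitude"], 0.002)
        idw_interpolate(samples, param, grid).write_ascii(OUT / f"07_idw_{param}.asc")
    print(f"\nIDW surfaces -> {OUT}/07_idw_ec.asc, {OUT}/07_idw_cd.asc")


if __name__ == "__main__":
    main()
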