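#!/usr/bin/env python
"""Contamination sheet: CFs, TCI/MCI/PLI/NPI/MPI, class weights and WCI."""

from pathlib import Path

from gwassess import load_samples
from gwassess.contamination import assess

OUT = Path("results")


def main() -> None:
    samples = load_samples(OUT / "samples.csv")
    sheet = assess(samples)
    sheet.to_csv(OUT / "03_contamination.csv")
    print(f"contamination sheet -> {OUT/'03_contamination.csv'}")
    print("\nstations per TCI class:")
    print(sheet["tci_class"].value_counts().to_string())
    hotspots = sheet.sort_values("tci", ascending=False).head(3)
    print("\nmost contaminated stations (TCI):")
    for station, row in hotspots.iterrows():
        print(f"  {station}: TCI {row['tci']:.2f} ({row['tci_class']}), "
              f"WCI {row['wci']:.2f} ({row['wci_class']})")


if __name__ == "__main__":
    main()
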