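#!/usr/bin/env python
"""Screen the station table against the four drinking-water authorities.

Writes per-parameter compliance percentages (WHO, USEPA, ISDW, BDWS) and
flags the parameters with the weakest compliance — in this setting the
salinity-linked block and cadmium/lead.
"""

from pathlib import Path

from gwassess import GuidelineRegistry, compliance, load_samples

OUT = Path("results")


def main() -> None:
    samples = load_samples(OUT / "samples.csv")
    table = compliance(samples, GuidelineRegistry.default(), decimals=1)
    table.to_csv(OUT / "02_compliance.csv")
    print(f"compliance table -> {OUT/'02_compliance.csv'}")
    worst = table["mean"].dropna().sort_values().head(5)
    print("\nlowest mean compliance (%):")
    for p, v in worst.items():
        print(f"  {p:>10}: {v:5.1f}")


if __name__ == "__main__":
    main()
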