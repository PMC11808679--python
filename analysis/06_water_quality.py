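#!/usr/bin/env python
"""Weighted-arithmetic water quality index and grade distribution.

Grades the synthetic stations against WHO standards and, for reference,
re-grades the 20 published station indices (55 % fall in the Excellent
band [0, 25]).
"""

from pathlib import Path

from gwassess import load_samples, paper_fixture
from gwassess.wqi import compute, grade_distribution

OUT = Path("results")


def main() -> None:
    samples = load_samples(OUT / "samples.csv")
    table = compute(samples, detail=True)
    table.to_csv(OUT / "06_wqi.csv")
    print(f"station WQI -> {OUT/'06_wqi.csv'}")
    print("\nsynthetic grade distribution (%):")
    print(grade_distribution(table["wqi"]).to_string(float_format=lambda v: f"{v:5.1f}"))

    published = grade_distribution(paper_fixture("table7")["wqi"])
    print("\npublished station indices re-graded (%):")
    print(published.to_string(float_format=lambda v: f"{v:5.1f}"))


if __name__ == "__main__":
    main()
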