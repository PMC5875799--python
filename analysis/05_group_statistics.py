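"""Straight-vs-tilted comparisons of oscillations, growth and coupling.

Mann-Whitney U comparisons of oscillation periods, pulse velocities,
pre/post 12 h temporal averages of elongation and curvature variation,
and the kymograph coupling correlation r — the statistical layer that,
on the real data, revealed the negative elongation/curvature-variation
coupling specific to tilted plants.

Reads results/analysis/per_plant.csv; writes
results/analysis/group_comparisons.csv.
"""

from pathlib import Path

import pandas as pd

from coleokin.stats import cohort_compare

ROOT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main():
    per_plant = pd.read_csv(ROOT / "per_plant.csv")
    report = cohort_compare(per_plant)
    report.to_csv(ROOT / "group_comparisons.csv", index=False)
    print(report.round(4).to_string(index=False))
    if "r_coupling" in report["quantity"].values:
        row = report.set_index("quantity").loc["r_coupling"]
        print(f"\ncoupling r: straight median {row['median_straight']:+.3f}, "
              f"tilted median {row['median_tilted']:+.3f}, p = {row['p']:.2e}")


if __name__ == "__main__":
    main()
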