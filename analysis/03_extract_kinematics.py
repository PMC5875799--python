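"""Extract kinematic kymographs and per-plant summaries for the cohort.

For every plant in results/dataset/: orientation and curvature from the
midlines, elongation rate from marker-profile image correlation, the
material curvature derivative, oscillation summaries, morphometrics
(tilted plants) and the elongation/curvature-rate coupling correlation.

Writes results/analysis/ (per-plant kymograph files, per_plant.csv,
comparisons.csv).
"""

from pathlib import Path

from coleokin import RunConfig
from coleokin.pipeline import run_pipeline

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    per_plant = run_pipeline(ROOT / "dataset", RunConfig(),
                             out_dir=ROOT / "analysis")
    print(f"analyzed {len(per_plant)} plants")
    cols = [c for c in ("group", "Tp_regr", "vp_regr", "r_coupling", "B")
            if c in per_plant.columns]
    print(per_plant[cols].groupby("group").median(numeric_only=True).round(3))


if __name__ == "__main__":
    main()
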