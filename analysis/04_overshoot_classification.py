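"""Predicted-vs-observed overshoot classification of the tilted group.

Builds the classification table (plant, morphometric B, extremal tip
angle, predicted overshoot via B > 2.8, observed overshoot) and runs
Fisher's exact test on predicted vs observed counts — the analysis that,
on the real experiment, showed coleoptiles overshoot far less often than
the posture model predicts.

Reads results/analysis/per_plant.csv; writes
results/analysis/overshoot_classification.csv and contingency.json.
"""

import json
from pathlib import Path

import pandas as pd

from coleokin.stats import fisher_exact

ROOT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main():
    per_plant = pd.read_csv(ROOT / "per_plant.csv")
    tilted = per_plant[per_plant["group"] == "tilted"].copy()
    cols = ["plant", "B", "A_max_tip", "predicted_overshoot",
            "observed_overshoot"]
    table = tilted[[c for c in cols if c in tilted.columns]]
    table.to_csv(ROOT / "overshoot_classification.csv", index=False)
    print(table.to_string(index=False))

    n = len(table)
    pred = int(table["predicted_overshoot"].fillna(False).sum())
    obs = int(table["observed_overshoot"].fillna(False).sum())
    cont = [[pred, n - pred], [obs, n - obs]]
    try:
        res = fisher_exact(cont)
        payload = {"table": cont, "odds_ratio": res.odds_ratio,
                   "p_right": res.p_right, "p_two_sided": res.p_two_sided}
        print(f"\npredicted {pred}/{n} vs observed {obs}/{n}: "
              f"OR = {res.odds_ratio:.2f}, right-tail p = {res.p_right:.4f}")
    except ValueError as exc:  # degenerate margins on tiny cohorts
        payload = {"table": cont, "error": str(exc)}
        print(f"\npredicted {pred}/{n} vs observed {obs}/{n}: "
              f"Fisher test not defined ({exc})")
    (ROOT / "contingency.json").write_text(json.dumps(payload, indent=1))


if __name__ == "__main__":
    main()
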