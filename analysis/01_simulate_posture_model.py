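"""Locate the overshoot threshold of the posture-control model.

Scans the balance number B = beta * L_eff / gamma on a 90-degree-tilted,
non-growing organ, reports the critical value from bisection under both
the linearized and the full sine graviceptive law, and stores example
tip-angle trajectories either side of the transition.

Writes results/posture_model/{threshold.json, tip_angles.csv}.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from coleokin.ac_model import ACParams, critical_balance_number, simulate_ac

OUT = Path(__file__).resolve().parent.parent / "results" / "posture_model"
OUT.mkdir(parents=True, exist_ok=True)


def main():
    bc_linear = critical_balance_number(tol=0.05)  # linearized, strict zero
    bc_sine = critical_balance_number(tol=0.05, sine=True, delta=0.02)
    print(f"critical balance number, linearized law : {bc_linear:.3f}")
    print(f"critical balance number, sine law       : {bc_sine:.3f}")
    (OUT / "threshold.json").write_text(json.dumps({
        "B_c_linearized": round(bc_linear, 4),
        "B_c_sine": round(bc_sine, 4),
        "overshoot_delta_sine": 0.02,
    }, indent=1))

    rows = {}
    for B in (1.5, 2.5, 2.8, 3.5, 5.0):
        p = ACParams(beta=B, gamma=1.0, L0=1.0, Lgz=1.0, tilt=np.pi / 2,
                     duration=20.0, ds=0.005)
        st = simulate_ac(p, sine=False)
        sub = slice(None, None, 50)
        rows[f"B={B}"] = st.tip_angle_series[sub]
        rows.setdefault("t", st.tip_time[sub])
    df = pd.DataFrame(rows).set_index("t")
    df.to_csv(OUT / "tip_angles.csv")
    print(f"tip-angle trajectories for {[k for k in rows if k != 't']} -> "
          f"{OUT / 'tip_angles.csv'}")
    print("minimum tip angles:", {k: round(float(v.min()), 3)
                                  for k, v in df.items()})


if __name__ == "__main__":
    main()
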