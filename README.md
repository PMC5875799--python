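# coleokin

Gravitropic kinematics of growing plant organs: kymograph extraction,
posture-control simulation, traveling-pulse characterization, and the
statistics of tilting experiments.

## The problem

When a dark-grown wheat coleoptile (the sheath around a grass seedling's
first shoot) is tilted to the horizontal, it actively bends back toward
the vertical.  The prevailing posture-control model writes the curvature
dynamics of the growing zone as the sum of graviception and
proprioception,

    DC/Dt = −β sin A − γ C,

where *A*(*s*, *t*) is the zenith angle along the organ (arc length *s*
from the apex), *C* = ∂*A*/∂*s* the curvature, *DC*/*Dt* the material
(co-moving) curvature derivative, β the graviceptive and γ the
proprioceptive gain.  A single dimensionless number,

    B = β L_eff / γ   (dynamic)   =   L_eff / L_c   (morphometric),

with L_eff the effective growth-zone length and L_c the length of the
finally curved zone, predicts whether the tip will overshoot the
vertical (B above a critical value ≈ 2.8) or settle short of it.

`coleokin` is for plant-biomechanics researchers who have organ midline
time series (and optionally surface-marker intensity profiles) and want
the full kinematic story: orientation, curvature, relative elongation
growth rate (REGR, from 1-D image correlation of the marker profiles),
the material curvature derivative, the period and apex-to-base velocity
of elongation/curvature pulses, per-plant balance numbers and overshoot
classification, and treatment-level statistics (Fisher exact,
Mann–Whitney, kymograph correlation).  A ground-truthed synthetic-data
generator makes every stage testable without any experimental data.

## Worked example

```python
import numpy as np
from coleokin import (GenConfig, RunConfig, analyze_plant,
                      critical_balance_number, fisher_exact,
                      generate_coleoptile_series)

# the model's overshoot threshold, located by bisection
bc = critical_balance_number(tol=0.05)
print(f"critical balance number: {bc:.3f}")

# one synthetic tilted coleoptile (24 h at 15-min cadence), analyzed
midlines, markers, truth = generate_coleoptile_series(GenConfig(seed=1))
res = analyze_plant(midlines, markers, RunConfig(), tilted=True)
s = res.summary
print(f"Tp = {s['Tp_regr']:.2f} h (true {truth.Tp_regr:.2f}), "
      f"vp = {s['vp_regr']:.1f} mm/h (true {truth.vp_regr:.1f})")
print(f"B = {s['B']:.2f} (true {truth.balance_number:.2f}), "
      f"coupling r = {s['r_coupling']:+.3f}")

# the predicted-vs-observed overshoot contingency analysis
t = fisher_exact([[16, 38], [5, 49]])
print(f"right-tail p = {t.p_right:.4f}, odds ratio = {t.odds_ratio:.2f}")
```

Output:

```
critical balance number: 2.781
Tp = 3.00 h (true 3.00), vp = 12.1 mm/h (true 12.0)
B = 1.44 (true 2.00), coupling r = -0.151
right-tail p = 0.0069, odds ratio = 4.13
```

The critical balance number 2.781 is the transition above which a
90°-tilted organ overshoots the vertical.  The synthetic plant's pulse
period and velocity are recovered to ~1%; its morphometric balance
number shows the expected low bias of shape-based measurement on a
growing organ (see the methods note); the negative coupling correlation
reflects the anti-phase differential-growth pulses the tilted treatment
carries.  The Fisher line is the exact test on a 54-plant tilted cohort
in which 16 overshoots were predicted but only 5 observed.

## Analysis workflow

Numbered drivers under `analysis/` run the complete study on a synthetic
cohort and write tables under `results/`:

```
python analysis/01_simulate_posture_model.py   # overshoot threshold + trajectories
python analysis/02_generate_cohort.py          # synthetic tilting experiment
python analysis/03_extract_kinematics.py       # kymographs + per-plant summaries
python analysis/04_overshoot_classification.py # B, predicted/observed, Fisher
python analysis/05_group_statistics.py         # straight-vs-tilted comparisons
```

A `coleokin` command-line tool exposes the same stages
(`generate`, `simulate`, `kinematics`, `oscillations`, `overshoot`,
`stats`, `all`); see `coleokin --help`.

## Acceptance script

`scripts/acceptance.py` recomputes the package's headline quantity from
scratch — it simulates the tilted posture-control dynamics over a range
of balance numbers and bisects for the critical overshoot threshold —
and writes the result as JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

`docs/methods.md` describes the model and every estimator (coordinate
conventions, smoothing and DIC parameters, the synthetic world and what
it does and does not emulate, numerical choices, known limitations).
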