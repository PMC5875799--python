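# Methods

`coleokin` analyzes the gravitropic kinematics of young grass
coleoptiles — elongating aerial organs that straighten toward the
vertical after being tilted — from time series of organ midlines and
surface-marker intensity profiles.  This note records the models, the
estimators, the synthetic world used for validation, the numerical
choices, and the known limitations.  All lengths are mm, times hours,
angles radians, elongation rates h⁻¹.

## Coordinates and kinematic fields

The organ midline is parameterized by arc length *s* measured **from the
apex** (*s* = 0) to the base (*s* = *L*(*t*)); many kymograph tools use a
base origin, this package never does.  The local orientation *A*(*s*, *t*)
is the zenith angle of the apexward tangent: 0 for vertical-up,
clockwise positive, so an organ tilted to the reader's right reads
+π/2.  Four fields are derived:

- curvature *C* = ∂*A*/∂*s*;
- relative elongation growth rate (REGR) *Ė*(*s*, *t*), the local axial
  strain rate;
- the material curvature derivative
  *DC*/*Dt* = ∂*C*/∂*t* + (∂*C*/∂*s*) ∫₀ˢ *Ė*(*s*′, *t*) d*s*′,
  the curvature change of a co-moving tissue element — the advection
  integral runs from the apex, because tissue laid down near the apex
  drifts basally in apex-origin coordinates;
- and, per organ, temporal averages of |*Ė*| and |*DC*/*Dt*|, split at
  12 h to separate the gravitropic transient from the near-equilibrium
  regime.

Fields live on a uniform (*s*, *t*) grid (0.1 mm × 15 min by default)
with a support mask *s* ≤ *L*(*t*); the organ grows, so the supported
region widens with time.

## Posture-control (graviception–proprioception) model

Curvature dynamics inside the growth zone:

    DC/Dt = −β sin A − γ C        (sine law; linearized: −β A − γ C)

with the base clamped at the imposed tilt, *A* integrated from the base,
and curvature frozen outside the growth zone.  β (mm⁻¹h⁻¹) is the
graviceptive gain, γ (h⁻¹) the proprioceptive gain.  The behaviour is
governed by the balance number

    B = β L_eff / γ,   L_eff = min(L, L_gz).

Small B leaves a residual lean; large B makes the tip overshoot the
vertical.  The solver is explicit Euler (default dt = 0.002/γ, guarded
by dt·γ < 0.5 and a divergence detector) on Lagrangian material nodes;
spatial integration of *A* uses the trapezoid rule.  With elongation
enabled, nodes advect by the apex-side REGR integral and the growth zone
is fixed in material terms.  At steady state γC = −β sin A holds inside
the zone to < 1% of β (regression-tested).

**Critical balance number.** `critical_balance_number` brackets and
bisects the overshoot transition on a non-growing organ tilted to π/2.
Two switches matter and both are exposed:

- *graviception law*: the linearized law puts the transition at
  **B_c ≈ 2.78**; the full sine law at ≈ 3.27 (the finite tilt weakens
  the restoring drive). The classical threshold 2.8 used for
  morphometric classification corresponds to the linear small-deviation
  analysis, so the linearized law is the default here.
- *overshoot guard δ*: tip minima of the noiseless simulation are
  smooth, so the transition is defined by the strict sign change
  (δ = 0).  For classifying noisy *measured* tip series the default
  guard is δ = 0.02 rad.

## Morphometric balance number

For tilted organs B is also measurable from shape alone, B = L_eff/L_c:

- **L_eff** — apical contiguous extent where time-averaged REGR exceeds
  10% of its maximum, capped by the initial organ length.
- **L_c** — length of the zone still curved at the end of the record,
  measured as the arc length where the final |C| profile exceeds 1/e of
  its peak.  The equilibrium profile decays roughly exponentially with
  length L_eff/B, so the 1/e cutoff makes L_c the decay length and
  B = L_eff/L_c consistent with βL_eff/γ (a far lower cutoff, e.g. 10%
  of peak, counts ≈ 2.3 decay lengths and halves B).
- **Quiescence guard** — L_c is only meaningful once curvature has
  stopped changing.  Because elongation/curvature pulses persist to the
  end of the record and the measured |DC/Dt| carries a noise floor, an
  absolute near-zero threshold can never pass; instead the final 2 h
  window must stay below 90% of the record's maximum windowed mean
  |DC/Dt| — i.e. the record must not end mid-transient.

Predicted overshoot is B > 2.8 (configurable); observed overshoot is the
measured tip angle passing −δ.  B is refused (NaN) for plants of the
straight treatment, which develop no curved zone to measure.

Two genuine biases remain in measured B (regression-tested at their
achieved level, ≈ −15% net): smoothing widens narrow curved zones, and
in a growing organ the advective term inflates the equilibrium curved
zone by roughly v/(γλ) ≈ 10–17%.  Predicted-vs-true overshoot
concordance on default synthetic cohorts is ≈ 94% for plants with true
B outside [2.6, 3.0].

## REGR by one-dimensional image correlation

Marker-intensity profiles sampled along the midline are matched between
frame pairs by windowed normalized cross-correlation (window 2 mm, 75%
overlap, search ±1 mm, 3-point parabolic subpixel refinement).  Pairs
are separated by two frames (30 min): displacement grows with the
baseline while the subpixel matching error stays fixed, and the result
is assigned to the central frame.  The velocity profile is anchored with
v(0) = 0 — material drift vanishes at the apex by construction — which
removes the one-sided boundary bias of the derivative; REGR is then the
local-quadratic (Savitzky–Golay) derivative of v(s) over 4 mm.  Windows
with zero variance or displacements at the search bound are masked.

Accuracy: imposed uniform strain rates in [0.005, 0.05] h⁻¹ are
recovered within 5%.  On full synthetic plants the REGR kymograph is
recovered to ≈ 12% relative RMS — the floor is systematic, not noise:
the smear of the growth-zone edge over the smoothing window, plus a
speckle-pattern-dependent subpixel bias (~0.1 sample) that temporal
averaging cannot remove.

## Noise chain for the material derivative

*DC/Dt* sits two derivatives beyond the measured midline: coordinates →
orientation → curvature → time/space derivatives.  With 0.02 mm
coordinate noise the cell-wise recovery of DC/Dt is poor (relative RMS
near 1) even after the dedicated smoothing path (curvature smoothed over
3 mm in *s* and 9 frames in *t* before differencing); what survives is
the *pattern*: correlation with the true field > 0.5 in the growth zone,
which is sufficient for the coupling statistic below.  Consumers should
treat single-cell DC/Dt values as indicative only.

## Oscillation characterization

Pulse maxima are local maxima in time at each position above the 0.7
quantile of the field's supported values, with parabolic refinement of
the peak time.  Maxima are linked greedily in time order (gap ≤ 0.75 h,
jump ≤ 8 mm, smallest-jump tie-break) into ridge tracks; each track is
fitted by least squares with the linear pulse model P(t) = v_p (t − t₀),
so v_p is the slope — the printed form v_p = P/(t + t₀) is dimensionally
inconsistent with that model and is deliberately not used.  The period
is T_p = T/n (span T over n successive inter-peak intervals) at a single
reference position — chosen as the best-supported high-variance column
with the most detected crests, which avoids double-counting a traveling
pulse and is robust to columns whose crests dip under the amplitude
threshold.  On synthetic plants at default noise, median errors of T_p
and v_p from the REGR kymograph are < 5% (≈ 1% typical); the DC/Dt
kymograph is usually too noisy for meaningful crest tracking (see
above).

## Statistics

Fisher's exact test computes hypergeometric tail probabilities from the
conditional distribution of the top-left cell; the two-sided p sums all
tables with point probability ≤ the observed (ties included); the odds
ratio is the sample cross-product ratio (conditional-MLE variant
available).  For the predicted-vs-observed overshoot table
[[16, 38], [5, 49]] the right tail gives p = 0.006854 and OR = 784/190 =
4.126; only the right-tailed reading reproduces the published p = 0.0069
(the two-sided value is 0.0137).  The published 95% CI [0.99, 17.28]
matches no standard construction on this table; a Wald interval is
available behind a flag with a caveat.  Mann–Whitney U uses midranks,
with a full-enumeration exact null for n₁+n₂ ≤ 20 (ties handled
exactly) and a tie-corrected, continuity-corrected normal approximation
otherwise.  Kymograph coupling is the Pearson r over jointly supported
cells, restricted to the growth zone in the pipeline (outside it both
fields are near zero and only dilute r).  No multiple-testing
correction is applied; every comparison is reported raw.

## Synthetic world

The generator emulates the tilting experiment: 15-min cadence over 24 h;
initial length 10–20 mm; a 10 mm apical growth zone with baseline REGR
0.036 h⁻¹ (1.0×10⁻⁵ s⁻¹); tilt 0 or π/2; elongation pulses
Ė = Ė₀(1 + a sin(2π(t/T_p − s/(v_p T_p)))) with relative amplitude
a = 0.4, clipped at zero and tapered to zero over the basal 2 mm of the
zone (real elongation profiles decline gradually; a step would be
unphysical and unresolvable by windowed correlation); and
differential-growth pulses forcing curvature at rate Ė·Δ/R (organ radius
R = 0.5 mm, curvature-rate amplitude 0.02 mm⁻¹h⁻¹) at a controllable
phase δφ relative to the elongation wave.  δφ = π (tilted default)
yields negative Ė-vs-DC/Dt kymograph correlation; δφ = 0 (straight
default) positive.  Cohort draws: T_p ~ U[2.5, 3.5] h,
v_p ~ U[8, 17] mm/h, B ~ U[0.5, 4], L₀ ~ U[10, 20] mm.  Coordinate
noise: 0.02 mm i.i.d. per midline point (subpixel-tracking scale);
marker profiles are rendered noise-free from exactly advected material
marker positions (8 mm⁻¹, Gaussian σ = 0.15 mm, amplitudes U[0.5, 1]).

The printed idealized-wave formula sin(s·T_p·v_p + t·T_p) has period
2πT_p and apex-ward crests; the generator's default form fixes both the
period (T_p exactly) and the propagation direction (apex→base at v_p),
and the literal form is retained behind a flag for reference.

Two intentional idealizations: the generator integrates the linearized
graviceptive law so that its overshoot transition (≈ 2.78) coincides
with the 2.8 classification threshold its cohorts are scored against;
and the ground-truth overshoot flag comes from a pulse-free companion
run, because differential-growth pulses wobble the tip by ~0.1 rad and
would blur the flag into a band of B.  The pulse-dressed tip trajectory
is still emitted for observed-overshoot measurement.

What a green synthetic test does **not** establish: real midlines come
from photographs via contour extraction (noise is correlated, not
i.i.d.); real marker fields blur, fade and occlude; real REGR profiles
are not separable sine waves; and real coleoptiles exhibit the
unexplained extra regulation (fewer overshoots than predicted) that
motivated the original experiment — the generator deliberately contains
no such mechanism.

## Numerical and degenerate-input conventions

Savitzky–Golay windows are clipped to odd lengths within each supported
run; support-edge derivatives are second-order one-sided; masked cells
propagate NaN and are re-masked after every derivation.  Midline frames
need ≥ 2 points (≥ 3 supported s-samples for curvature); duplicate
consecutive points are malformed input.  Zero-variance correlation
windows are masked with a logged warning, as are displacements at the
search bound.  An organ straight at the end of the record has undefined
L_c (and B).  The overshoot predicate is strict: a minimum exactly at
−δ does not count.  Fixed seeds make every generator output
byte-identical.

## Known limitations

- DC/Dt is pattern-accurate, not cell-accurate, at realistic noise (see
  noise chain); its oscillation summaries are unreliable.
- Morphometric B carries a ≈ −15% bias on growing organs (advective
  widening + smoothing); the overshoot classification inherits it for
  B within ~15% above threshold.
- The DIC estimator assumes locally rigid windows; strain within a
  window (> a few % per baseline) biases displacement slightly.
- The pipeline starts from midlines and marker profiles; photograph
  segmentation is out of scope.
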