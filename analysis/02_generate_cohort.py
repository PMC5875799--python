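"""Generate the synthetic tilting-experiment cohort.

Emulates the darkroom protocol: plants randomly assigned to a straight
(vertical) or tilted (90 degrees) treatment, photographed every 15 min
for 24 h.  Tilted plants carry anti-phase differential-growth pulses
(the coupling the analysis is designed to detect); straight plants the
in-phase control.  Per-plant wave parameters are drawn from
Tp ~ U[2.5, 3.5] h, vp ~ U[8, 17] mm/h, B ~ U[0.5, 4].

Writes results/dataset/ (midlines, marker profiles, hidden truth,
manifest).  Adjust N_PER_GROUP for a larger run.
"""

from pathlib import Path

from coleokin.synthetic import generate_cohort

N_PER_GROUP = 8
SEED = 0
OUT = Path(__file__).resolve().parent.parent / "results" / "dataset"


def main():
    manifest = generate_cohort(N_PER_GROUP, N_PER_GROUP, OUT, seed=SEED)
    counts = manifest["group"].value_counts().to_dict()
    print(f"wrote {len(manifest)} plants to {OUT} ({counts})")


if __name__ == "__main__":
    main()
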