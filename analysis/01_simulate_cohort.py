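"""Simulate the micro-well cohort that drives the downstream analyses.

Generates Th17 and Treg condition populations under the study conditions
(52 hr at 30-min frames; RORγt onset ~ N(21.8, 9.4²) hr, Foxp3 onset
~ N(39.3, 8.2²) hr; Th17 fate mix 57/22/21 SPR/DP/DN, Treg 46/20/34
SPF/DP/DN) and writes the trace, pixel and metadata CSVs that the later
scripts consume.

Writes: results/data/{traces,wells,pixels}.csv
"""

import sys
from pathlib import Path

import numpy as np

from clonefate import synthetic as syn

SEED = 20260929
OUT = Path("results/data")


def main():
    th17 = syn.th17_spec(n_clones=190)
    treg = syn.treg_spec(n_clones=190)
    rec_th17 = syn.simulate_population(th17, seed=SEED)
    rec_treg = syn.simulate_population(treg, seed=SEED + 1)
    records = rec_th17 + rec_treg

    # pixel-level rendering of the last five frames for 120 non-DN wells,
    # all the angle analysis needs
    rng = np.random.default_rng(SEED + 2)
    candidates = [r for r in records if r.params.fate != "DN"]
    chosen = rng.choice(len(candidates), size=120, replace=False)
    rendered = []
    for i in chosen:
        r = candidates[i]
        spec = th17 if r.trace.condition == "Th17" else treg
        frames = syn.simulate_well_pixels(
            r.params, spec, well_id=r.well_id,
            frame_indices=range(spec.n_frames - 5, spec.n_frames))
        rendered.append(syn.CloneRecord(r.well_id, r.params, r.trace, frames))

    paths = syn.write_population_csvs(records, OUT)
    px = syn.pixels_frame(rendered)
    px.to_csv(OUT / "pixels.csv", index=False)

    fates = [r.params.fate for r in rec_th17]
    print(f"simulated {len(records)} wells "
          f"({len(rec_th17)} Th17, {len(rec_treg)} Treg)")
    print("Th17 generating fate mix:",
          {f: fates.count(f) for f in ("SPR", "DP", "DN")})
    print(f"pixel-rendered wells: {len(rendered)} (last 5 frames)")
    print("wrote:", ", ".join(str(p) for p in paths.values()),
          f"and {OUT/'pixels.csv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
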