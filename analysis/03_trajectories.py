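"""Phase-plane trajectories: does co-expression change either reporter's path?

Builds median ± std traces per fate group, draws the DP trajectory in the
(Foxp3, RORγt) plane against the extrapolation that pairs SPF's Foxp3
dynamics with SPR's RORγt dynamics, and scores the agreement with a
normalized RMSD against a split-half bootstrap null.  A DP trajectory
indistinguishable from the extrapolation means the two reporters rise
independently even when co-expressed.

Reads:  results/data/{traces,wells}.csv, results/calls.csv
Writes: results/trajectory.json, results/figures/trajectories.png
"""

import importlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from clonefate import trajectory as traj

OUT = Path("results")
SEED = 20260931


def main():
    sys.path.insert(0, str(Path(__file__).parent))
    load_traces = importlib.import_module("02_classify_clones").load_traces
    traces, _ = load_traces()
    calls = pd.read_csv(OUT / "calls.csv")

    def group(fate, condition):
        ids = calls.loc[(calls.fate == fate) & (calls.condition == condition),
                        "well_id"]
        return [traces[w] for w in ids]

    spr = traj.median_traces(group("SPR", "Th17"), "SPR")
    dp_traces = group("DP", "Th17")
    dp = traj.median_traces(dp_traces, "DP")
    spf = traj.median_traces(group("SPF", "Treg"), "SPF")

    observed = traj.phase_trajectory(dp)
    expected = traj.extrapolated_trajectory(spr, spf)
    dist = traj.trajectory_distance(observed, expected)
    null = traj.bootstrap_half_distances(dp_traces, n_boot=300,
                                         rng=np.random.default_rng(SEED))
    p95 = float(np.percentile(null, 95))
    print(f"DP vs extrapolated SPR×SPF trajectory: normalized RMSD = "
          f"{dist:.3f} (split-half null 95th pct = {p95:.3f})")
    verdict = "consistent with independent reporter dynamics" \
        if dist <= p95 else "DEVIATES from the independence extrapolation"
    print("->", verdict)

    (OUT / "trajectory.json").write_text(json.dumps({
        "distance_dp_vs_extrapolated": dist,
        "bootstrap_null_p95": p95,
        "n_dp_clones": len(dp_traces),
        "observed": observed.tolist(),
        "expected": expected.tolist(),
        "times": dp.times.tolist(),
    }, indent=1))

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    for ax, ch, label in ((axes[0], "G", "RORγt-GFP"),
                          (axes[1], "R", "Foxp3-RFP")):
        for med, color in ((spr, "tab:blue"), (dp, "tab:pink"),
                           (spf, "tab:red")):
            m = getattr(med, f"median_{ch}")
            s = getattr(med, f"std_{ch}")
            ax.plot(med.times, m, color=color, label=med.population)
            ax.fill_between(med.times, m - s, m + s, color=color, alpha=0.2)
        ax.set(xlabel="time (hr)", ylabel=f"total {label} (a.u.)")
        ax.legend()
    ax = axes[2]
    ax.plot(observed[:, 0], observed[:, 1], color="tab:pink", label="DP")
    ax.plot(expected[:, 0], expected[:, 1], "k--", label="extrapolated")
    ax.scatter(*observed[0], marker="o", color="k", zorder=3)
    ax.scatter(*observed[-1], marker="^", color="k", zorder=3)
    ax.set(xlabel="Foxp3 (a.u.)", ylabel="RORγt (a.u.)",
           title=f"nRMSD = {dist:.3f}")
    ax.legend()
    fig.tight_layout()
    (OUT / "figures").mkdir(exist_ok=True, parents=True)
    fig.savefig(OUT / "figures" / "trajectories.png", dpi=150)
    print("wrote results/trajectory.json and results/figures/trajectories.png")
    return 0


if __name__ == "__main__":
    sys.exit(main())
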