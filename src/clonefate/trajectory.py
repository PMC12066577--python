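"""Population trajectories in the Foxp3–RORγt phase plane.

The key question: do the two reporters evolve independently when
co-expressed?  If so, the trajectory of double-positive clones in the
(Foxp3, RORγt) plane should coincide with an extrapolated trajectory
built by pairing the Foxp3 dynamics of SPF clones with the RORγt
dynamics of SPR clones.  Agreement is quantified by a normalized RMSD
with a bootstrap split-half null.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .containers import CloneTrace, MedianTrace

__all__ = [
    "median_traces", "phase_trajectory", "extrapolated_trajectory",
    "trajectory_distance", "bootstrap_half_distances",
]


def _common_grid(traces: Sequence[CloneTrace]) -> np.ndarray:
    t0 = traces[0].times
    for tr in traces[1:]:
        if len(tr.times) != len(t0) or not np.allclose(tr.times, t0):
            raise ValueError("traces must share a common time grid "
                             "(no resampling is performed)")
    return t0


def median_traces(traces: Sequence[CloneTrace], population: str) -> MedianTrace:
    """Pointwise median ± std of a fate group's traces (>= 3 traces)."""
    if len(traces) < 3:
        raise ValueError("median trace requires at least 3 traces")
    times = _common_grid(traces)
    g = np.stack([tr.total_G for tr in traces])
    r = np.stack([tr.total_R for tr in traces])
    return MedianTrace(population=population, times=times,
                       median_G=np.median(g, axis=0), std_G=g.std(axis=0),
                       median_R=np.median(r, axis=0), std_R=r.std(axis=0))


def phase_trajectory(median: MedianTrace) -> np.ndarray:
    """(T, 2) trajectory ordered by time: x = median Foxp3, y = median RORγt."""
    return np.column_stack([median.median_R, median.median_G])


def extrapolated_trajectory(spr: MedianTrace, spf: MedianTrace) -> np.ndarray:
    """Independence prediction: SPF's Foxp3 paired with SPR's RORγt over time."""
    if len(spr.times) != len(spf.times) or not np.allclose(spr.times, spf.times):
        raise ValueError("SPR and SPF median traces must share a time grid")
    if np.any(np.diff(spr.times) <= 0):
        raise ValueError("times must be strictly increasing")
    return np.column_stack([spf.median_R, spr.median_G])


def trajectory_distance(observed: np.ndarray, expected: np.ndarray) -> float:
    """Normalized RMSD between two equal-length phase trajectories.

    Root-mean-square pointwise Euclidean distance divided by the RMS
    magnitude of the expected trajectory; dimensionless and invariant to
    joint rescaling of both trajectories.
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("trajectories must have equal length")
    rmsd = np.sqrt(np.mean(np.sum((observed - expected) ** 2, axis=1)))
    scale = np.sqrt(np.mean(np.sum(expected ** 2, axis=1)))
    if scale == 0:
        return 0.0 if rmsd == 0 else float("inf")
    return float(rmsd / scale)


def bootstrap_half_distances(traces: Sequence[CloneTrace], n_boot: int = 200,
                             rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Split-half null for trajectory agreement.

    Repeatedly splits the clone set into random halves and measures the
    normalized RMSD between the two half-median trajectories; the
    resulting distribution is what "indistinguishable" means for a
    population of this size.
    """
    if rng is None:
        rng = np.random.default_rng()
    n = len(traces)
    if n < 6:
        raise ValueError("bootstrap split-half needs at least 6 traces")
    half = n // 2
    out = np.empty(n_boot)
    for b in range(n_boot):
        perm = rng.permutation(n)
        a = [traces[i] for i in perm[:half]]
        c = [traces[i] for i in perm[half:]]
        ta = phase_trajectory(median_traces(a, "half_a"))
        tc = phase_trajectory(median_traces(c, "half_b"))
        out[b] = trajectory_distance(ta, tc)
    return out
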