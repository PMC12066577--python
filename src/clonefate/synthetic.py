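"""Synthetic micro-well, flow-cytometry and bulk-expression data.

This module generates data with the statistical structure the downstream
analyses assume, so the whole pipeline is testable without the imaging
dataset.  Three generators are provided:

* clone-level fluorescence traces and abstract pixel sets for micro-wells
  (sigmoidal reporter onset, division-driven doubling, Gaussian noise);
* flow-cytometry-like event tables with configurable state-transition
  probabilities and an origin dye label;
* bulk log2 expression tables with per-gene placement of the DP population
  between the two single-positive populations.

Default parameters encode the study conditions: 52 hr of differentiation
imaged at 30-minute intervals, RORγt onset ~ N(21.8, 9.4²) hr, Foxp3 onset
~ N(39.3, 8.2²) hr, first division ~ N(38.8, 6²) hr under Th17 and
N(36, 6²) hr under Treg conditions, Th17 fate mix 57% SPR / 22% DP and
Treg mix 46% SPF / 20% DP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FATES, CloneTrace, WellPixelFrame

__all__ = [
    "CloneParams", "PopulationSpec", "CloneRecord",
    "th17_spec", "treg_spec",
    "simulate_clone_trace", "simulate_well_pixels", "simulate_population",
    "simulate_flow_events", "simulate_expression_table",
    "population_metadata", "traces_frame", "pixels_frame",
    "write_population_csvs", "render_tiff_stack",
    "FLOW_DEFAULT_MEANS", "FLOW_DEFAULT_SDS",
]

# channels active per fate
_FATE_CHANNELS = {
    "SPR": ("G",),
    "SPF": ("R",),
    "DP": ("G", "R"),
    "DN": (),
}


@dataclass(frozen=True)
class CloneParams:
    """Generative parameters of a single clone (one micro-well)."""

    fate: str
    onset_time_G: float          # hours; sigmoid midpoint of the GFP channel
    onset_time_R: float
    amplitude_G: float           # fluorescence units at full rise (pre-division)
    amplitude_R: float
    baseline: float
    rise_width: float            # hours; logistic time scale
    division_times: tuple = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.fate not in FATES:
            raise ValueError(f"unknown fate {self.fate!r}")
        if self.rise_width <= 0:
            raise ValueError("rise_width must be > 0")
        if self.onset_time_G < 0 or self.onset_time_R < 0:
            raise ValueError("onset times must be >= 0")
        if self.amplitude_G < 0 or self.amplitude_R < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.fate == "DN" and (self.amplitude_G > 0 or self.amplitude_R > 0):
            raise ValueError("DN clones must have zero amplitude in both channels")
        object.__setattr__(self, "division_times",
                           tuple(float(d) for d in self.division_times))


@dataclass(frozen=True)
class PopulationSpec:
    """Conditions of one simulated micro-well experiment.

    ``onset_*_dist`` and ``division_time_dist`` are (mean, sd) in hours;
    onsets of active channels are sampled from the corresponding normal
    truncated to the observation window [0, duration], since a clone whose
    reporter never rises within the experiment is by definition negative
    in that channel.
    """

    condition: str = "Th17"
    fate_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"SPR": 0.57, "DP": 0.22, "DN": 0.21})
    onset_G_dist: tuple = (21.8, 9.4)
    onset_R_dist: tuple = (39.3, 8.2)
    division_time_dist: tuple = (38.8, 6.0)
    n_clones: int = 100
    frame_interval: float = 0.5   # hours
    duration: float = 52.0        # hours
    baseline: float = 100.0
    amplitude: float = 150.0
    rise_width: float = 0.5
    noise_sd: float = 25.0
    division_cycle: float = 12.0  # hours between successive divisions

    def __post_init__(self):
        total = sum(self.fate_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fate_fractions must sum to 1 (got {total})")
        if any(f not in FATES for f in self.fate_fractions):
            raise ValueError("fate_fractions keys must be fates")
        n = self.duration / self.frame_interval
        if abs(n - round(n)) > 1e-9:
            raise ValueError("frame_interval must divide duration")
        for name in ("onset_G_dist", "onset_R_dist", "division_time_dist"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name} sd must be >= 0")
        if self.n_clones < 0:
            raise ValueError("n_clones must be >= 0")

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.duration / self.frame_interval))
        return np.linspace(0.0, self.duration, n + 1)

    @property
    def n_frames(self) -> int:
        return len(self.times)


def th17_spec(**overrides) -> PopulationSpec:
    """Th17-condition defaults (57% SPR, 22% DP, first division ~38.8 hr)."""
    return replace(PopulationSpec(), condition="Th17", **overrides)


def treg_spec(**overrides) -> PopulationSpec:
    """Treg-condition defaults (46% SPF, 20% DP, first division ~36 hr)."""
    base = PopulationSpec(
        condition="Treg",
        fate_fractions={"SPF": 0.46, "DP": 0.20, "DN": 0.34},
        division_time_dist=(36.0, 6.0),
    )
    return replace(base, **overrides)


def _truncated_normal(rng, mean, sd, low, high, size=None):
    if sd == 0:
        out = np.full(size if size is not None else (), float(mean))
        return np.clip(out, low, high)
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd,
                               size=size, random_state=rng)


def _n_cells(times: np.ndarray, division_times: Sequence[float]) -> np.ndarray:
    """Cell count over time: doubles instantaneously at each division."""
    if not len(division_times):
        return np.ones_like(times, dtype=int)
    divs = np.sort(np.asarray(division_times, dtype=float))
    return 2 ** np.searchsorted(divs, times, side="right")


def _growth(times: np.ndarray, division_times: Sequence[float]) -> np.ndarray:
    """Division-driven growth of the total expression signal.

    Continuous at division times (daughter cells split the parent's
    fluorophore content, no loss): between successive divisions the
    total production capacity ramps exponentially so that it has doubled
    by the time of the next division.  Before the first division the
    factor is 1; after the last observed division it stays flat (the
    next doubling would complete outside the experiment).
    """
    t = np.asarray(times, dtype=float)
    if not len(division_times):
        return np.ones_like(t)
    divs = np.sort(np.asarray(division_times, dtype=float))
    exponent = np.zeros_like(t)
    for k in range(len(divs) - 1):
        d0, d1 = divs[k], divs[k + 1]
        seg = (t >= d0) & (t < d1)
        exponent[seg] = k + (t[seg] - d0) / (d1 - d0)
    exponent[t >= divs[-1]] = len(divs) - 1
    return 2.0 ** exponent


def _sigmoid(times, onset, width):
    from scipy.special import expit
    return expit((times - onset) / width)


def simulate_clone_trace(params: CloneParams, spec: PopulationSpec,
                         well_id: str = "well") -> CloneTrace:
    """Render one clone's total-fluorescence trace on the frame grid.

    Each channel follows ``baseline + amplitude * logistic(t) * growth(t)
    + noise`` where growth doubles the expression signal at every division
    time, and the logistic midpoint sits at the channel's onset time.
    Deterministic for a fixed ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    t = spec.times
    growth = _growth(t, params.division_times)
    out = {}
    for ch, onset, amp in (("G", params.onset_time_G, params.amplitude_G),
                           ("R", params.onset_time_R, params.amplitude_R)):
        signal = amp * _sigmoid(t, onset, params.rise_width) * growth
        noise = rng.normal(0.0, params.noise_sd, size=t.shape) \
            if params.noise_sd > 0 else 0.0
        out[ch] = params.baseline + signal + noise
    return CloneTrace(well_id=well_id, times=t, total_G=out["G"],
                      total_R=out["R"], condition=spec.condition,
                      division_times=params.division_times)


def simulate_well_pixels(params: CloneParams, spec: PopulationSpec,
                         n_pixels_per_cell: int = 12,
                         n_background_pixels: int = 150,
                         pixel_background: float = 2.0,
                         pixel_noise_sd: float = 1.0,
                         well_id: str = "well",
                         frame_indices: Optional[Sequence[int]] = None) -> list[WellPixelFrame]:
    """Render a clone as per-frame two-channel pixel sets.

    Cells double at division times; each cell occupies ``n_pixels_per_cell``
    pixels that split the clone's expression signal equally, on top of a
    flat pixel background.  Background pixels carry background plus noise
    only.  The pixel set is abstract: no spatial layout is simulated.

    Noise is seeded per frame, so rendering a subset via ``frame_indices``
    (e.g. only the last five frames, all that the angle analysis needs)
    reproduces exactly the pixels a full render would give at those frames.
    """
    if n_pixels_per_cell < 1:
        raise ValueError("n_pixels_per_cell must be >= 1")
    t = spec.times
    growth = _growth(t, params.division_times)
    cells = _n_cells(t, params.division_times)
    if frame_indices is None:
        frame_indices = range(len(t))
    frames = []
    for i in frame_indices:
        ti = t[i]
        rng = np.random.default_rng(
            np.random.SeedSequence([int(params.seed), 1, int(i)]))
        n_cells = int(cells[i])
        n_cell_px = n_cells * n_pixels_per_cell
        n_px = n_cell_px + n_background_pixels
        g = np.full(n_px, pixel_background)
        r = np.full(n_px, pixel_background)
        # each cell carries signal*growth/n_cells, spread over its pixels
        for ch, arr, onset, amp in (("G", g, params.onset_time_G, params.amplitude_G),
                                    ("R", r, params.onset_time_R, params.amplitude_R)):
            if amp > 0:
                share = (amp * _sigmoid(ti, onset, params.rise_width) * growth[i]
                         / (n_cells * n_pixels_per_cell))
                arr[:n_cell_px] += share
        if pixel_noise_sd > 0:
            g = g + rng.normal(0.0, pixel_noise_sd, n_px)
            r = r + rng.normal(0.0, pixel_noise_sd, n_px)
        frames.append(WellPixelFrame(well_id=well_id, frame_index=i,
                                     time_hr=float(ti),
                                     G=np.clip(g, 0, None),
                                     R=np.clip(r, 0, None)))
    return frames


@dataclass(frozen=True)
class CloneRecord:
    """One simulated well: parameters, trace, optional pixel frames."""
    well_id: str
    params: CloneParams
    trace: CloneTrace
    frames: Optional[list] = None


def _draw_params(spec: PopulationSpec, fate: str, rng,
                 seed: int) -> CloneParams:
    channels = _FATE_CHANNELS[fate]
    onset_G = spec.duration + 1.0
    onset_R = spec.duration + 1.0
    if "G" in channels:
        onset_G = float(_truncated_normal(rng, *spec.onset_G_dist, 0.0, spec.duration))
    if "R" in channels:
        onset_R = float(_truncated_normal(rng, *spec.onset_R_dist, 0.0, spec.duration))
    first_div = float(_truncated_normal(rng, *spec.division_time_dist,
                                        4.0, spec.duration + spec.division_cycle))
    divs = []
    d = first_div
    while d <= spec.duration:
        divs.append(d)
        d += spec.division_cycle
    amp_G = spec.amplitude if "G" in channels else 0.0
    amp_R = spec.amplitude if "R" in channels else 0.0
    return CloneParams(fate=fate, onset_time_G=onset_G, onset_time_R=onset_R,
                       amplitude_G=amp_G, amplitude_R=amp_R,
                       baseline=spec.baseline, rise_width=spec.rise_width,
                       division_times=tuple(divs), noise_sd=spec.noise_sd,
                       seed=seed)


def simulate_population(spec: PopulationSpec, seed: int,
                        render_pixels: bool = False,
                        pixel_kwargs: Optional[dict] = None) -> list[CloneRecord]:
    """Simulate a full cohort of clones under one culture condition.

    Fates are drawn from ``spec.fate_fractions``; onset and division times
    from the spec's distributions.  Bitwise reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    fates = list(spec.fate_fractions)
    probs = np.array([spec.fate_fractions[f] for f in fates])
    drawn = rng.choice(len(fates), size=spec.n_clones, p=probs)
    records = []
    pixel_kwargs = pixel_kwargs or {}
    for i, fi in enumerate(drawn):
        well_id = f"{spec.condition}_{i:04d}"
        clone_seed = int(rng.integers(0, 2**31 - 1))
        params = _draw_params(spec, fates[fi], rng, clone_seed)
        trace = simulate_clone_trace(params, spec, well_id=well_id)
        frames = None
        if render_pixels:
            frames = simulate_well_pixels(params, spec, well_id=well_id,
                                          **pixel_kwargs)
        records.append(CloneRecord(well_id=well_id, params=params,
                                   trace=trace, frames=frames))
    return records


# ---------------------------------------------------------------------------
# tabular views / writers

def population_metadata(records: Sequence[CloneRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append({
            "well_id": rec.well_id,
            "n_cells_t0": rec.trace.n_cells_t0,
            "n_beads_t0": rec.trace.n_beads_t0,
            "condition": rec.trace.condition,
            "true_fate": rec.params.fate,
            "division_times": ";".join(f"{d:.3f}" for d in rec.params.division_times),
        })
    return pd.DataFrame(rows)


def traces_frame(records: Sequence[CloneRecord]) -> pd.DataFrame:
    parts = []
    for rec in records:
        parts.append(pd.DataFrame({
            "well_id": rec.well_id,
            "time_hr": rec.trace.times,
            "total_G": rec.trace.total_G,
            "total_R": rec.trace.total_R,
        }))
    return pd.concat(parts, ignore_index=True)


def pixels_frame(records: Sequence[CloneRecord]) -> pd.DataFrame:
    parts = []
    for rec in records:
        if rec.frames is None:
            continue
        for fr in rec.frames:
            parts.append(pd.DataFrame({
                "well_id": fr.well_id,
                "frame": fr.frame_index,
                "time_hr": fr.time_hr,
                "pixel_id": np.arange(fr.n_pixels),
                "G": fr.G,
                "R": fr.R,
            }))
    if not parts:
        return pd.DataFrame(columns=["well_id", "frame", "time_hr",
                                     "pixel_id", "G", "R"])
    return pd.concat(parts, ignore_index=True)


def write_population_csvs(records, outdir) -> dict:
    """Write traces, metadata and (if rendered) pixel CSVs; return paths."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["traces"] = outdir / "traces.csv"
    traces_frame(records).to_csv(paths["traces"], index=False)
    paths["metadata"] = outdir / "wells.csv"
    population_metadata(records).to_csv(paths["metadata"], index=False)
    px = pixels_frame(records)
    if len(px):
        paths["pixels"] = outdir / "pixels.csv"
        px.to_csv(paths["pixels"], index=False)
    return paths


def render_tiff_stack(frames: Sequence[WellPixelFrame], path) -> tuple:
    """Write one well's pixel frames as a (T, 2, H, W) TIFF for I/O tests.

    Pixels are laid out row-major into the smallest square that holds the
    largest frame; unused pixels are zero.
    """
    import tifffile
    n_max = max(fr.n_pixels for fr in frames)
    side = int(math.ceil(math.sqrt(n_max)))
    stack = np.zeros((len(frames), 2, side, side), dtype=np.float32)
    for i, fr in enumerate(frames):
        for c, arr in enumerate((fr.G, fr.R)):
            flat = stack[i, c].reshape(-1)
            flat[:arr.size] = arr
    tifffile.imwrite(path, stack)
    return stack.shape


# ---------------------------------------------------------------------------
# flow-cytometry event tables

FLOW_DEFAULT_MEANS = {
    "SPR": (1000.0, 100.0),
    "SPF": (100.0, 1000.0),
    "DP": (1000.0, 1000.0),
    "DN": (100.0, 100.0),
}
FLOW_DEFAULT_SDS = {
    "SPR": (200.0, 15.0),
    "SPF": (15.0, 200.0),
    "DP": (200.0, 200.0),
    "DN": (15.0, 15.0),
}


def simulate_flow_events(n_events: int,
                         per_population_means: Mapping[str, tuple] = None,
                         per_population_sds: Mapping[str, tuple] = None,
                         transition_probs: Mapping[tuple, float] = None,
                         dye_labeling: bool = True,
                         dyed_origins: Sequence[str] = ("SPR",),
                         origin_fractions: Mapping[str, float] = None,
                         condition: str = "Th17",
                         mixture_ratio: str = "100:0",
                         seed: int = 0) -> pd.DataFrame:
    """Simulate a dye-labeled co-culture flow-cytometry event table.

    Each event starts in an origin population; with probability
    ``transition_probs[(origin, dest)]`` its intensities are drawn from the
    destination population's (G, R) distribution instead.  The dye label
    records the origin (emulating eFluor 450 staining of the sorted input
    population), so transition frequencies are measurable after re-culture.
    """
    means = dict(FLOW_DEFAULT_MEANS, **(per_population_means or {}))
    sds = dict(FLOW_DEFAULT_SDS, **(per_population_sds or {}))
    transition_probs = dict(transition_probs or {})
    for p in transition_probs.values():
        if not 0.0 <= p <= 1.0:
            raise ValueError("transition probabilities must be in [0, 1]")
    origin_fractions = dict(origin_fractions or {"SPR": 1.0})
    rng = np.random.default_rng(seed)

    origins = list(origin_fractions)
    origin_idx = rng.choice(len(origins), size=n_events,
                            p=[origin_fractions[o] for o in origins])
    rows = {"event_id": np.arange(n_events)}
    origin_col = np.array([origins[i] for i in origin_idx], dtype=object)
    dest_col = origin_col.copy()
    u = rng.random(n_events)
    for o in origins:
        mask = origin_col == o
        # sequential allocation of destination states by transition prob
        cum = 0.0
        for (src, dst), p in transition_probs.items():
            if src != o or p == 0.0:
                continue
            take = mask & (u >= cum) & (u < cum + p)
            dest_col[take] = dst
            cum += p
            if cum > 1.0:
                raise ValueError(f"transition probabilities out of {o} exceed 1")
    g = np.empty(n_events)
    r = np.empty(n_events)
    for d in np.unique(dest_col):
        mask = dest_col == d
        mg, mr = means[d]
        sg, sr = sds[d]
        g[mask] = rng.normal(mg, sg, mask.sum())
        r[mask] = rng.normal(mr, sr, mask.sum())
    df = pd.DataFrame({
        "event_id": np.arange(n_events),
        "G_intensity": np.clip(g, 0, None),
        "R_intensity": np.clip(r, 0, None),
        "condition": condition,
        "mixture_ratio": mixture_ratio,
    })
    if dye_labeling:
        df["origin"] = origin_col
        df["dye_positive"] = np.isin(origin_col, list(dyed_origins))
    return df


# ---------------------------------------------------------------------------
# bulk expression tables

_CLASS_TARGET_S = {"SPR-like": 1.0, "intermediate": 0.0, "SPF-like": -1.0}


def simulate_expression_table(n_genes: int = 2000,
                              frac_spr_like: float = 0.48,
                              frac_intermediate: float = 0.30,
                              frac_distinct: float = 0.20,
                              effect_size: float = 2.5,
                              n_reps: int = 3,
                              seed: int = 0,
                              *,
                              n_de: int = 300,
                              frac_spf_like: Optional[float] = None,
                              rep_sd: float = 0.25,
                              base_mean: float = 6.0,
                              base_sd: float = 2.0) -> tuple:
    """Simulate a gene × population × replicate log2 expression table.

    ``n_de`` genes get SPR and SPF means separated by ``effect_size`` log2
    units; each DE gene's DP mean is placed according to its similarity
    class (SPR-like at the SPR mean, SPF-like at the SPF mean,
    intermediate at the midpoint, distinct outside the SPR–SPF interval).
    Returns ``(table, truth)`` where truth records each gene's class.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if frac_spf_like is None:
        frac_spf_like = 1.0 - frac_spr_like - frac_intermediate - frac_distinct
    fracs = {"SPR-like": frac_spr_like, "intermediate": frac_intermediate,
             "distinct": frac_distinct, "SPF-like": frac_spf_like}
    if any(f < -1e-9 for f in fracs.values()) or sum(fracs.values()) > 1 + 1e-9:
        raise ValueError("class fractions must be non-negative and sum to <= 1")
    if n_de > n_genes:
        raise ValueError("n_de cannot exceed n_genes")
    rng = np.random.default_rng(seed)

    base = rng.normal(base_mean, base_sd, n_genes)
    classes = np.array(["null"] * n_genes, dtype=object)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    labels = list(fracs)
    probs = np.array([fracs[c] for c in labels], dtype=float)
    probs = probs / probs.sum()
    class_draw = rng.choice(len(labels), size=n_de, p=probs)
    classes[de_idx] = [labels[i] for i in class_draw]

    sign = rng.choice([-1.0, 1.0], size=n_genes)
    is_de = classes != "null"
    mean_spr = base + np.where(is_de, sign * effect_size / 2.0, 0.0)
    mean_spf = base - np.where(is_de, sign * effect_size / 2.0, 0.0)
    s_target = np.zeros(n_genes)
    for cls, s in _CLASS_TARGET_S.items():
        s_target[classes == cls] = s
    distinct_sign = rng.choice([-1.0, 1.0], size=n_genes)
    s_target[classes == "distinct"] = 2.0 * distinct_sign[classes == "distinct"]
    mean_dp = mean_spf + (s_target + 1.0) / 2.0 * (mean_spr - mean_spf)
    mean_dp[~is_de] = base[~is_de]

    rows = []
    gene_ids = np.array([f"gene_{i:05d}" for i in range(n_genes)])
    for pop, mu in (("SPR", mean_spr), ("DP", mean_dp), ("SPF", mean_spf)):
        for rep in range(1, n_reps + 1):
            noise = rng.normal(0.0, rep_sd, n_genes) if rep_sd > 0 else 0.0
            rows.append(pd.DataFrame({
                "gene_id": gene_ids, "population": pop, "replicate": rep,
                "log2_expression": mu + noise,
            }))
    table = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame({
        "gene_id": gene_ids, "true_class": classes, "is_de": is_de,
        "true_similarity": np.where(is_de, s_target, np.nan),
        "mean_SPR": mean_spr, "mean_DP": mean_dp, "mean_SPF": mean_spf,
    })
    return table, truth
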