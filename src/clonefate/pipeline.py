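"""End-to-end orchestration: simulate → quantify → classify → trajectory →
heterogeneity → similarity → transitions → report.

A single :class:`RunConfig` (YAML round-trippable) drives every stage.
The global seed is fanned out deterministically: child seed i of stage
``name`` is ``SeedSequence([global_seed, STAGE_INDEX[name]])``, so any
stage can be rerun in isolation and reproduce its outputs bitwise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import classify as cls
from . import heterogeneity as het
from . import similarity as sim
from . import synthetic as syn
from . import trajectory as traj
from . import transitions as trans
from .quantify import filter_wells

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "STAGE_INDEX"]

STAGE_INDEX = {
    "simulate_th17": 0, "simulate_treg": 1, "pixels": 2,
    "flow": 3, "expression": 4, "bootstrap": 5,
}


def stage_seed(global_seed: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(global_seed), STAGE_INDEX[stage]])


@dataclass
class RunConfig:
    """All pipeline parameters; every field has a default."""

    seed: int = 0
    n_clones_th17: int = 190
    n_clones_treg: int = 190
    n_pixel_wells: int = 60            # wells rendered at pixel level
    n_artificial_pairs: int = 30
    # classification
    k: float = 3.0
    persistence_frames: int = 2
    endpoint_frames: int = 5
    # heterogeneity
    bin_width_deg: float = het.DEFAULT_BIN_WIDTH_DEG
    smoothing_sigma_deg: float = het.DEFAULT_SMOOTHING_SIGMA_DEG
    min_prominence_frac: float = het.DEFAULT_MIN_PROMINENCE_FRAC
    min_separation_deg: float = het.DEFAULT_MIN_SEPARATION_DEG
    intensity_floor: float = het.DEFAULT_INTENSITY_FLOOR
    pixel_background: float = 2.0
    # similarity
    n_genes: int = 2000
    n_de: int = 300
    effect_size: float = 2.5
    n_reps: int = 3
    fc_threshold: float = sim.DEFAULT_FC_THRESHOLD
    p_threshold: float = sim.DEFAULT_P_THRESHOLD
    denominator_floor: float = sim.DEFAULT_DENOMINATOR_FLOOR
    # transitions
    n_flow_events: int = 5000
    transition_spr_dp: float = 0.217
    transition_dp_spr: float = 0.1501
    mixture_ratios: tuple = ("100:0", "75:25", "50:50")
    # population overrides (PopulationSpec fields)
    th17: dict = field(default_factory=dict)
    treg: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "mixture_ratios" in data:
            data["mixture_ratios"] = tuple(data["mixture_ratios"])
        return cls(**data)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mixture_ratios"] = list(self.mixture_ratios)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _child_seed(ss: np.random.SeedSequence, i: int) -> int:
    return int(np.random.SeedSequence(ss.entropy, spawn_key=(i,))
               .generate_state(1)[0] % (2**31 - 1))


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every analysis stage; write tabular outputs and a summary JSON.

    Any stage failure aborts with an error naming the stage; outputs of
    completed stages are retained in ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {"config_hash": config.config_hash(), "seed": config.seed}
    stage = "simulate"
    try:
        if config.n_clones_th17 <= 0 or config.n_clones_treg <= 0:
            raise ValueError("n_clones must be > 0 for both conditions")
        th17 = syn.th17_spec(n_clones=config.n_clones_th17, **config.th17)
        treg = syn.treg_spec(n_clones=config.n_clones_treg, **config.treg)
        rec_th17 = syn.simulate_population(
            th17, _child_seed(stage_seed(config.seed, "simulate_th17"), 0))
        rec_treg = syn.simulate_population(
            treg, _child_seed(stage_seed(config.seed, "simulate_treg"), 0))
        records = rec_th17 + rec_treg
        syn.write_population_csvs(records, outdir)

        stage = "classify"
        meta = syn.population_metadata(records)
        t0_G = np.array([r.trace.total_G[0] for r in records])
        t0_R = np.array([r.trace.total_R[0] for r in records])
        threshold = cls.compute_response_threshold(t0_G, t0_R, k=config.k)
        t0_sig = pd.DataFrame({"well_id": [r.well_id for r in records],
                               "t0_G": t0_G, "t0_R": t0_R})
        included = set(filter_wells(meta, t0_sig, threshold))
        calls = [cls.classify_clone(r.trace, threshold,
                                    config.persistence_frames,
                                    config.endpoint_frames)
                 for r in records if r.well_id in included]
        calls_df = cls.calls_frame(calls)
        calls_df.to_csv(outdir / "calls.csv", index=False)

        th17_calls = calls_df[calls_df["condition"] == "Th17"]
        fate_counts = th17_calls["fate"].value_counts()
        summary["fate_fractions_th17"] = {
            f: float(fate_counts.get(f, 0) / len(th17_calls)) for f in
            ("SPR", "SPF", "DP", "DN")}
        groups = {
            "SPR/G": th17_calls.loc[th17_calls.fate == "SPR", "rise_time_G"],
            "DP/G": th17_calls.loc[th17_calls.fate == "DP", "rise_time_G"],
            "DP/R": th17_calls.loc[th17_calls.fate == "DP", "rise_time_R"],
            "SPF/R": calls_df.loc[(calls_df.condition == "Treg") &
                                  (calls_df.fate == "SPF"), "rise_time_R"],
        }
        summary["rise_times"] = cls.summarize_rise_times(
            groups, pairs=[("SPR/G", "DP/G"), ("DP/R", "SPF/R")])
        summary["division"] = cls.division_vs_rise(calls_df)

        stage = "trajectory"
        by_id = {r.well_id: r for r in records}
        def fate_traces(cond_df, fate):
            return [by_id[w].trace for w in cond_df.loc[cond_df.fate == fate,
                                                        "well_id"]]
        spr_traces = fate_traces(th17_calls, "SPR")
        dp_traces = fate_traces(th17_calls, "DP")
        spf_traces = fate_traces(calls_df[calls_df.condition == "Treg"], "SPF")
        spr_med = traj.median_traces(spr_traces, "SPR")
        dp_med = traj.median_traces(dp_traces, "DP")
        spf_med = traj.median_traces(spf_traces, "SPF")
        observed = traj.phase_trajectory(dp_med)
        expected = traj.extrapolated_trajectory(spr_med, spf_med)
        dist = traj.trajectory_distance(observed, expected)
        null = traj.bootstrap_half_distances(
            dp_traces, n_boot=200,
            rng=np.random.default_rng(stage_seed(config.seed, "bootstrap")))
        traj_out = {
            "distance_dp_vs_extrapolated": dist,
            "bootstrap_null_p95": float(np.percentile(null, 95)),
            "observed": observed.tolist(), "expected": expected.tolist(),
            "times": dp_med.times.tolist(),
        }
        (outdir / "trajectory.json").write_text(json.dumps(traj_out, indent=1))
        summary["trajectory"] = {k: traj_out[k] for k in
                                 ("distance_dp_vs_extrapolated",
                                  "bootstrap_null_p95")}

        stage = "heterogeneity"
        rng = np.random.default_rng(stage_seed(config.seed, "pixels"))
        pixel_wells = {}
        candidates = [r for r in records if r.well_id in included and
                      r.params.fate != "DN"]
        chosen = rng.choice(len(candidates),
                            size=min(config.n_pixel_wells, len(candidates)),
                            replace=False)
        for i in chosen:
            r = candidates[i]
            pixel_wells[r.well_id] = (r.params.fate, syn.simulate_well_pixels(
                r.params, th17 if r.trace.condition == "Th17" else treg,
                well_id=r.well_id, pixel_background=config.pixel_background))
        het_kwargs = dict(
            bin_width_deg=config.bin_width_deg,
            smoothing_sigma_deg=config.smoothing_sigma_deg,
            intensity_floor=config.intensity_floor,
            background=(config.pixel_background, config.pixel_background),
            min_prominence_frac=config.min_prominence_frac,
            min_separation_deg=config.min_separation_deg)
        reports = []
        for well_id, (fate, frames) in pixel_wells.items():
            dist_ = het.angle_distribution(
                frames, config.bin_width_deg, config.smoothing_sigma_deg,
                config.intensity_floor,
                (config.pixel_background, config.pixel_background))
            rep = het.detect_peaks(dist_, config.min_prominence_frac,
                                   config.min_separation_deg)
            reports.append({"well_id": well_id, "true_fate": fate,
                            "n_peaks": rep.n_peaks_capped,
                            "peak_angles": ";".join(f"{a:.1f}" for a in
                                                    rep.peak_angles),
                            "classification": rep.classification})
        peaks_df = pd.DataFrame(reports)
        peaks_df.to_csv(outdir / "peaks.csv", index=False)
        sprs = [f for _, (fate, f) in pixel_wells.items() if fate == "SPR"]
        spfs = [f for _, (fate, f) in pixel_wells.items() if fate == "SPF"]
        artificial = [het.compose_artificial_heterogeneous(a, b, "SPR", "SPF")
                      for a, b in zip(sprs, spfs)][:config.n_artificial_pairs]
        fp, sens = het.evaluate_detector(
            [f for _, (fate, f) in pixel_wells.items()], artificial,
            **het_kwargs)
        summary["heterogeneity"] = {
            "n_wells": len(pixel_wells),
            "multipeak_fraction": fp,
            "artificial_sensitivity": sens,
            "peak_count_percentages": {
                str(k): float(v) for k, v in
                (peaks_df["n_peaks"].value_counts(normalize=True) * 100)
                .sort_index().items()},
        }

        stage = "similarity"
        expr, _truth = syn.simulate_expression_table(
            n_genes=config.n_genes, n_de=config.n_de,
            effect_size=config.effect_size, n_reps=config.n_reps,
            seed=_child_seed(stage_seed(config.seed, "expression"), 0))
        sim_table = sim.similarity_table(
            expr, config.denominator_floor, config.fc_threshold,
            config.p_threshold)
        sim_table.to_csv(outdir / "similarity.csv")
        de = sim_table[sim_table["de_any"]]
        summary["similarity"] = {
            "n_de_union": int(de.shape[0]),
            "bin_fractions": {k: float(v) for k, v in
                              de["bin"].value_counts(normalize=True).items()},
            "pairwise_de_counts": {c: int(sim_table[c].sum()) for c in
                                   sim_table.columns if c.startswith("de_")
                                   and c != "de_any"},
        }

        stage = "transitions"
        flow_seed = _child_seed(stage_seed(config.seed, "flow"), 0)
        tables = []
        for j, ratio in enumerate(config.mixture_ratios):
            spr_frac = {"100:0": 1.0, "75:25": 0.75, "50:50": 0.5}.get(ratio, 0.5)
            tables.append(syn.simulate_flow_events(
                config.n_flow_events,
                transition_probs={("SPR", "DP"): config.transition_spr_dp,
                                  ("DP", "SPR"): config.transition_dp_spr},
                origin_fractions={"SPR": spr_frac, "DP": 1 - spr_frac}
                if spr_frac < 1 else {"SPR": 1.0},
                mixture_ratio=ratio, seed=flow_seed + j))
        flow = pd.concat(tables, ignore_index=True)
        # gate thresholds calibrated on an unstimulated (DN) tube
        naive = syn.simulate_flow_events(
            500, origin_fractions={"DN": 1.0}, dye_labeling=False,
            mixture_ratio="naive", seed=flow_seed + 1000)
        flow_thr = cls.compute_response_threshold(
            naive["G_intensity"], naive["R_intensity"], k=config.k)
        freqs = trans.transition_frequencies(flow, thresholds=flow_thr)
        freqs.to_csv(outdir / "transitions.csv", index=False)
        pooled = freqs[(freqs.origin == "SPR") & (freqs.destination == "DP")]
        summary["transitions"] = {
            "SPR_to_DP_percent_by_ratio": {
                row["mixture_ratio"]: float(100 * row["frequency"])
                for _, row in pooled.iterrows()},
            "ratio_homogeneity": trans.compare_across_ratios(freqs, "SPR", "DP"),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True))
    return summary
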