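"""Transcriptome similarity of the double-positive population.

Given bulk log2 expression for SPR, DP and SPF populations with
replicates, this module selects differentially expressed genes (fold
change >= 2 and Welch-test p < 0.05 between any pair) and places each
gene's DP mean on the SPR–SPF axis via a similarity index

    s = 2 * (mean_DP - mean_SPF) / (mean_SPR - mean_SPF) - 1

so that s = +1 means DP expression matches SPR and s = -1 matches SPF.
Indices are binned at ±0.5 / ±1.5 into SPF-like, intermediate, SPR-like
and distinct (beyond either single-positive level).
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "population_means", "differential_genes", "similarity", "similarity_table",
    "bin_similarity", "population_correlation",
    "DEFAULT_FC_THRESHOLD", "DEFAULT_P_THRESHOLD", "DEFAULT_DENOMINATOR_FLOOR",
    "POPULATIONS", "BIN_BREAKPOINTS",
]

POPULATIONS = ("SPR", "DP", "SPF")
PAIRS = (("SPR", "DP"), ("SPR", "SPF"), ("DP", "SPF"))
DEFAULT_FC_THRESHOLD = 2.0
DEFAULT_P_THRESHOLD = 0.05
DEFAULT_DENOMINATOR_FLOOR = 0.25       # log2 units
BIN_BREAKPOINTS = (-1.5, -0.5, 0.5, 1.5)


def _pivot(table: pd.DataFrame) -> pd.DataFrame:
    """gene × (population, replicate) wide view of a tidy expression table."""
    required = {"gene_id", "population", "replicate", "log2_expression"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"expression table is missing columns {sorted(missing)}")
    wide = table.pivot_table(index="gene_id", columns=["population", "replicate"],
                             values="log2_expression")
    for pop in POPULATIONS:
        if pop not in wide.columns.get_level_values(0):
            raise ValueError(f"population {pop!r} absent from the table")
        if wide[pop].shape[1] < 2:
            raise ValueError(f"population {pop!r} needs >= 2 replicates")
    return wide


def population_means(table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean log2 expression of each population (columns SPR/DP/SPF)."""
    wide = _pivot(table)
    return pd.DataFrame({pop: wide[pop].mean(axis=1) for pop in POPULATIONS})


def differential_genes(table: pd.DataFrame,
                       fc_threshold: float = DEFAULT_FC_THRESHOLD,
                       p_threshold: float = DEFAULT_P_THRESHOLD) -> pd.DataFrame:
    """Flag DE genes per population pair; fold change AND Welch-test rule.

    A gene is DE for a pair when |mean difference| >= log2(fc_threshold)
    and the Welch t-test p-value < p_threshold.  Genes constant across
    all replicates of all populations have no defined test and are
    excluded with a warning.  The returned frame has one boolean column
    per pair plus ``de_any`` (the union over the three pairs).
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1 (linear fold change)")
    wide = _pivot(table)
    constant = wide.std(axis=1, ddof=0).to_numpy() == 0
    if constant.any():
        log.warning("%d genes constant across all replicates excluded from DE",
                    int(constant.sum()))
    lfc_min = np.log2(fc_threshold)
    out = pd.DataFrame(index=wide.index)
    for a, b in PAIRS:
        va, vb = wide[a].to_numpy(), wide[b].to_numpy()
        diff = np.abs(va.mean(axis=1) - vb.mean(axis=1))
        t, p = stats.ttest_ind(va, vb, axis=1, equal_var=False)
        flag = (diff >= lfc_min) & (p < p_threshold)
        flag[constant | np.isnan(p)] = False
        out[f"de_{a}_{b}"] = flag
    out["de_any"] = out.any(axis=1)
    out.loc[constant, "de_any"] = False
    return out


def similarity(mean_spr: float, mean_dp: float, mean_spf: float,
               denominator_floor: float = DEFAULT_DENOMINATOR_FLOOR) -> float:
    """Similarity index of one gene; NaN when SPR ≈ SPF (denominator floor)."""
    denom = mean_spr - mean_spf
    if abs(denom) < denominator_floor:
        return float("nan")
    return float(2.0 * (mean_dp - mean_spf) / denom - 1.0)


def similarity_table(table: pd.DataFrame,
                     denominator_floor: float = DEFAULT_DENOMINATOR_FLOOR,
                     fc_threshold: float = DEFAULT_FC_THRESHOLD,
                     p_threshold: float = DEFAULT_P_THRESHOLD) -> pd.DataFrame:
    """Per-gene means, DE flags, similarity index and bin label."""
    means = population_means(table)
    de = differential_genes(table, fc_threshold, p_threshold)
    denom = means["SPR"] - means["SPF"]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = 2.0 * (means["DP"] - means["SPF"]) / denom - 1.0
    s = s.where(denom.abs() >= denominator_floor)
    out = means.join(de)
    out["similarity"] = s
    out["bin"] = bin_similarity(s)
    return out


def bin_similarity(indices) -> pd.Series:
    """Bin similarity indices at the ±0.5 / ±1.5 breakpoints.

    [-1.5, -0.5) → SPF-like, [-0.5, 0.5) → intermediate,
    [0.5, 1.5] → SPR-like; outside [-1.5, 1.5] → distinct-low/high;
    undefined indices → "undefined".
    """
    index = indices.index if isinstance(indices, pd.Series) else None
    s = pd.Series(np.asarray(indices, dtype=float), index=index)
    lo, a, b, hi = BIN_BREAKPOINTS
    bins = pd.Series("undefined", index=s.index, dtype=object)
    bins[s < lo] = "distinct-low"
    bins[(s >= lo) & (s < a)] = "SPF-like"
    bins[(s >= a) & (s < b)] = "intermediate"
    bins[(s >= b) & (s <= hi)] = "SPR-like"
    bins[s > hi] = "distinct-high"
    bins[s.isna()] = "undefined"
    return bins


def population_correlation(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation (3×3) of per-gene population mean expression."""
    means = population_means(table)
    if len(means) < 50:
        raise ValueError("population correlation needs >= 50 genes")
    corr = np.corrcoef(means.to_numpy().T)
    return pd.DataFrame(corr, index=POPULATIONS, columns=POPULATIONS)
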