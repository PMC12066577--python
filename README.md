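# clonefate

Clone-level analysis of dual-reporter T-cell differentiation in micro-well
arrays.

## The problem

When naive CD4⁺ T cells are activated under Th17-polarizing conditions, some
clones up-regulate only RORγt (the Th17 master transcription factor), while a
distinct population co-expresses RORγt *and* Foxp3 (the Treg master factor).
Whether this double-positive (DP) state is a genuine cell state — with its own
transcriptome and stable dynamics — or an artifact of mixed or transitioning
cells is hard to settle with endpoint flow cytometry alone.

`clonefate` implements the quantitative pipeline for answering this with
dual-reporter (RORγt-GFP / Foxp3-RFP) data from micro-well arrays, where each
well holds one founder cell imaged every 30 minutes for 52 h:

1. **Well quantification** — total background-subtracted fluorescence per
   channel per frame; inclusion filter (1 cell, ≥ 1 activation bead, dark at
   t0).
2. **Clone classification** — response threshold calibrated from naive t0
   signals (mean + k·sd, k = 3); the rise time in channel *c* is the first
   time the trace starts a persistent run (2 frames) above threshold;
   presence/absence of a rise per channel calls the clone SPR / SPF / DP / DN.
3. **Phase-plane trajectories** — median ± std traces per fate; the DP
   trajectory in the (Foxp3, RORγt) plane is compared with the *extrapolated*
   trajectory pairing SPF's Foxp3 dynamics with SPR's RORγt dynamics, scored
   by a normalized RMSD

   `d = sqrt(mean ||obs_t − exp_t||²) / sqrt(mean ||exp_t||²)`

   with a split-half bootstrap null. Small `d` ⇒ the two reporters rise
   independently even when co-expressed.
4. **Intra-clonal heterogeneity** — every retained pixel is reduced to its
   angle in the (RFP, GFP) plane (0° = pure Foxp3 reporter, 90° = pure RORγt,
   ~45° = co-expression); the last-5-frame angle histogram is
   Gaussian-smoothed and local maxima are counted. One peak ⇒ homogeneous
   clone; two or more ⇒ a mixed clone. Artificial heterogeneous clones
   (union of an SPR and an SPF well's pixels) validate the detector.
5. **Similarity index** — for each differentially expressed gene
   (fold change ≥ 2, Welch p < 0.05), the DP population's mean log2
   expression is placed on the SPR–SPF axis:

   `s = 2·(mean_DP − mean_SPF)/(mean_SPR − mean_SPF) − 1`

   so s = +1 matches SPR and s = −1 matches SPF, binned at ±0.5 / ±1.5 into
   SPF-like / intermediate / SPR-like / distinct.
6. **Transition frequencies** — dye-labeled co-culture flow tables are
   quadrant-gated and the fraction of origin-*o* events found in state *d*
   is compared across mixture ratios with a chi-square homogeneity test.

A synthetic-data module generates all three input modalities (traces +
pixels, flow event tables, expression tables) with the statistical structure
these analyses assume, so the full pipeline is testable without the imaging
dataset.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic data
(each reads the previous script's outputs from `results/`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_classify_clones.py
```

which prints, among other things:

```
threshold: G 172.6, R 172.0 (mean + 3 sd of 380 naive t0 signals)
wells passing the 1-cell / >=1-bead / dark-at-t0 filter: 377/380
Th17 fate mix (%): {'SPR': 63.1, 'DP': 19.8, 'DN': 17.1}
rise time SPR/G: 23.7 ± 8.9 hr (n=118, median 24.0)
rise time DP/R:  37.2 ± 6.9 hr (n=37, median 37.0)
Welch t-test SPR/G vs DP/G: p = 0.287
fraction of rises after first division: RORγt 0.08, Foxp3 0.59
median first division (hr): {'Th17': 38.4, 'Treg': 36.9} p = 0.000705
```

RORγt rises early (~22 h) and Foxp3 late (~39 h); each reporter's timing is
the same whether it rises alone or in a DP clone (Welch p ≫ 0.05); RORγt
rises before the first division while Foxp3 mostly rises after it.
`analysis/03_trajectories.py` then reports

```
DP vs extrapolated SPR×SPF trajectory: normalized RMSD = 0.121
(split-half null 95th pct = 0.220) -> consistent with independent reporter dynamics
```

and `analysis/04_heterogeneity.py` finds 0 % multi-peak wells among true
clones but 100 % among artificial SPR×SPF compositions — clones are
internally homogeneous, and the detector would see it if they were not.
Scripts 05 and 06 reproduce the DP transcriptome placement (≈48 % SPR-like /
29 % intermediate / 22 % distinct) and the composition-insensitive
SPR↔DP transition frequencies (≈21.7 % and ≈15 %).

The same pipeline runs from a single config via the CLI:

```bash
clonefate all --config run.yaml --out results/run
```

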