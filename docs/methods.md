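# Methods

## Generative model of a micro-well clone

Each clone (one micro-well, one founder cell) is simulated per channel
*c* ∈ {G = RORγt-GFP, R = Foxp3-RFP} as

    F_c(t) = baseline + amplitude_c · σ((t − onset_c)/w) · growth(t) + ε_t

on a frame grid of 0.5 h over 52 h (105 frames), with σ the logistic
function, `w` the rise width, and ε_t i.i.d. Gaussian frame noise. The
logistic form is a modelling choice: the measured readout is "time of rise
above a threshold", and a monotone curve with a well-defined midpoint makes
that readout identifiable. `onset_c` is the midpoint.

**Fates.** A clone's fate decides which channels carry signal: SPR (G only),
SPF (R only), DP (both), DN (neither; amplitudes 0). Fates are drawn from
per-condition fractions — Th17: 57 % SPR / 22 % DP / 21 % DN; Treg: 46 % SPF /
20 % DP / 34 % DN.

**Onset distributions.** Active-channel onsets are drawn from truncated
normals on [0, duration]: RORγt ~ N(21.8, 9.4²) h, Foxp3 ~ N(39.3, 8.2²) h.
Truncation implements two constraints: onsets are non-negative, and a clone
whose reporter never rises within the experiment would by definition not be
positive in that channel. A consequence worth stating explicitly: the
within-window mean of the Foxp3 distribution is ≈ 38.3 h, so any estimator
reading rise times off a 52-h record recovers the windowed mean, about 1 h
below the nominal 39.3. An alternative reading of the source statistics
(±0.07 as a standard error rather than ±8.2 as an sd) can be configured via
`onset_R_dist`.

**Division and growth.** First division ~ N(38.8, 6²) h (Th17) or
N(36, 6²) h (Treg), subsequent divisions every 12 h. The sd of 6 h is chosen
so a cohort of ~90 wells has a standard error of ≈ 0.6 h on its median. Total
signal is continuous at divisions (daughters split the parent's fluorophore
content); between successive divisions the production term ramps
exponentially so that it has doubled by the next division, and it stays flat
after the last observed division. Cell *count* doubles discretely at each
division — this distinction matters only for pixel rendering.

**Default magnitudes.** baseline 100, frame-noise sd 25, amplitude 150
(arbitrary fluorescence units). The amplitude default deliberately places
the naive response threshold (mean + 3 sd of t0 signals ≈ baseline + 75) at
the half-rise point of the logistic, so the first-crossing rise-time
estimator is centred on the onset midpoint rather than systematically early
(a threshold far below half-rise is crossed ~`w·ln(amplitude/δ − 1)` before
the midpoint, where δ is the threshold's height above baseline).

**Pixel rendering.** Pixel sets are abstract (no spatial layout — nothing
downstream uses geometry). Per frame, each of the `n_cells` cells owns 12
pixels sharing the cell's signal equally on top of a flat pixel background
(2.0, noise sd 1.0); 150 background pixels carry background plus noise.
Pixel noise is seeded per frame, so rendering only the last five frames
(all the angle analysis consumes) reproduces exactly what a full render
would give there.

**Flow events and expression tables.** Flow events are two-channel Gaussian
mixtures per population (DN at (100, 100) ± 15, positives at 1000 ± 200 on
the positive channel(s)); an event transitions from its origin to a
destination population with the configured probability and keeps its origin
dye label. Expression tables place each DE gene's SPR and SPF means
±effect/2 (default 2.5 log2 units) around a N(6, 2²) base and position the
DP mean by the gene's similarity class (s = 1, 0, −1, ±2 for SPR-like /
intermediate / SPF-like / distinct), with N(0, 0.25²) replicate noise,
three replicates.

## Estimators and numerical choices

* **Threshold**: mean + k·sd of naive t0 signals, default k = 3, ≥ 10 wells
  required. k = 0 (threshold at the mean) is allowed.
* **Rise time**: first frame starting ≥ 2 consecutive frames above
  threshold ("persistence" suppresses single-frame noise crossings);
  absent if no such run by the final frame. First persistent crossing, not
  a fitted midpoint.
* **Endpoint MFI**: mean total fluorescence over the last 5 frames, the
  same window the angle analysis pools.
* **Angles**: computed from background-subtracted, zero-clipped intensities;
  (0, 0) pixels carry no angle; pixels with combined intensity below the
  intensity floor (default 4.0 ≈ background mean + 2 sd of the combined
  channels) are discarded as noise-dominated. `arctan2(G, R)` in degrees:
  R = 0 → 90°, G = 0 → 0°.
* **Angle histogram**: bin width 3° with bin *centers* on multiples of the
  width, so 0°, 45° and 90° are representable peak locations; Gaussian
  smoothing with sigma = 6° (2 bins) and mirror boundary handling, which
  reflects mass about the 0°/90° centers and preserves boundary modes.
* **Peak detection**: strict local maxima of the smoothed density,
  *including* the boundary bins (a mode at 0° or 90° is genuine — pure-SPF
  and pure-SPR clones live there); topographic prominence with array
  borders acting as valleys and an empty side imposing no base; candidates
  need prominence ≥ 5 % of the density maximum; greedy pruning keeps the
  higher peak when two candidates are closer than 15°. Off-the-shelf
  detectors that ignore boundary samples halve the sensitivity on composed
  SPR×SPF wells, which is why this one is written out; the test suite
  checks it against an exhaustive brute-force scan. "2 peaks" in reports
  means ≥ 2.
* **Trajectory distance**: RMS pointwise Euclidean distance divided by the
  RMS magnitude of the expected trajectory; invariant to joint rescaling;
  compared on the shared acquisition grid with no time warping. The
  "agreement" reference value is 0.1; the split-half bootstrap of the DP
  set provides the population-size-aware null.
* **DE test**: Welch t-test on log2 values per population pair, flagged at
  |Δmean| ≥ log2(2) and p < 0.05, union over the three pairs; no
  multiple-testing correction (the selection rule is a raw-p rule);
  constant genes are excluded with a warning. The similarity index is
  undefined when |mean_SPR − mean_SPF| < 0.25 log2 units (denominator
  floor), binned "undefined".
* **Gating**: quadrant gate against per-channel thresholds calibrated from
  a declared negative (naive/unstimulated) event population, same mean +
  k·sd rule. Origin groups under 20 events are flagged low-confidence.

## What the generator emulates — and what it does not

It reproduces the statistical structure the analyses rely on: per-channel
sigmoidal onsets with fate-specific distributions, division-driven growth,
within-clone pixel homogeneity, event-level state transitions with dye
provenance, and per-gene DP placement between the single-positive
populations. It does **not** model cell death, asymmetric division,
migration between wells, regulatory interactions between the two factors,
spatial image structure (segmentation, bead detection and ROI finding are
out of scope; well ROIs and division times enter as metadata/annotations),
spectral spillover in flow data, or count-based RNA-seq noise. Passing
tests therefore demonstrate that the estimators recover the truth under
this generative model at realistic noise — not that the model captures
every failure mode of real imaging data.

## Problem sizes

The analysis scripts use 190 clones per condition (380 wells, of which 120
are pixel-rendered), 2000-gene expression tables with 300 DE genes, and
5000-event flow tables per mixture ratio. The acceptance script uses
200-clone cohorts for rise times, 400 wells for detector specificity,
1000 clones for fate fractions and 5000 events for transitions; recovery
tolerances are stated in standard-error units of those sizes.

## Known limitations

* The windowed-mean effect on late onsets (above) is inherent to any
  finite-duration rise-time readout; estimates of the Foxp3 mean carry a
  ≈ −1 h offset relative to the nominal generating mean.
* The Treg-condition "low-level DP" clones are not modelled as a separate
  class; a secondary high-expression threshold would be needed to split
  them and is not enabled by default.
* The bootstrap null for trajectory agreement uses split halves, so it is
  conservative for very small DP groups (< ~20 clones).
* Histogram-based peak locations are reported at bin centers (3°
  granularity); no sub-bin interpolation is performed.
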