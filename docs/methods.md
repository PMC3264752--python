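# Methods

This note records the models, conventions and numerical choices behind
`melanotrack`, in the order the pipeline runs.

## Synthetic movies and the motion model

The generator (`melanotrack.simulate`) emulates a transmitted-light +
fluorescence recording of pigmented organelles in a thin, flat region of
cytoplasm. Defaults describe the acquisition the pipeline targets: a
20×20 µm field imaged for 100 frames at 1 frame/s with 16 pixels per
micrometre, holding 50 particles of radius 0.12–0.22 µm.

**Two-state motion.** Each particle occupies either a *static* or a *motile*
state. The state sequence is a two-state Markov chain with geometric dwell
times: with per-particle static occupancy `p` and dwell scale `d`
(`state_dwell_frames`, default 8 frames), the leave rates are
`q(static→motile) = (1−p)/d` and `q(motile→static) = p/d`, which makes `p`
exactly the stationary static occupancy whatever `d`. `d = 1` gives a
memoryless chain in which the state (and the run speed) is redrawn every
frame. The literature on this system describes observed speed regimes, not
a generative process; the geometric-dwell switch is the simplest process
exhibiting both docking and directed runs, and is a stand-in rather than an
inference about the real dwell statistics.

- A **static** particle takes an isotropic Gaussian step each frame.
  `static_jitter_sigma` (default 0.015 µm) is the *RMS frame-to-frame
  displacement* (per-axis sd is `sigma/√2`). This convention makes the
  displacement distribution Rayleigh with scale `sigma/√2`, so the maximum
  over the ~5 000 events of a typical fixed-sample movie sits near
  `sigma·√(ln n)` ≈ 0.04–0.05 µm and the median near `0.83·sigma` ≈
  0.013 µm/s at 1 fps — the regime reported for immobilised samples.
- A **motile** particle performs a directed run: speed drawn uniformly from
  `motile_speed_range` (default 0.1–0.8 µm/s, the microtubule-transport
  regime) once per run, direction persistent with angular diffusion of
  0.3 rad/frame, plus the same jitter.
- The field boundary reflects.
- **Excluded volume.** Solid pigment cores cannot interpenetrate, so after
  each step any pair of particles closer than contact (sum of radii plus a
  0.08 µm gap) is pushed apart symmetrically, with a few relaxation sweeps.
  Without this, motile particles settle on top of neighbours and remain
  merged in the transmitted channel for whole dwell periods, which is both
  unphysical and ruinous for tracking evaluation. A small tail of
  frame-to-frame displacements therefore exceeds the drawn run speed (a
  pushed particle moves further); tests bound the bulk of the speed
  distribution, not its extreme order statistics.

**Label–motility coupling.** Each particle's fluorescence label level is
drawn uniformly from `label_intensity_range`. With `coupling_sign =
"negative"`, the static occupancy is `p = (1−motile_fraction) +
coupling_strength·(u−0.5)` (clipped to [0, 1]), where `u` is the label level
rescaled to [0, 1]; `"positive"` mirrors the sign and `coupling_strength = 0`
decouples the two. Coupling acts on state occupancy, not on within-state
speed: one knob reproduces the structure of interest (more static events at
high MMFI). The default `motile_fraction = 0.37` makes ~63% of events
static, the live-cell figure this class of recordings reports; the default
`coupling_strength = 0.5` spans per-decile static fractions of roughly
40–85%.

**Rendering.** The transmitted channel is a bright background (200 a.u.)
minus a soft-edged disc per particle (depth 150 a.u., linear edge ramp one
pixel wide, giving sub-pixel centroid information); each fluorescence
channel is a uniform cytosolic background (12 a.u.) plus a Gaussian spot per
particle with sd `0.7·radius` and amplitude equal to the label level;
additive Gaussian noise (sd 2.5 a.u.) goes on every channel. No PSF, TIRF
evanescent-depth or photobleaching modelling. Identical seeds give
bit-identical movies.

`simulate_fixed_sample` forces the motile state off (the jitter then
represents residual localisation noise); `simulate_ground_truth` +
`ground_truth_events` bypass rendering entirely and emit event tables with
speeds from true positions and MMFI = label + Gaussian measurement noise —
used where the statistics stage needs large n and rasterisation would
dominate cost.

## Detection

Particles are dark on bright (melanin absorbs; a polarity flag inverts).
Pixels below the intensity threshold (Otsu of frame 0 when not given) are
foreground; 8-connected components with area inside `[min_area, max_area]`
(defaults 0.02–0.50 µm²) become observations. The upper bound deliberately
admits a pair of touching organelles as a single particle — clusters merge
into one reported component; there is no watershed splitting. Centroids are
unweighted mask centroids, 0-based, pixel-centre origin at top-left,
reported in µm. MFI per fluorescence channel is the mean over the
transmitted-light mask (no dilation) minus the per-frame background
estimate: the median intensity outside all foreground pixels (global frame
median as fallback, logged). Background correction can be disabled for
recordings pre-selected for high organelle:cytosol signal ratio; MFI may
then legitimately be ≤ 0 after subtraction elsewhere.

## Tracking

"Shortest-path" linking is realised as per-frame-pair globally optimal
gated assignment: the one-to-one partial matching minimising total squared
centroid displacement subject to a hard gate (default 1.2 µm, ≈1.5× the
fastest per-frame step at default settings), maximal in cardinality among
gated matchings, solved as a padded linear sum assignment problem. The
dummy (non-match) penalty exceeds any achievable total pair cost, so an
extra match is always preferred; exact cost ties break toward
lexicographically smallest index pairs via an infinitesimal perturbation.
No gap closing, no merge/split handling, no motion-model prediction.
Matchings chain into tracks; tracks shorter than `min_track_length`
(default 10 frames) are discarded and the count logged — together with the
census report (track count, Σ(length−1) data points, length histogram),
this replaces manual visual authentication with auditable numbers.

## Events

One event per consecutive observation pair: speed = Euclidean displacement
/ frame interval; per-channel MMFI = mean of the two bounding observations'
MFI (the frame-t vs frame-t+1 attribution of intensity to a displacement is
inherently ambiguous; the symmetric mean is stable); size = mean of the two
areas. Ratios (channel A / channel B) are computed only where the
denominator exceeds `epsilon` (default a machine-scale 1e−9 when background
subtraction is active; 0 otherwise); excluded events stay in the table
flagged NaN and are counted, never silently dropped. Channel normalisation
divides by the per-cell median of the channel — a robust, scale-free choice
for an operation whose exact form is a genuinely open design point.

## Statistics

- **Static threshold**: maximum event speed of the fixed-sample event set
  (source `fixed_calibration`), else the conventional 0.05 µm/s default.
  Classification is *inclusive* (static iff speed ≤ threshold): only the
  inclusive comparison makes a sample 100% static against its own
  calibrated maximum.
- **Decile binning** is per cell (compensating expression differences):
  events stably sorted by the binning variable (MMFI, MMFI ratio, or size);
  rank r of N goes to bin ⌊r·n_bins/N⌋, so bin sizes differ by ≤1 and sum
  to N. Cells with fewer events than bins are an error naming the cell.
- **Three reporting layers**, all implemented separately because all three
  are used: per-cell per-bin summaries (median speed, motile-only median
  with an explicit undefined flag when a bin has no motile events, percent
  static); hypothesis tests on bins pooled across cells by bin index;
  cross-cell aggregates as mean ± SEM (sample sd/√n_cells, undefined for a
  single cell) of per-cell bin medians. Every report value carries a
  provenance label.
- **Kruskal–Wallis** (tie-corrected, chi-square p, via scipy) with **Dunn's
  post-test**: pairwise z from pooled mid-ranks with the standard tie
  correction, two-sided normal p, Bonferroni over all k(k−1)/2 pairs — the
  conventional reading of "Dunn's post-test" in legacy graphing packages;
  the adjustment method is recorded in the report. All-identical input
  degenerates to H = 0, p = 1.
- **Mann–Whitney**: scipy, exact p for small tie-free samples, otherwise
  normal approximation with tie correction.
- **Spearman**: tie-corrected (mid-rank) r; 95% CI by Fisher z with
  variance 1.06/(n−3), the standard Spearman-specific inflation; zero
  variance in either variable yields an undefined flag rather than an
  error.
- **Percentiles** (5/25/50/75/95 speed summary) use linear interpolation,
  stated in the output, because box-plot conventions differ.

## Validation strategy and problem sizes

Every non-trivial algorithm is checked against an independent oracle that
shares no code with the implementation: gated linking against brute-force
enumeration of all partial matchings (≤6 particles per frame, 200 random
instances); KW H, Dunn z, Mann–Whitney exact p and tied Spearman r against
direct textbook-formula/enumeration implementations at total n ≤ 9 (the KW
chi-square p is compared with the full permutation null, where the
approximation is good to a few hundredths at such n); binning against the
explicit rank formula. Pipeline-level properties run on synthetic movies:
link recovery ≥95% on the default 50-particle movie; threshold closure
(fixed sample classifies itself 100% static) through the full
detect-track-event path on a 40-particle, 60-frame fixed movie; coupling
recovery on 5 000 trajectory-level events at the weakest covered coupling
(0.5); null calibration of the KW rejection rate over 200 replicate
1 200-event data sets, asserted inside the central 95% binomial band.

The null calibration uses the generator's memoryless configuration
(`state_dwell_frames = 1`), under which events are independent and the
pooled-event KW test is exercised under its own assumptions. This is a
deliberate and documented caveat: with persistent dwells, events cluster
within particles, the pooled-event test is anti-conservative, and its
nominal 5% level is not attained — a limitation shared by any analysis that
pools frame-to-frame events as if independent, including the workflow this
package automates. The per-cell mean-of-medians reporting layer is the
robust counterpart.

## What passing tests do and do not show

The generator omits optical blur, Poisson shot noise, photobleaching,
organelle shape variation, focus drift and dense perinuclear clustering.
Passing recovery tests therefore demonstrates correctness of the
algorithms under the stated model, not performance on arbitrary real
microscopy; on real data the practical limits are dense clusters (merged
components are reported as single particles and their tracks break, by
design) and fast motion beyond the gate. All defaults are exposed in
`SimulationConfig`, `DetectionParams`, `TrackingParams` and
`AnalysisParams`.
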