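# melanotrack

Correlative analysis of organelle motility and membrane-associated protein
content in multi-channel time-lapse microscopy.

## The problem

Peripheral membrane proteins such as Rab GTPases and their effectors are
recruited to organelle membranes, where they regulate transport — switching
organelles between fast microtubule-based runs and slow actin-dependent
movement or docking. Watching organelle movement alone cannot say *which*
organelles carry the protein. When the organelle is intrinsically visible in
transmitted light (the pigmented melanosome is the canonical case) and the
protein of interest carries a fluorescent tag, both quantities can be read
from the same recording: each tracked organelle contributes, for every pair
of consecutive frames, one **movement event** with

- a frame-to-frame speed `s_i = |x(t_{i+1}) − x(t_i)| / Δt` (µm/s), and
- a mean organelle-associated fluorescence intensity (**MMFI**) `f_i`,
  measured over the organelle's transmitted-light mask and
  background-corrected.

`melanotrack` implements the full pipeline: particle detection by intensity
and size/area filters, frame-to-frame linking by gated minimum-cost
assignment, removal of tracks shorter than 10 frames, event extraction,
classification of events as **static** (speed ≤ threshold, where the
threshold is calibrated as the maximum event speed observed in a chemically
fixed sample — by construction 100% of the fixed sample is static) or
**motile**, per-cell binning of events into MMFI deciles, and the
nonparametric test battery: Kruskal–Wallis with Dunn's Bonferroni-adjusted
post-test across bins, Mann–Whitney for pairwise data-set comparisons, and
Spearman rank correlation with a Fisher-z 95% confidence interval for full
scatters. A two-channel mode bins events by the MMFI ratio of two
fluorophores and reports per-bin normalized intensities of each channel.

Because real recordings of this kind are rarely deposited, the package ships
a first-class synthetic-movie generator with known ground truth (positions,
static/motile state sequences, label levels), so every stage is testable:
dark soft-edged discs on a bright transmitted background, Gaussian
fluorescence spots whose amplitude is the particle's label level, and a
two-state motion model whose static-state occupancy can be coupled —
negatively, positively, or not at all — to the label level.

## Worked example

```
melanotrack simulate --seed 7 --out-prefix cell1
melanotrack track cell1.tif --cell-id cell1 --out-prefix cell1
melanotrack simulate --seed 8 --fixed --out-prefix fixed
melanotrack track fixed.tif --cell-id fixed --out-prefix fixed
melanotrack analyze cell1_events.csv --fixed-events fixed_events.csv --out-prefix analysis
```

The first four commands synthesise and track a live-condition movie (50
particles, 20×20 µm, 100 frames at 1 frame/s, 16 px/µm) and a fixed-sample
movie, printing their track censuses:

```
census: 63 tracks, 4881 frame-to-frame data points
census: 50 tracks, 4950 frame-to-frame data points
```

The final command calibrates the static threshold from the fixed sample,
bins the live events into MMFI deciles and runs the statistics:

```
threshold 0.0636 µm/s (fixed_calibration); 4881 events in 1 cell(s); 59.1% static
```

`analysis_report.json` then contains, among other fields: the calibrated
threshold (0.0636 µm/s — the maximum fixed-sample event speed, slightly
above the generator's nominal jitter because measured speeds include
localisation noise); the overall static fraction (59.1%); the
MMFI–speed Spearman correlation `r = −0.270` (95% CI −0.297 to −0.243,
p ≈ 2e−82), recovering the generator's negative label–motility coupling;
Kruskal–Wallis `H = 396.9` (p ≈ 6e−80) across the ten MMFI bins with the
Dunn pairwise matrix; and the per-bin percent-static profile rising from
38.4% in the lowest-MMFI decile to 82.0% in the highest — the signature of
a protein enriched on docked organelles. Every value is labelled with its
provenance (pooled events vs mean ± SEM of per-cell bin medians).

Pre-computed event tables from other tracking software can enter directly at
`melanotrack analyze` as CSV with columns
`cell_id, track_id, frame, speed_um_s, mmfi_ch1[, mmfi_ch2], size_um2`.

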