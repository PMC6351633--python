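# Methods

## Model and procedure

A *measurement* is a time-ordered series of centroided scans from one
continuous acquisition of one sample. The pipeline has five stages.

**Binning.** Peaks in [`mz_min`, `mz_max`) are assigned to half-open bins
`[mz_min + i·w, mz_min + (i+1)·w)` by `floor((mz − mz_min)/w)`;
co-binned peaks are summed (which preserves the TIC exactly and makes
TIC normalization commute with binning); out-of-range peaks are dropped
and tallied. Defaults `mz_min=100`, `mz_max=1300`, `w=0.01` Da give a
dense dimension N = 120 000; the 0.01 Da width matches a mass precision
of ~2 ppm over this range, coarsening the data to the measurement's own
precision and no further. Vectors are stored sparse (scipy CSR), but all
contracts are over the dense semantics: an absent bin is a zero.

**Similarity.** Pearson's r uses the mean over all N coordinates, zeros
included; sparse evaluation reproduces dense semantics exactly through
`Σ(X−X̄)(Y−Ȳ) = ΣXY − N·X̄·Ȳ` (and likewise for the variances). The
cosine measure needs no centering. Matrices are computed blockwise from
the stacked sparse scan matrix (one Gram product), symmetrized to remove
float asymmetry from summation order, clipped into [−1, 1], and the
diagonal set to exactly 1 for non-degenerate rows. Degenerate vectors
(all-zero; for Pearson also constant over all N coordinates) get value 0
rather than NaN: NaN would poison downstream medians and plots, while 0
renders degenerate scans as visible low-similarity bands. Cosine is the
default pipeline metric — on 10⁵-dimensional nonnegative vectors it
differs negligibly from r and costs less.

**Moving median.** Output spectrum k is the per-bin median of input
scans `[k·step, k·step + window)`. Windows are leading, not centered —
centered windows would need edge padding — and only full windows are
emitted (`⌊(n − window)/step⌋ + 1` outputs), because edge medians over
fewer than `window` scans would have different breakdown properties.
Windows must be odd so the median is a single order statistic. Since
intensities are nonnegative, a bin absent from more than half of a
window's scans has median 0, so the implementation only densifies the
columns actually occupied in the window. With clean values holding the
majority in every window, an artifact run of length ≤ ⌊window/2⌋ is
removed *exactly*. Default `window=51, step=51` (non-overlapping windows,
~1 minute of acquisition each) for sample-level profiling; `step=1`
retains maximal time detail for inspecting profile changes within a run.

**Artifact filtering.** Each raw scan is scored by its cosine to a
reference spectrum, the mean of the median-smoothed series. ("Aggregate
of the smoothed scans" rather than "smoothed aggregate scan": a single
aggregate spectrum has no time axis left to smooth, so the latter reading
collapses; the chosen reading yields a reference that isolated artifact
scans cannot pull.) A fixed threshold in [0, 1] may be supplied; the
default `auto` rule is described below. Degenerate (all-zero) scans are
always rejected. The consensus spectrum is the sum or mean over kept
scans only.

**Visualization.** Heatmaps use one fixed value→color mapping per report
(default viridis over [0, 1]) so panels are comparable; negative Pearson
values are clamped to 0 for display only, never in stored matrices. Scans
run by measurement then time, origin top-left. The value→color mapping is
a pure function exposed separately from rendering.

## The automatic threshold

Good scans score close to 1; their deviations `d = 1 − score` are a
weighted sum of squared relative intensity errors — chi-square-like with
few effective degrees of freedom when a handful of peaks dominates the
squared norm, hence strongly right-skewed. Two shapes of good-scan score
distribution occur in practice: a tight skewed cluster, and a *bimodal*
one, produced when a dominant peak lies within the m/z jitter of a bin
edge and hops bins from scan to scan. A location–scale rule
(median − k·MAD, on any scale) fails on one shape or the other: on the
raw scale it clips the skewed tail; on the log scale the bimodal spread
inflates the MAD until the fence passes the d ≤ 1 bound and nothing is
rejected.

The `auto` rule therefore keys on the defining feature of genuine
artifacts — they are *detached* from the score mass and *near total
dissimilarity* — instead of on distribution shape. With
`m = median(log d)` over non-degenerate scans, the sorted `log d` values
are scanned for the lowest gap such that everything above it satisfies
`log d > m/3` (the deviation has crossed two-thirds of the log-distance
from the typical deviation to d = 1) and the gap exceeds `ln 2` (a
factor-two jump separates the rejected scans from the rest). The
threshold is the gap midpoint mapped back to the score scale,
`1 − exp(cut)`; if no such gap exists, no scan is score-rejected. The
two constants are interpretable rather than fitted: a scan that has not
lost most of its log-distance to "unrelated spectrum", or that is merely
the continuation of the score tail, is not called an artifact. In seeded
validation across default, low-noise, high-noise, drifting and
artifact-free regimes (220 runs) the rule recovered the injected
artifact set exactly in all but one run at 3× the default noise, where it
failed conservatively by rejecting nothing.

A scan whose only anomaly is overall intensity (a TIC spike or dropout
with intact profile direction) is invisible to any scale-invariant score
by construction; the TIC trace (`tic_trace`, `plot_tic`) is the
complementary diagnostic for those.

## Synthetic measurements

The generator emulates needle-electrospray acquisitions: ~300 scans per
measurement, 50 peaks per profile drawn uniformly over m/z 100–1300 with
intensities spanning two decades (log-uniform — a lipid-like dynamic
range in which a few peaks dominate the vector norm), per-peak
multiplicative log-normal noise (`noise_sigma`, default 0.1), a per-scan
log-normal TIC scale factor (`scale_sigma`, default 0.2, mimicking spray
output fluctuation), m/z jitter of ±2 ppm (the instrument precision;
deliberately large enough that peaks near m/z 1300 can hop 0.01 Da bins),
optional linear drift of the profile toward an independent target
(`drift_rate` per scan, default 0), and injected artifact scans of three
kinds: `tic_spike` (×10 scale plus spurious peaks), `tic_dropout`
(×0.01 scale), `foreign_profile` (an unrelated profile at normal TIC).
All draws come from one `numpy.random.default_rng(seed)` stream, so a
config is fully reproducible. A study groups fragments that share one
base profile (fresh noise per fragment) within samples whose profiles
differ.

What the generator does *not* emulate: isotope patterns, adducts,
lipid-class m/z structure, correlated (non-iid) peak noise, centroiding
errors, and chemical background common to all samples. Consequences for
interpretation: between-sample similarities here are near 0 because
independent random 50-peak profiles rarely share bins, whereas real
tissue lipid profiles overlap heavily and show intermediate similarity;
and artifact recovery on synthetic data demonstrates the mechanics of the
score-gap rule, not its false-rejection rate on real score distributions,
which can be broader. Passing tests show the pipeline is correct and the
rule is robust to the modeled noise sources, not that the default
threshold rule is optimal for any particular instrument.

## Numerical choices

* Degeneracy: a vector counts as constant when its variance is below
  10⁻¹² of its squared norm; degenerate similarity is 0, flagged.
* Matrix symmetry is enforced by averaging with the transpose; values
  clipped into [−1, 1]; diagonal set to 1 for non-degenerate rows.
* Score deviations are floored at 10⁻¹⁵ before taking logs, so identical
  scans (score exactly 1) remain representable.
* Peak tables are parsed with numpy's correctly-rounded float parser and
  written with `%.17g`, so write→read round-trips are exact.
* Duplicate m/z within a scan are summed at read time, consistent with
  binning semantics.
* Scans with zero peaks are retained by default (flagged and rejected at
  QC); readers accept `drop_empty_scans=True` for the other convention.

## Problem sizes used in tests and the acceptance script

Deterministic small grids for exact properties (vectors up to N = 1000,
series up to 300 scans); 20 seeded runs at the study conditions
(300 scans × 50 peaks, 5 foreign-profile artifacts, noise 0.1) for
recovery rates; a 2-samples × 2-fragments study (1200 scans total) for
block structure and the smoothing trend. These sizes reproduce the
qualitative regime of a real study day at desk scale.

## Known limitations

* mzML support is read-only and centroid-only; profile-mode spectra are
  rejected, not centroided.
* Uniform bins only; no ppm-adaptive binning or peak alignment, so peaks
  sitting on a bin edge can split between bins (the similarity metrics
  tolerate this; see the threshold discussion).
* The cosine/Pearson score cannot detect scale-only artifacts (TIC
  spikes/dropouts with intact profiles); screen the TIC trace.
* Moving-median guarantees hold for artifact runs up to ⌊window/2⌋
  consecutive scans; longer instability periods require a wider window
  or manual exclusion.
* Heterogeneous samples whose profile genuinely changes during
  acquisition produce legitimately low within-measurement similarity;
  the tools expose this (step-1 smoothing, block summaries) but do not
  classify it.
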