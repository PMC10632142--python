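# Methods

This note documents the models, parameter choices and numerical decisions
behind `retinads`, and what the synthetic-data tests do and do not show
about real recordings.

## ΔF/F and response extraction

ΔF/F = (F − F₀)/F₀ with F₀ the mean raw fluorescence over the last 23 s
before the first stimulus onset. If less pre-stimulus recording exists, all
available frames are used and a warning is emitted; a non-positive F₀ is
rejected as non-physical. Background correction subtracts either a no-laser
control recording or a background-ROI trace elementwise before ΔF/F.

Per-epoch responses are the maximum ΔF/F within [t_on, t_off + 1 s]; the
1-s tail captures indicator decay after stimulus offset. Maxima are taken
per trial and then averaged per direction (not the maximum of the trial
average) — with three trials the two differ whenever response timing
jitters.

Slow background oscillations are removed by a zero-phase second-order
Butterworth high-pass (`sosfiltfilt`). At a 0.05 Hz cutoff this attenuates
a 0.01 Hz oscillation to ~4% while transients much shorter than 1/cutoff
retain ≥90% of their peak. A running-percentile detrend
(`method="percentile"`, 10th percentile over 3/cutoff seconds) is available
as an alternative, but it cannot suppress oscillations slower than its
window, which is why the linear filter is the default. The cutoff is a free
parameter; nothing in the source protocol pins it.

Responsiveness uses the strict rule: mean per-epoch peak amplitude
> 1.5 × the ΔF/F standard deviation over the baseline window. The mean is
taken over all epochs (all directions), configurable; an amplitude of
exactly 1.5 sd is not responsive.

## Tuning statistics

Negative trial peaks are clipped to 0 before vector summation so that
NVS = |V|/ΣR is guaranteed to lie in [0, 1]; with all-zero responses the
magnitude is 0 and the angle is flagged undefined rather than invented.

The von Mises fit uses least squares with μ₀ at the vector-sum angle,
R_max₀ at the peak response, κ₀ = 1 and κ bounded to [0, 50]. On exact
model data the fit recovers (R_max, μ, κ) to <1%; on constant data it
degenerates cleanly to κ = 0 with R_max at the constant. Non-convergence is
reported (`fit_ok=False`) without discarding the raw statistics.

DSI uses preferred = argmax of the trial-mean responses (ties broken toward
the vector-sum angle) and null = preferred + 180°. For drug comparisons the
pre-drug axis is retained, so a response that flips under GABA_A blockade
yields a negative DSI — the signature seen in blockade experiments.

Group comparisons use the two-sided Wilcoxon rank-sum (Mann–Whitney U,
exact null when untied) and the Wilcoxon signed-rank test for paired data;
all-tied paired input returns p = 1 with a warning instead of an error.

## Pixel vector-sum mapping

The movie is converted to ΔF/F per pixel with the same 23-s baseline rule
(shared code path with ROI processing), spatially Gaussian filtered
(σ = 2 px, reflect boundary; filtering is 2D per frame), max-projected per
bar presentation, averaged per direction, and vector-summed per pixel. The
reported magnitude is the raw |V| (heat-map convention); |V|/ΣR is returned
alongside.

Dark pixels make the per-pixel division unstable, so a pixel is kept only
when its F₀ exceeds both the 1st-percentile of the F₀ image and 5% of its
99th percentile. The absolute floor matters for synthetic fields, where
most of the frame is genuinely unlabelled; in real bolus-loaded tissue
nearly all pixels carry background fluorescence and the floor is inactive.

Candidates are 8-connected components above the 0.995 magnitude quantile
with area ≥ 4 px, reported with centroid, area and magnitude-weighted
circular-mean angle. The quantile is a software default, not a biological
claim. At the standard test conditions (fields of 5 DS + 15 untuned cells,
peak SNR 5, 3 trials) detection achieves sensitivity ≈ 1.0 and precision
≈ 0.98 with ~2° angle error over 10 seeds.

## Mosaic statistics

VDRI = mean/sd of Voronoi domain areas, computed with the population (n)
denominator; a domain is excluded when it is unbounded or any vertex lies
outside or on the region boundary. With these conventions uniform-random
mosaics give a seed-averaged VDRI of ≈1.89 at large n and ≈2.03 at the
small-sample condition of 54 points at 13.14 cells/mm² (small samples bias
the index upward). Zero spread (a perfect lattice) is flagged infinite.
Null distributions use uniform points at exactly matched n and region.

The DRP counts neighbours in 20-µm annuli from 0 to 1000 µm. Each annulus
area is corrected by its intersection with the sampling region using a
closed-form circle–rectangle overlap (validated against polygon-clipping to
0.1%); polygon regions fall back to shapely. Density(r) = Σᵢ countsᵢ /
Σᵢ areaᵢ over reference points i, reported per mm². The well density is the
mean of the 3 lowest-density bins excluding the first bin (elevated
variance from its tiny area); the plateau is the mean density over
390–1000 µm; convergence = well/plateau × 100.

### Superposed mosaics

Pooling k independent regular mosaics dilutes both signatures of
regularity, but not equally. The pooled pair-correlation deficit at short
range is (k−1)/k of the plateau rather than 0, so the DRP well of a k = 3
union is shallow and, at realistic sample sizes, indistinguishable from
flat — convergence rises from ~0% per component to ≳40% for the union.
The VDRI, by contrast, retains a detectable excess: in simulations across
packing ratios 0.2–0.6 and n = 150–1500, the union's VDRI sat above its
matched random-null 95th percentile in 35 of 36 runs. The discriminating
statistic for the multiple-mosaic inference is therefore the DRP well
(absent in the union, complete in each component) together with the VDRI
*dilution* (union below the component mean), not a fall of the union VDRI
all the way into the random band. Real pooled mosaics behave the same way:
a pooled regularity index slightly above matched random simulations is the
expected signature of superposed subtype mosaics.

Coverage factor is the plain product density × dendritic-field area (3.73
at 31.1 cells/mm² and 0.119892 mm²); no per-sample averaging scheme is
imposed. Density grids use 500-µm cells; cells flagged unusable are imputed
by the mean of their valid 8-neighbours, or left missing with a warning
when isolated.

## Classification

Marker intensities are z-scored per imaging batch with the population
denominator, making downstream clustering invariant to per-batch affine
gain/offset drift. k-means (k-means++, 10 restarts, recorded seed) labels
the higher-first-channel cluster as the BNC2-high type; clustering is
flagged degenerate when centroid separation falls below twice the
within-cluster spread (a single biological class). The threshold classifier
is the strict z > threshold rule; its agreement with k-means is the
cross-check used in practice.

FISH dots per cell = (integrated − background·area)/single-dot intensity,
floored at 0 and kept non-integer; positivity thresholds are strict
(>40 BNC2, >80 FSTL4). Artifact exclusion (vessels, high cell background)
is a boolean input column, not an image operation.

The marker screen normalises each cell to the median library size, takes
the natural-log fold change of cluster means (base configurable; "2 log
fold" is read as natural log, the common single-cell convention), and
excludes a foveal/peripheral pair when any screened gene has |lfc| > 2 and
rank-sum p < 0.05. With no true fold change the simulated exclusion rate
stays at or below the nominal level (the conjunction makes the screen
conservative).

## Morphometry

Depth profiles subtract the mean background, normalise to the maximum,
clip negatives to 0, and map z linearly between the INL and GCL border
positions (either acquisition direction; the axis is re-ordered to be
increasing). Contact fractions sum per-slice overlap of the reference and
partner binary masks as a percentage of total reference area. The rotation
control turns the partner 90° in-plane about the volume centre: exact
(`rot90`, area-conserving) for square frames, nearest-neighbour resampling
with reported area loss otherwise.

## Synthetic-data generators

The movie generator's defaults follow the standard recording protocol:
8 directions in pseudorandomized blocks (each direction once per block),
3 trials, 500 µm/s bars, 5-s inter-stimulus interval, 35-s pre-stimulus
period (≥ the 23-s baseline window). A cell's response to a bar epoch is
its von Mises amplitude times a boxcar — from the moment the bar's leading
edge reaches the soma centre, lasting width/speed — convolved with a causal
exponential of the indicator decay constant (default τ = 0.5 s; the real
indicator's kinetics are not published, so τ is a free parameter, not a
claim) and normalised so the continuous-time peak equals the programmed
amplitude. Somas are isotropic 2D Gaussians (σ = radius/2, truncated at
3σ); noise is additive Gaussian per pixel per frame (Poisson optional).

Consequences worth knowing: at fast bar speeds the crossing (e.g. 0.4 s at
500 µm/s for a 200-µm bar) is short relative to τ and the frame interval,
so sampled peaks sit a few percent below the programmed amplitude —
direction-selectivity statistics are scale-invariant and unaffected, but
exact amplitude-recovery checks use slow, wide bars. At peak SNR 5 the
per-epoch max estimator has a positive noise bias, which saturates the NVS
of extremely sharp cells (κ = 8 measures slightly below κ = 4); NVS remains
monotone in κ over the useful range.

Mosaic generation: uniform i.i.d. (random), sequential dart-throwing with a
10⁴·n rejection budget (exclusion; infeasible packings raise with the
achieved count), or the union of k independent exclusion mosaics at
density/k (superposition). Marker tables are class-conditional Gaussians;
expression matrices are negative-binomial (dispersion 0.5, log-normal gene
means around 5 counts) with programmed natural-log fold changes between
declared foveal/peripheral partners.

What the generators do *not* model: optics and PSF, motion artefacts,
vascular shadowing, indicator nonlinearity, spatially correlated noise, and
ROI segmentation error (ROIs come from ground truth). Passing tests
therefore validate the statistics and their implementations under the
stated statistical structure, not robustness to those real-data nuisances.

## Problem sizes and determinism

Default validation sizes: 160-µm fields with 20 cells and 3 trials at 4 Hz
for mapping; 150–200 seeds for small-sample VDRI averages and 20 seeds at
n = 10,000 for the large-n benchmark; 99 simulations per VDRI null; 200
simulated cluster pairs for the screen's error rate. Every stochastic
routine takes an explicit seed; the pipeline runner derives per-stage seeds
(< 2³¹) from one root seed and records them in its manifest, and rerunning
a config reproduces every output bit-for-bit.

## Units

Coordinates and distances in µm, densities per mm² (conversion fixed at
10⁻⁶ mm²/µm²), times in s, angles in degrees of stimulus motion on the
retina (superior = 90°, temporal = 0°, inferior = 270°, nasal = 180°, with
an explicit chirality flip for mounted tissue). Retinal magnification uses
223 µm per degree of visual angle (macaque), exposed as
`retinads.MACAQUE_UM_PER_DEG`; 500 µm/s ≙ 2.24 deg/s.
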