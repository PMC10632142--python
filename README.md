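# retinads

Quantitative analysis of direction-selective retinal ganglion cells
(DSGCs), for researchers characterising rare cell types in primate retina
by combining two-photon calcium imaging, immunofluorescence, fluorescence
in situ hybridization (FISH), and mosaic spatial statistics.

ON-type DSGCs — the retinal neurons that feed gaze-stabilisation reflexes —
make up only 1–2.5% of ganglion cells, so identifying them requires a chain
of statistics rather than a single assay. `retinads` implements that chain
as a tested library, together with synthetic-data generators that emulate
every input with known ground truth, so the whole pipeline runs and is
validated without any microscope data.

## What it computes

**Direction tuning** (`imaging`, `tuning`). Somatic fluorescence is
converted to ΔF/F = (F − F₀)/F₀ with F₀ the mean over a 23-s pre-stimulus
window, and per-epoch peak responses are averaged over trials per motion
direction. Tuning is summarised by:

- the *normalized vector sum* NVS = |Σ R_d (cos θ_d, sin θ_d)| / Σ R_d,
  which is 0 for untuned and 1 for perfectly directional cells;
- the *direction selectivity index* DSI = (R_pref − R_null)/(R_pref + R_null),
  ranging −1…1, negative when the residual response flips to the opposite
  direction (e.g. under GABA_A blockade);
- a von Mises fit R(x) = R_max · exp(κ cos((x − μ)·π/180)) / exp(κ), the
  circular analogue of the Gaussian, giving preferred direction μ and
  tuning width κ.

**DS-soma mapping** (`dsmap`). The per-pixel analogue: the ΔF/F movie is
Gaussian filtered (σ = 2 px), max-projected per bar presentation, averaged
per direction, and vector-summed per pixel; clusters of high-magnitude
pixels mark candidate DS somas.

**Mosaic statistics** (`mosaic`). The Voronoi domain regularity index
(VDRI = mean/sd of border-excluded Voronoi domain areas; ≈1.9 for random
points, higher for regular mosaics) with matched random-null simulations,
the Rodieck density recovery profile (20-µm annuli to 1 mm, analytic edge
correction) with its exclusion-well convergence statistic, coverage factor
(density × dendritic-field area), 500-µm density grids with neighbour
imputation, and the equivalent-eccentricity transform √((0.61x)² + y²).

**Classification** (`classify`). Per-batch z-scoring of marker intensities,
k-means and threshold classifiers for two-marker (BNC2/FOXP2-style) tables,
FISH dot counting — dots = (integrated − background × area)/single-dot
intensity, with strict >40 (BNC2) and >80 (FSTL4) positivity thresholds —
and the foveal/peripheral expression screen that excludes cluster pairs
whose candidate receptor genes differ by >2 natural-log fold at P < 0.05
(Wilcoxon rank-sum).

**Morphometry** (`morpho`). IPL stratification depth profiles (0% = INL
border, 100% = GCL border) and co-fasciculation contact fractions with a
90°-rotation chance control.

**Synthetic data** (`synth`). Drifting-bar calcium movies with von
Mises-tuned and untuned cells, indicator decay and noise; random,
exclusion-zone and superposed soma mosaics; bimodal marker tables;
negative-binomial expression matrices with programmable fold changes;
wrapped-dendrite volumes. Every generator is seed-deterministic.

## Worked example

`examples/01_direction_tuning.py` builds a noiseless movie of one tuned
cell (programmed R_max = 0.5, μ = 90°, κ = 4), runs the ΔF/F pipeline and
prints:

```
NVS                = 0.866  (angle 90.0°)
DSI                = 0.999  (pref 90°)
von Mises fit      : r_max=0.500, mu=90.0°, kappa=4.00
ground truth       : r_max=0.500, mu=90.0°, kappa=4.00
```

The fit recovers the programmed tuning exactly; the NVS of 0.87 reflects a
strongly but not perfectly directional cell (responses at ±45° are still
31% of peak). The other examples cover vector-sum mapping
(`02_vector_sum_mapping.py`: all 5 implanted DS somas found at SNR 5 with
~2° angle error), mosaic statistics (`03`), marker/FISH/screen
classification (`04`) and depth/contact morphometry (`05`). A thin CLI
(`retinads synth|dff|tune|dsmap|mosaic|classify|dots|screen|morpho|run-all`)
wraps the same functions for shell use; `run-all` writes a run directory
with a provenance manifest.

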