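# Methods

`qdstem` models one specific measurement: counting individual membrane
receptors on intact cells by tagging them with streptavidin-conjugated
quantum dots (QDs) of two sizes and imaging the labels as bright spots in
annular dark-field STEM. Receptor surface densities (labels/µm²) per
membrane region and per cell subtype are the quantities of interest. This
note records the model behind each stage, the parameters that matter, and
the choices made where the design was genuinely open.

## Imaging model and the synthetic frame generator

A dark-field STEM frame of a QD-labelled membrane is modelled as

```
I(x, y) = B + T(x, y) + Σ_k A_k · disk_k(x, y) + noise
```

* `B` — flat background level (counts), default 3000.
* `T` — zero-mean Gaussian random field standing in for membrane and
  cytoplasmic material: white noise smoothed to a correlation length
  (default 50 px) and rescaled to SD `texture_amplitude` (default 500).
  Substrate-only (background-labelled) regions carry no texture.
* `disk_k` — a flat-top disk of the particle's sampled core diameter with
  a Gaussian-smoothed edge (σ = 1 px): QDs are solid crystals, and
  dark-field contrast is approximately projected mass, so the profile is a
  blurred top-hat, `0.5·erfc((ρ − r)/σ√2)`. Class amplitudes default to
  9000 (large) and 6000 (small) counts; the 1.5× ratio reflects the larger
  projected thickness of the bigger crystal.
* noise — Poisson counting noise applied to `I·g` and rescaled by the gain
  `g` (default 0.05 counts per intensity unit), a one-parameter stand-in
  for electron counting statistics. The default puts the particle peak at
  roughly 25× the background noise SD, a high-contrast regime; no detector
  MTF or scan distortion is modelled.

Geometry defaults follow the acquisition being emulated: 0.83 nm pixels,
512 × 512 px frames for tests (2048 × 2048 px frames are configurable).

**Particle placement.** Positions follow a homogeneous Poisson process at
the configured per-class density inside each region mask: the count is
drawn as Poisson(density × area) and positions are placed sequentially
(dart-throwing) when a hard-core minimum separation is set. Dart-throwing
rather than Matérn-style thinning is used so that the expected count stays
exactly density × area. Distances for the hard-core check are computed
toroidally: in a bounded window a plain rejection rule accepts more points
near the frame edge (fewer neighbours exclude area there), which measurably
depletes the interior at high densities; the periodic metric keeps the
process homogeneous and is strictly conservative (wrap distance ≤ real
distance, so the real-space minimum separation still holds).

**Rendered core diameters.** The two conjugates render at 10.0 ± 0.7 nm
(large) and 5.5 ± 0.5 nm (small). These are *electron-dense core* scales,
deliberately smaller than the full streptavidin conjugates (~14–18 nm and
~12 nm respectively), and they are calibrated against the detection
pipeline: the maximum-entropy threshold sits below the half-maximum of a
blurred particle, so the apparent (thresholded) radius exceeds the
rendered radius by roughly 0.5–1 px. With these cores the apparent size
distributions fall at the centres of the detection gates (9–13 nm for the
large class and its scaled-down counterpart for the small class). Both
diameters are configuration values, not claims about the physical
particles.

**Default densities** correspond to the most commonly sampled membrane
condition in the data being emulated (clustered regions: ~270 small and
~6.6 large labels/µm²). Region layouts for multi-region frames are
vertical strips by area fraction; fractions must sum to ≤ 1.

## Detection pipeline

The detector re-implements a classical ImageJ-style particle analysis as a
pure function of (image, config):

1. **Gaussian smoothing**, σ = 1.5 px ("radius 1.5 px" interpreted as
   sigma; the parameter is exposed so a radius ≈ 2.5σ convention can be
   tested).
2. **FFT bandpass.** Gaussian rolloff in squared radial frequency with
   half-power exactly at each cutoff: structures larger than the large
   cutoff — including the DC term — are suppressed, structures smaller
   than the small cutoff (default 2 px) attenuated. The output is shifted
   by its minimum to be non-negative for thresholding. The large cutoff
   defaults to **20 px**: besides removing cell-scale background it sets
   the width of the negative "moat" of local-mean subtraction around each
   particle, and thereby where the threshold contour lands on the blurred
   particle edge. A looser cutoff (e.g. 40 px) leaves that contour so far
   down the edge profile that apparent areas inflate past the
   diameter-derived gates; 20 px keeps apparent areas close to physical
   footprints while passing QD-scale structure (transfer ≈ 0.8 at 13 px).
3. **Maximum-entropy (Kapur) threshold** on a 256-bin histogram of the
   min–max rescaled filtered image: the split `t` maximizes the sum of
   Shannon entropies of the class-normalized histograms below and above
   `t`; zero-mass classes contribute zero; ties break to the smallest `t`
   (with a 1e-10 tolerance so analytically tied splits are not decided by
   round-off). Foreground = bins > t. A histogram with fewer than two
   occupied bins means nothing is detectable and yields empty output.
4. **Connected components** at 8-connectivity (configurable to 4);
   centroid = arithmetic mean of member pixel coordinates; components
   touching the frame edge are kept but flagged.
5. **Size gating.** The large gate is a closed physical-diameter interval
   (default 9–13 nm) converted to pixel area via `π(d/2)²/p²`; the small
   gate is derived by scaling both diameters by a ratio (default 7/11),
   clipped below the large gate's lower bound to keep the gates disjoint.
   Components are labelled large / small / rejected, exactly one label
   each; counts are conserved. Touching particles are not split (no
   watershed): merged blobs exceed the large gate and are rejected, which
   the recovery tests monitor.

Coordinates are 0-based, x = column, y = row, with pixel centres on the
integer grid (the simulator renders with the same convention, so truth
positions and detected centroids are directly comparable; centroid RMSE on
well-separated particles is ~0.1 px).

## Quantification

* Per-image density = count / analyzed area (labels/µm²).
* Group summaries by (cell subtype × region): mean and sample SD (n−1) of
  the per-image densities, plus the pooled density (total count / total
  area). Groups backed by one image report SD 0 with a flag. Particles
  outside every region mask are tallied as unassigned with a warning,
  so group counts + unassigned always equals the input count.
* Labeling-efficiency correction: receptor density = observed density /
  efficiency (defaults 0.80 small, 0.50 large). An alternative
  "increase-by-percentage" mode (× (1 + efficiency)) is provided because
  that reading of the calibration differs by up to ~25%; division is the
  default as the standard estimator.
* EGFR-enriched cell calling: cells at or above `fold` × a population
  reference (median by default, fold 2.0) of per-cell fluorescence are
  flagged; the reference is re-estimated once on the unflagged remainder
  and the flags finalized. One re-estimation pass makes the reference
  robust to the enriched tail without iterating to a fixed point; the rule
  is monotone in `fold`.
* Detector evaluation: greedy nearest-neighbour matching within a radius
  (default 5 px), each point used at most once; precision, recall, a
  (truth class × detected class) confusion matrix, and centroid RMSE over
  matches. Undefined ratios (no detections / empty truth) report 1.0 with
  an explicit flag. An optional border margin excludes truth and
  detections near the frame edge — the usual benchmarking convention,
  since boundary-cropped particles have no well-defined apparent size; it
  is off by default.

## Recovery benchmark

The published densities from real STEM frames cannot be reproduced without
the original images, so the substitute benchmark is parameter recovery on
simulated frames: 20 frames of 512 × 512 px per condition, conditions
spanning the reported density ranges (clustered regions: 270 small + 6
large labels/µm²; large membrane protrusions: 990 + 20), hard-core
separation 20 nm (at 990/µm² the blobs remain individually resolvable with
~9 nm edge gaps; a separation of 3× the particle diameter would exceed the
hard-core packing limit at that density), 10 px border exclusion, 5 px
match radius. At these settings the detector achieves per-class precision
and recall ≥ 0.95 (typically ≥ 0.98), class confusion below 1%, centroid
RMSE ≈ 0.1 px, and mean recovered densities within 3 SE of the programmed
values. Frame count and size were chosen to make the Poisson standard
error a few percent while keeping the suite fast.

## What passing tests do and do not show

The generator reproduces the *statistical* structure the pipeline relies
on — two well-separated size classes, high spot contrast, Poisson counting
noise, smooth cellular background — but not instrument-specific effects:
no probe convolution or multiple scattering, no graphene/liquid-layer
contrast, no scan distortion, no size-dependent QD shape (real large
conjugates are slightly elongated), and no spatial clustering of receptors
beyond region-level density differences. Recovery results therefore
validate the implementation of the pipeline, not its performance on real
micrographs; on real data the size gates are expected to need manual
adjustment exactly because apparent sizes depend on instrument PSF and
threshold placement (see the bandpass discussion above).

Known limitations:

* On a frame containing *no* particles but realistic noise, the rescaled
  histogram collapses onto the noise distribution and the maximum-entropy
  threshold lands inside it, producing spurious small components. This is
  intrinsic to histogram-normalized entropy thresholding (the original
  tooling behaves the same way); density estimates on particle-bearing
  frames are unaffected because the histogram range is then set by the
  particle amplitude.
* The per-image mean ± SD convention and the pooled count/area convention
  differ when per-image areas vary; both are reported, and they are only
  interchangeable when the per-image densities are homogeneous.
* Labeling efficiencies are treated as exact constants; no uncertainty is
  propagated through the correction.
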