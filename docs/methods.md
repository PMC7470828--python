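# Methods

This note documents the models and procedures `trpscope` implements, the
defaults that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Imaging model and preprocessing

### Movie model

Movies are T×Y×X (or T×Z×Y×X) grey-level arrays with a frame period
(default 4 s, i.e. 0.25 Hz volumetric acquisition) and a lateral pixel
size. z-stacks are averaged to one plane per time point before any other
processing.

### Drift correction

Each frame's translation relative to a reference image — the temporal mean
of the first `n_ref_frames` (default 10) pre-stimulus frames — is
estimated by phase cross-correlation and undone. Integer-pixel shifts are
the tested contract (`upsample_factor=1`); subpixel registration is
available. Out-of-field pixels are filled with edge values. Reported
`shifts[t]` is the frame's measured drift; the correction applied is its
negative. Constant (degenerate) frames get zero shift with a warning.

### Non-responsive mask and background surface

Pixels are classed *non-responsive* when their temporal coefficient of
variation (population SD over time / mean over time) falls below the Otsu
threshold of the CV map (256 equal-width bins). The CV of a pixel whose
temporal mean is ≤ 1e-6 × image max is set to 0 (flagged).

This criterion presumes substantial baseline fluorescence everywhere in
the field (tissue autofluorescence): CV then ranks pixels by transient
activity. With a near-black background the CV map inverts (dim noisy
pixels have the highest CV); the synthetic generator therefore defaults to
a bright background (see §5).

The background is a bivariate polynomial of total degree ≤ 4 (15 terms,
x^i·y^j with i+j ≤ 4, coordinates normalised to [-1, 1]) least-squares
fitted to the non-responsive pixels of the **time-averaged** image, and
subtracted from every frame (clamped at 0). "Fourth order" is read as
total degree, not degree per axis; both are configurable. The fit is
performed once, not per frame: the mask is defined by temporal statistics,
so the model is temporal by construction, and per-frame fitting would
absorb stimulus-locked signal. A rank-deficient design (mask confined to a
line) is rejected.

### Normalisation

F/F₀ and ΔF/F₀ = (F−F₀)/F₀ are computed against the pre-stimulus
reference of the background-corrected movie. Pixels with F₀ at or below a
guard are excluded (set to 0, flagged). In the assembled pipeline the
guard is 5% of the 99th-percentile F₀ — after background subtraction,
non-tissue pixels have F₀ ≈ 0 + noise, and a scale-free but tiny guard
(1e-6 × max, used elsewhere for division safety) would let ΔF/F₀ explode
there. A structure dimmer than 5% of the bright baseline is treated as
unmeasurable.

## 2. ROI extraction

### DRG somata

Import mode takes a label mask verbatim (mirroring manual/visual neuron
identification, which is the experimental ground-truth workflow).
Automatic mode band-passes the reference image at the soma scale
(difference of Gaussians), thresholds it at max(Otsu, median + 5 robust
SD) — the robust floor prevents Otsu's collapse when somata occupy a tiny
area fraction — splits touching somata by watershed on the distance
transform, and keeps blobs within the configured equivalent-diameter
range.

### Skin nerve endings: correlated-activity segmentation

A deterministic seed-and-grow segmenter replaces constrained
matrix-factorisation approaches, honouring the same contract (contiguous,
temporally coherent, pairwise-disjoint regions with a mean trace each):

* **Seeds** are pixels whose mean Pearson correlation with their
  8-neighbours exceeds `min_corr` (default 0.8) *and* whose activity
  passes an automatic Otsu gate. The gated statistic is the temporal SD
  divided by the pixel's own white-noise level (robust first-difference
  estimate, MAD/√2): on a ΔF/F₀ movie the raw SD is inversely weighted by
  baseline brightness, so dim pixels would otherwise dominate; the
  normalised statistic is ≈ 1 under white noise at any brightness and ≫ 1
  for stimulus-locked transients.
* **Growth** proceeds from the strongest seed outwards (FIFO, fixed
  neighbour order — fully deterministic): a neighbouring pixel joins when
  its correlation with the region's running mean trace is ≥ `min_corr`.
  Pixels are claimed at most once, so regions are disjoint and connected
  by construction.
* Regions smaller than `min_size_px` (default 10) are discarded; final
  labels are connected components.

Raising `min_corr` never increases total ROI area (monotonicity, tested).

### WGA retrograde-label classification

An ROI is WGA⁺ only if its mean intensity in the label channel strictly
exceeds background mean + 5 × background SD ("exceeded" ⇒ strict; boundary
cells are negative). Background defaults to all pixels outside the 3-px
dilation of the ROI set. The margin is stored per ROI for audit. The rule
is invariant to multiplicative rescaling of the channel (both the mean and
the SD scale), not to additive offsets.

## 3. Response classification

For each ROI × stimulus, with a pre-stimulus baseline window (the frames
between the previous window's end plus a recovery gap and the current
onset, at most `pre_frames` = 10):

1. **Peak criterion** — max over the stimulus window of the
   baseline-subtracted ΔF/F₀ > 5 × SD(pre-window). The peak is measured
   above the pre-window mean: the criterion is read as exceedance over the
   local baseline (the raw-F/F₀ reading is available via
   `baseline_subtract=False`; the margin is identical).
2. **Derivative criterion** — max over the window of the first difference
   divided by the frame period > 1 × SD of pre-window first differences.
   No smoothing is applied (minimal assumption; the first-difference SD of
   the pre-window already reflects the same noise bandwidth).

SDs are sample SDs (ddof = 1). A zero pre-window SD is replaced by 1e-12
and the call flagged degenerate. Both margins are logged. The dual
criterion is monotone: raising either multiplier never converts a
non-responder into a responder.

**High-K⁺ exclusion (DRG mode).** ROIs failing the criterion on the K⁺
window are flagged excluded and removed from every downstream summary:
responder lists, fractions (numerator and denominator), co-expression
tallies and K⁺-normalised amplitudes (set NaN). Skin mode skips exclusion
and K-normalisation — nerve endings do not reliably respond to
depolarisation — and reports *responsive area* instead: Σ area of
responding ROIs / imaged area, per stimulus and per exact co-expression
class (exact classes partition the responding area).

**Co-expression classes.** The set of agonists (M3/A1/V1) an ROI responded
to — 8 possible classes including ∅ — with per-group relative frequencies
summing to 1.

## 4. RNAscope quantification

* **Rolling-ball background** (radius 1 µm): implemented as grey-level
  morphological opening with a disc footprint — structures narrower than
  the disc (the dots) are excluded from the background estimate, smooth
  shading is removed, output clamped at 0. In the infinite-radius limit
  the output tends to image − min(image). Radii below 1 px are rejected.
* **Spot detection** (diameter 0.8 µm): scale-matched
  Laplacian-of-Gaussian (σ = diameter/(2√2)) with local maxima above a
  prominence floor. The floor defaults to 8 × the noise SD estimated from
  the LoG response's *negative lobe* (uncontaminated by spots; the
  zero-clipped background noise is heavy-tailed, so a Gaussian-calibrated
  5σ admits false maxima), with a 5%-of-max floor for noise-free images.
* **Objects** are the connected components of the image above half the
  median peak brightness that contain ≥ 1 maximum. Integrated intensity is
  summed over the component dilated by one dot radius — the same measure
  for singles and clusters, so the cluster/single intensity ratio is
  unbiased (a fixed-diameter disc would systematically under-integrate
  clusters and break signal conservation).
* **Cluster flagging**: an object is a cluster when its equivalent
  diameter exceeds 1.5 × the median object diameter (configurable factor;
  the corrected totals move by < 10% between factors 1.3–1.7 on the
  reference synthetic slide, tested), or when it contains more than one
  detected maximum (overlapping dots by construction).
* **Cluster correction**: equivalent dots = cluster intensity / mean
  single-dot intensity of the same slide (≥ 5 singles required; never
  pooled across slides), rounded to the nearest integer, minimum 1. If a
  slide lacks 5 singles, cells are reported uncorrected and flagged.
* **Per-cell counting**: spots are assigned by intensity-weighted centroid
  membership (0-based pixel-centre convention); spots outside all masks go
  to a reported background bin. `dots_total` = singles + cluster
  equivalents; **positive** ⇔ dots_total ≥ 5. The count is invariant under
  multiplicative rescaling of the probe channel (the ratio cancels).
* **Summaries**: per-animal positive fractions with mean ± SEM over
  animals.

## 5. Synthetic data: the stated world

The generator is the package's ground-truth source; its defaults are fixed
once:

| parameter | default | rationale |
|---|---|---|
| frame period | 4 s (0.25 Hz) | volumetric acquisition rate of the emulated recordings |
| background offset / modulation | 300 / ±20 grey | bright tissue autofluorescence; required for the CV criterion to be variance-dominated (§1) |
| cell resting excess | 100 grey | somata visibly brighter than neuropil |
| noise | Gaussian, SD 5 grey (Poisson optional) | additive homoscedastic noise keeps SD-based criteria analytically checkable |
| transient | instant rise, exponential decay, τ = 8 frames | indicator-limited decay ~30 s at 0.25 Hz; kinetics are not otherwise parameterised |
| response amplitude | 10 × noise SD | clearly supra-threshold against the 5×SD criterion, stated in noise-SD units so criteria are checkable in closed form |
| WGA contrast | +10 × background SD for labelled cells | makes the 5×SD classifier unambiguous; a borderline mode exists for stress tests |
| RNAscope | 100 cells, Poisson(8) dots/cell, 20% clustered (chains of 2–4 at 0.9 dot-diameter spacing), SNR 10, 0.325 µm/px | stated quantification conditions; cluster integrated intensity is exactly the member sum |
| cohort | 6 virtual animals/side × 30 cells, M3 responder probability 0.4 ipsi / 0.2 contra, 90% K⁺-responsive | ≥ 100 analysed neurons per side is the realistic regime for such experiments; at much smaller cohorts the ratio-of-proportions estimator carries a noticeable Jensen bias (see Limitations) |

Not emulated (deliberately): optical PSF, z-dependent attenuation,
photobleaching, non-rigid tissue deformation, autofluorescent debris.
A green test on these data therefore establishes algorithmic correctness
and parameter recovery under the stated model — not robustness to optics
or tissue motion beyond rigid translation.

## 6. Statistics

* **Bootstrap ratio-of-means CI**: for B = 10,000 resamples, draw with
  replacement *within each group independently* (the groups are distinct
  cell populations, not pairs), record mean(target\*)/mean(reference\*) ×
  100, and report the percentile interval (default 95%). The point
  estimate is the observed ratio. The seed is a required, logged
  parameter. Percentile (not BCa) is the minimal reading of
  "bootstrapping"; resampling is at the cell level (animal-level
  resampling can be performed by passing per-animal summaries). Degenerate
  single-valued groups collapse the CI to the point and are flagged; a
  point estimate outside its own percentile CI (possible in principle) is
  flagged.
* **Shapiro–Wilk gate**: the non-parametric route is taken iff *any*
  compared group rejects normality at α = 0.05 (or is too small /
  constant, flagged).
* **Kruskal–Wallis + Dunn**: scipy omnibus; Dunn's pairwise z statistics
  on pooled mean ranks with tie correction, Holm-adjusted. (Implemented
  in-package; validated against full permutation enumeration at small n.)
* **One-way ANOVA + Holm–Šidák**: scipy omnibus and pairwise t tests;
  step-down adjustment p_adj(i) = 1 − (1 − p_(i))^(m−i+1) with enforced
  monotonicity (statsmodels). Single-value groups are excluded from the
  post-hoc stage and flagged.
* **Paired Wilcoxon signed-rank**: zeros dropped, exact null distribution
  for ≤ 25 non-zero pairs.

## 7. Known limitations

* The correlated-activity segmenter is a deliberate, documented substitute
  for constrained NMF; equivalence with factorisation-based ROIs on real
  micro-endoscopic data is not claimed.
* Cell-level bootstrap CIs ignore nesting of cells within animals; treat
  animal-level resampling as the conservative alternative.
* The ratio-of-proportions point estimate is biased upward by
  E[1/p̂] > 1/p at small reference-group counts (≈ +15% at ~16 reference
  responders, ≈ +5% at ~32); the cohort default sits in the regime where
  this is small relative to CI width.
* Dot counting is 2-D; overlapping dots in z project into clusters and are
  recovered only via the intensity-ratio correction.
* The spot/cluster separation (1.5 × median diameter, multi-maximum rule)
  is this package's operationalisation; no universal definition of a
  "single dot" exists.
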