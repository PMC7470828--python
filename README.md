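# trpscope

Quantitative image analysis for TRP-channel function and expression in
somatosensory neurons.

`trpscope` measures two complementary readouts used to study heat-activated
TRP channels (TRPM3, TRPA1, TRPV1) in nociceptors:

* **Function** — GCaMP calcium-imaging movies of dorsal-root-ganglion (DRG)
  somata or cutaneous nerve endings, acquired as time-lapse (optionally
  z-stacked) TIFFs while agonists of each channel and a depolarising
  high-K⁺ solution are applied in a fixed order (M3 → A1 → V1 → K⁺).
* **Expression** — RNAscope single-molecule FISH slides, where each
  fluorescent dot marks detected mRNA transcript signal in a manually
  segmented neuron.

Both readouts support group comparisons (e.g. inflamed *ipsilateral* vs
control *contralateral* paw, with afferents identified by a retrograde
WGA-AF647 label), ending in a bootstrap ratio-of-means confidence interval.

Because such imaging datasets are rarely deposited in computable form, the
package ships a first-class synthetic-data generator (`trpscope.synthgen`)
that emulates every input — somata and neurite geometry, stimulus-locked
transients of known amplitude, translational drift, smooth polynomial
background, RNAscope dots and intensity-additive clusters — with complete
ground truth, so every stage of the pipeline is testable end to end.

## The core procedures

**Responder criterion.** An ROI's ΔF/F₀ trace is a *responder* to a
stimulus window only if both hold (strict inequalities):

1. peak over the window, above the pre-stimulus baseline mean, exceeds
   5 × SD(ΔF/F₀) of the pre-stimulus window;
2. peak of dF/dt over the window exceeds SD(dF/dt) of the pre-stimulus
   window.

ROIs that fail the criterion on the terminal high-K⁺ window are considered
non-excitable and excluded from all downstream summaries (DRG mode);
amplitudes are reported normalised to the K⁺ response. Skin-nerve mode
instead reports *responsive area* (summed area of responding ROIs / imaged
area) without K⁺ exclusion.

**Preprocessing.** z-average → translational drift correction against the
mean of the first 10 pre-stimulus frames (phase cross-correlation) → a
non-responsive pixel mask from the Otsu threshold of the temporal
coefficient of variation → least-squares fit of a bivariate polynomial
surface (total degree ≤ 4) to non-responsive pixels, subtracted from every
frame → F/F₀ and ΔF/F₀ against the pre-stimulus reference.

**ROI extraction.** DRG somata come from an imported label mask (the
manual-identification workflow) or automatic blob detection; skin nerve
endings from a deterministic seed-and-grow segmenter that finds contiguous
areas with temporally correlated activity in the ΔF/F₀ movie. ROIs are
WGA⁺ only if their mean label-channel fluorescence strictly exceeds
background mean + 5 × background SD.

**RNAscope counting.** Rolling-ball background subtraction (1 µm) →
Laplacian-of-Gaussian spot detection (0.8 µm) → overlapping-dot clusters
converted to equivalent dot counts by dividing cluster intensity by the
per-slide mean single-dot intensity (rounded, minimum 1) → a cell is
positive at ≥ 5 dots.

**Statistics.** Percentile bootstrap (10,000 resamples, resampling within
each group) for ratio-of-means CIs reported as percentages; a Shapiro–Wilk
gate routes group tests to one-way ANOVA + Holm–Šidák or Kruskal–Wallis +
Dunn; paired ipsi/contra designs use the exact Wilcoxon signed-rank test.

## Worked example

```python
import trpscope as t

protocol = t.default_protocol()          # M3 -> A1 -> V1 -> K windows
truth = t.make_soma_truth((128, 128), n_cells=8, seed=1)
movie, wga, truth = t.gen_soma_movie(
    truth, protocol, (protocol.last_end + 10, 128, 128), seed=2
)
res = t.analyze_drg_movie(
    movie, protocol, wga_image=wga,
    cell_masks=t.synthgen.soma_label_image(truth, (128, 128)),
)
print(res["fractions"][["stimulus", "n_rois", "n_responders", "fraction"]]
      .to_string(index=False))
```

```
stimulus  n_rois  n_responders  fraction
      M3       8             5     0.625
      A1       8             3     0.375
      V1       8             1     0.125
       K       8             8     1.000
```

All 8 somata respond to the depolarising K⁺ challenge (so none are
excluded); 5 of 8 respond to the TRPM3 agonist, matching the generator's
programmed expression exactly. Per-ROI co-expression classes and WGA
status are in `res["table"].rois`:

```
roi_id coexpression_class wga_status
     1              M3+A1   positive
     2                 M3   positive
     3               none   negative
     ...
```

A cohort-level experiment — 6 virtual animals per side with a programmed
2× ipsilateral enrichment of TRPM3 responders — runs through the whole
pipeline and ends in the bootstrap comparison:

```python
cohort = t.simulate_cohort(seed=1)
print(cohort["comparison"])   # -> "164% (95% CI 119% to 234%)"
```

## Command line

A thin CLI mirrors the stages: `trpscope simulate | preprocess | segment |
respond | rnascope | compare` (see `trpscope --help`).

## Acceptance script

`scripts/acceptance.py` regenerates the synthetic datasets from a seed and
runs the package's main computations end to end — the DRG ipsi/contra
cohort with its bootstrap CI and exclusion audit, skin-nerve correlated-ROI
segmentation, and RNAscope per-cell counting — then writes its JSON output:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

The model, its assumptions, parameter defaults, numerical choices and
known limitations are described in [docs/methods.md](docs/methods.md).
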