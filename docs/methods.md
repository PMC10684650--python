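# Methods

## Problem setting

A Raman hyperspectral map (RHM) of a tissue section is a regular spatial
grid where every pixel carries a full Raman spectrum. In pancreatic-cancer
sections the fingerprint window (650–1800 cm⁻¹) contains the protein,
nucleic-acid and metabolite bands that distinguish tumor subtypes and
subcellular compartments. The package classifies each pixel's spectrum
into seven classes — stroma/empty (0), AVAC nucleus/cytoplasm (1/2),
cPDAC nucleus/cytoplasm (3/4), IPMC nucleus/cytoplasm (5/6) — and then
interprets each class's spectra by PCA. Classification is strictly
per-spectrum: no spatial features are used, so a trained model transfers
to single-spectrum modalities and is insensitive to tissue morphology.

## Synthetic data generator

Real annotated tumor maps are not distributable, so all tests and
benchmarks run on generated maps. The generator emulates:

* **Class chemistry.** Each class is a sum of Lorentzian bands (Gaussian
  available per band) at literature band positions: shared protein bands
  (Phe ring breathing 1004, CH₂/CH₃ bending ~1450, amide III 1230–1340,
  amide I 1514–1750 cm⁻¹); DNA backbone bands in nuclei (785, 1070, 1095,
  1128 cm⁻¹); methylation markers concentrated in AVAC nuclei (1391, 1489,
  1280, 879 cm⁻¹); amide I centred at 1628 cm⁻¹ (β-sheet) for cPDAC
  nuclei, 1650 cm⁻¹ (random coil) for IPMC nuclei and ~1670 cm⁻¹ for AVAC
  nuclei; cytoplasm accents (Tyr 1170 and amide II 1540 for IPMC,
  Phe/Trp C–C₆H₅ 1208 for cPDAC, methyl/methylene 1448/1299/1378 and
  reduced cytochrome C 1128 cm⁻¹ for AVAC and IPMC). Amplitudes are
  qualitative free parameters chosen once so that, on noiseless spectra,
  the three diagnostic ratios order the nuclei as reported: β-sheet
  cPDAC > IPMC > AVAC, random coil maximal in IPMC, methylation maximal
  in AVAC. These orderings are invariant under overall amplitude scaling.
* **Local AVAC hypermethylation.** Only part of AVAC nuclei are
  hypermethylated, so a configurable fraction (default 0.5) of
  AVAC-nucleus pixels draws from a boosted-methylation signature variant.
* **Backgrounds and noise.** Class-specific cubic polynomial baselines
  stand in for fluorescence; per-pixel multiplicative lognormal amplitude
  jitter (σ = 0.1 in log space, bands only) prevents classifiers from
  memorising a single vector; additive Gaussian noise with
  σ = `sigma_rel` × (class max band amplitude), default 2%, since the
  study protocol adds unspecified-level noise; optional Poisson-placed
  cosmic spikes (default rate 0).
* **Spatial layout.** Disk-shaped cells (cytoplasm) each containing one
  nucleus disk, placed without overlap on a stroma background by seeded
  rejection sampling with full restarts on dead-ends. Map sizes default to
  80 × 80 px at 1 µm/pixel, bracketing typical measured maps.

What the generator does *not* emulate: realistic tissue morphology,
paraffin residues, water bands, the lipid C–H region (washed out by
deparaffinization in FFPE protocols), detector artifacts beyond additive
Gaussian noise, and spatial correlation of noise. Passing benchmarks
therefore demonstrate the correctness and internal consistency of the
pipeline on separable spectra of the stated noise level — not clinical
performance on patient tissue.

## Preprocessing

Fixed chain order: baseline → smoothing → trim/resample.

* **Baseline.** "3rd-order polynomial correction" is under-specified, so
  the default is iterative polynomial fitting: fit, clip the working
  spectrum to the fit, refit, until max change < 10⁻⁶ of the spectrum
  scale or 100 iterations. This keeps peaks from dragging the baseline up;
  plain least squares is available (`baseline_method="ols"`). Fitting is
  vectorized across spectra with a precomputed pseudoinverse.
* **Savitzky–Golay.** Order 3, window 15 points (scipy). Edge handling
  uses polynomial edge interpolation (scipy's `interp`), chosen over
  reflect padding because it preserves the filter's defining property —
  polynomials up to the fit order pass through unchanged — at the edges
  too; `sg_mode="mirror"` is available.
* **Trim/resample.** Linear interpolation onto the canonical uniform
  320-point grid over the closed interval [650, 1800] cm⁻¹. The 320-point
  width follows the training-array convention; it is a convention, not a
  reconstruction of any instrument grid.
* **Augmentation.** Originals plus `n_copies` Gaussian replicates with
  σ = 2% of each spectrum's maximum. Default `n_copies=2`, fixed by the
  printed dataset sizes (42,098 → 126,294 = ×3).
* **int64 packing.** A documented optional encoding of (shift, intensity)
  into one integer (shift quantized to 0.01 cm⁻¹ in the high 32 bits,
  intensity to 0.001 in the low 32 bits, both non-negative). The default
  pipeline achieves shift alignment by canonical-grid resampling instead,
  so the packing is off by default.

## Classifiers

Both networks run on a small in-package numpy engine (Conv1D with 'same'
padding, max-pool, dense, ReLU, softmax cross-entropy head, Adam,
Glorot-uniform init). All randomness flows from one `random_state`; the
engine is validated against numeric differentiation in the test suite.

* **Stage 1 (spectral CNN).** 13 one-dimensional conv layers in four
  max-pooled blocks (4+3+3+3), filters 8/16/32/64, kernels 7/5/3/3,
  followed by a 256/64/7 dense head with softmax. The per-layer schedule
  is this package's reference choice — the layer counts (13 conv +
  3 dense) are the architectural contract, and the filter widths are
  sized for practical single-CPU training. Defaults: 40 epochs, batch
  105, Adam lr 10⁻³; the benchmark uses 10 epochs (below).
* **Stage 2 (ratio classifier).** Input is the 9-component record:
  DNA sum (1050–1150), methylated-DNA sum (1360–1420), methylation ratio,
  total-protein sum (1514–1750), β-sheet sum (1218–1228), β-sheet ratio,
  random-coil sum (1640–1664), random-coil ratio, stage-1 class. The
  windows for the three named sums are the only windows defined for those
  species; sums are plain grid-point sums over closed windows
  (trapezoidal integration available). Internally the eight numeric
  components are robust-standardized (median centring, IQR-derived scale,
  clipped to ±10) — plain z-scoring is dominated by near-singular ratios
  from weak stroma spectra whose DNA-band denominator is ~0 — and the
  class component is expanded to 7 indicators, since an integer-coded
  category would impose a false ordering. The record remains 9 components
  at the interface, and undefined ratios (denominator below
  ε = 10⁻¹²·p·max|I|) are reported as 0 with a flag. Architecture
  32/16/7, 17 epochs, batch 9.
* **Two-stage training.** Stage 2 trains on ground-truth labels with its
  `cnn_class` feature taken from stage-1 predictions, so training matches
  deployment. (Training on stage-1 outputs as labels is the alternative
  reading; ground truth was chosen because it lets stage 2 correct
  stage-1 errors rather than reproduce them.)
* **Splits.** Stratified 70/30 by default; train size is round(0.7·n).

## Prediction maps and PCA

Prediction maps preserve pixel order and carry provenance tags; rendering
is a pure function of (classes, palette, scale) to a PNG with an optional
legend, using a fixed colorblind-safe palette. Agreement with a
ground-truth mask is quantified by a 7×7 confusion matrix over annotated
pixels.

PCA is mean-centered without variance scaling (intensities share units;
scaling would distort loadings). Signs are fixed so each loading's
largest-magnitude element is positive. Loading annotation reports local
extrema above a prominence threshold (default 5% of the loading's max
|value|) with their wavenumbers. Per-class score centroids and count
histograms (shared bin edges) summarize class separation along each
component. The variance fractions printed for any particular tissue
dataset are properties of that data; the synthetic benchmarks assert
ordering, oracle-equivalence and band-recovery properties instead.

## Benchmark conditions and numerical choices

* Reference benchmark (`ramanpc.benchmark.run_benchmark`): 1000 spectra
  per class at 2% noise on the acquisition axis, preprocessing to the
  canonical grid, stratified 70/30 split, CNN trained 10 epochs, dense
  classifier 17 epochs; evaluation on the 30% held-out split and on three
  freshly-seeded 48 × 48 maps (one per tumor type, 6 cells each).
* Clean-data identity (`clean_map_identity`): three noiseless 28 × 28
  maps (3 cells each, radii 5/2), model trained 8 epochs on the pooled
  pixels, maps predicted back; expected pixel-for-pixel agreement.
* Ties in argmax go to the lowest class index. Division guards use
  ε = 10⁻¹²·(axis length)·max intensity. Compute dtype is float32 in the
  network engine (float64 in tests' gradient checks).
* Seeds: every stochastic step (generation, jitter, noise, splits, init,
  shuffling) derives from explicit integer seeds; benchmark sub-seeds are
  drawn from one base seed via a seeded generator.

## Known limitations

* The synthetic classes are, by construction, separable at the default
  noise level; benchmark accuracies near 100% reflect that construction.
  The pipeline's value on real tissue depends on annotation quality and
  class overlap that the generator does not model.
* The per-layer CNN schedule is a reference stand-in; only the 13+3 layer
  structure is contractual.
* Cosmic-ray removal is not implemented; the generator's default spike
  rate is zero, and spiked spectra would reach the classifier unfiltered.
* The long-text map format stores the axis per pixel and is intended for
  small fixtures and interchange, not for full-size maps (use the HDF5
  container).
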