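# ramanpc

Classification of Raman hyperspectral maps of pancreatic-cancer tissue into
seven subcellular classes — stroma/empty plus the nucleus and cytoplasm of
the three tumor groups AVAC (ampulla of Vater adenocarcinoma), cPDAC
(conventional pancreatic ductal adenocarcinoma) and IPMC (intraductal
papillary mucinous carcinoma) — followed by per-class PCA interpretation of
the spectra that drive the separation.

The package is aimed at vibrational-spectroscopy groups who map tissue
sections pixel by pixel (a full Raman spectrum per ~1 µm pixel) and want an
automatic, per-spectrum route from raw maps to tissue-class images and
molecular interpretation, without relying on spatial image recognition.

## Method

1. **Preprocessing.** Each spectrum is baseline-corrected with an
   iteratively fitted 3rd-order polynomial, smoothed with a Savitzky–Golay
   filter (order 3, 15 points), and trimmed/resampled onto a canonical
   320-point grid over the fingerprint window 650–1800 cm⁻¹. Training sets
   are augmented with additive Gaussian-noise replicates (default ×3 total).
2. **Stage 1 — spectral CNN.** A 1-D convolutional network (13 conv layers
   in four max-pooled blocks + 3 dense layers, Glorot-uniform init, Adam,
   categorical cross-entropy) maps each 320-point spectrum to one of the 7
   classes.
3. **Stage 2 — band-ratio classifier.** For every spectrum a 9-component
   record is built: band sums and the three diagnostic ratios

   - DNA methylation: Σ I(1360–1420) / Σ I(1050–1150)  (δ(CH₂,CH₃) over νs(PO₂⁻)),
   - protein β-sheet: Σ I(1218–1228) / Σ I(1514–1750)  (β amide III over total amide I),
   - protein random coil: Σ I(1640–1664) / Σ I(1514–1750),

   plus the stage-1 class. A shallow 3-layer dense network over these
   records emits the final class, sharpening the CNN-only decision.
4. **Prediction maps.** Final classes are folded back onto the pixel grid
   and rendered with a fixed colorblind-safe palette.
5. **PCA interpretation.** Spectra of selected classes (e.g. the three
   nuclei classes) are pooled; mean-centered PCA gives scores, centroid
   separations and loadings whose annotated extrema identify the
   responsible bands (e.g. β-sheet amide I at 1628 cm⁻¹ vs random-coil
   amide I at 1650 cm⁻¹).

Because real tumor maps are rarely shareable, the package ships a seeded
synthetic generator (`ramanpc.synth`) producing maps of disk-shaped cells
with nuclei on a stroma background, whose class signatures carry the
reported molecular contrasts (AVAC nuclear hypermethylation — locally, in
a configurable fraction of pixels; cPDAC β-sheet-rich nuclei; IPMC
random-coil-rich nuclei; subtype-specific cytoplasm bands), on cubic
fluorescence-like baselines with amplitude jitter and Gaussian noise.

## Worked example

```python
import numpy as np
import ramanpc as rp

axis = rp.acquisition_axis()                       # 600-1900 cm^-1, 2 cm^-1 steps
mask = rp.generate_layout(rp.TissueLayoutConfig(
    height=48, width=48, n_cells=6, tumor_type="cPDAC", seed=1))
hmap = rp.generate_map(mask, rp.default_signatures(),
                       rp.NoiseConfig(sigma_rel=0.02, seed=1), axis)

pre = rp.RamanPreprocessor(axis=axis)
train = pre.transform_map(hmap)                    # 48 x 48 x 320

X, y = rp.simulate_labeled_spectra(300, noise=rp.NoiseConfig(sigma_rel=0.02, seed=2))
X = pre.fit(X).transform(X)
Xtr, Xte, ytr, yte = rp.split_train_test(X, y, 0.7, seed=2)
model = rp.TwoStageClassifier(
    cnn=rp.SpectralCNNClassifier(epochs=10, random_state=2),
    dense=rp.RatioDenseClassifier(random_state=2),
).fit(Xtr, ytr)

print("CNN held-out accuracy:     ", np.mean(model.predict_stage1(Xte) == yte))
print("combined held-out accuracy:", np.mean(model.predict(Xte) == yte))
pm = rp.predict_map(train, model)
print("unseen-map accuracy:       ", rp.confusion_vs_mask(pm, mask)[1])
```

prints

```
CNN held-out accuracy:      1.0
combined held-out accuracy: 1.0
unseen-map accuracy:        1.0
```

i.e. on the 2%-noise synthetic benchmark the CNN separates all seven
classes on held-out spectra, the ratio stage preserves that decision, and
the model transfers to a map generated from a seed it never saw. With
`rp.render_map(pm, "map.png")` the prediction becomes a tissue image;
`rp.fit_pca` + `rp.annotate_loadings` on `rp.extract_class_spectra(...)`
recover the band positions separating the classes.

The same workflow is scriptable from a shell via the `ramanpc` CLI
(`simulate`, `preprocess`, `train`, `predict`, `render`, `features`, `pca`).

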