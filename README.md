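# har-locator

Protein subcellular location prediction from brightfield
immunohistochemistry (IHC) images.

IHC tissue images carry two absorbing stains — brown DAB on a target
protein and purple hematoxylin on nuclear DNA — and the spatial pattern of
the protein stain encodes where in the cell the protein lives. This
package classifies that pattern into seven locations (cytosol, endoplasmic
reticulum, Golgi, nucleoli, mitochondria, centrosome, vesicles) with a
hybrid ensemble aimed at researchers who analyze protein expression in
tissue atlases and need an inspectable, fully seeded reference pipeline.

The pipeline, end to end:

1. **Preprocessing** — saturation-based quality filtering; per-image
   linear spectral unmixing of inverted intensities `255 − RGB` into
   protein (DAB) and DNA (hematoxylin) abundance channels via exact
   2-column nonnegative least squares, with the stain basis estimated from
   the two dominant peaks of the saturation-weighted hue histogram;
   two-scale Canny border cropping; bilinear resize to the 512×512 network
   input.
2. **Shallow features (1096-D)** — 836 wavelet-domain Haralick statistics
   of the protein channel (db4, 5 levels; 13 GLCM statistics × 4 offsets ×
   16 bands + 4 raw-channel contrasts), 4 DNA spatial-distribution
   features, and a 256-bin 3×3 LBP histogram.
3. **HARnet** — a pre-activation residual CNN with three hybrid attention
   modules `X' = σ(P(X) + G(X)) ⊙ B(X)` (pointwise-conv local context P,
   pooled global context G, bottom-up/top-down refined branch B) and a
   2048-D global-average-pooling head; the three attention taps plus the
   GAP vector are the multi-view abstract features.
4. **Selection + confidence banks** — Wilks'-λ stepwise discriminant
   analysis picks a discriminative subset per feature space; seven
   one-vs-rest RBF SVMs with Platt calibration produce a 7-D confidence
   vector per bank, for five banks (H1/H2/H3/G each + shallow, and
   shallow-only).
5. **Decision ANN** — the five confidence vectors stack into a 35-D input
   of a 35→256→128→64→7 network that outputs the final label.

A seeded synthetic IHC generator (two-stain additive rendering with
class-specific textures and known ground-truth abundances) makes every
stage testable without any external download. No deep-learning framework
is required: the network runs on a compact in-package numpy engine.

See `docs/methods.md` for the model details, conventions and limitations.

## Worked example

Run the scaled-down, fully synthetic cross-validated study (70 images,
10 per class, 128×128, width-reduced HARnet, stratified 10-fold):

```bash
har-locator run --synthetic --tiny --seed 1 --out run_out
```

which trains the full pipeline inside every fold and prints:

```
accuracy 1.000 precision 1.000 recall 1.000 AUC 1.000 -> run_out/report.json
```

Pooled accuracy/precision/recall are computed from the single pooled
confusion matrix over all 10 test folds; AUC is the micro-averaged
one-vs-rest ROC area of the decision ANN's probabilities. On this clean
synthetic benchmark the seven classes are fully separable, so the
ensemble reaches the ceiling; `report.json` additionally records
per-fold metrics, per-class accuracies, each sub-predictor's pooled
accuracy (0.957–1.0 in this run) and the mean-of-confidences baseline,
so the contribution of the stacking layer over its inputs is visible.

Library use mirrors the CLI:

```python
from har_locator.synthetic import SynthConfig, generate_dataset
from har_locator.preprocess import preprocess_image
from har_locator.shallow import shallow_vector

sample = generate_dataset(SynthConfig(n_per_class=1, seed=0))[3]  # nucleoli
rgb, pair, model, bbox = preprocess_image(sample.image, input_size=512)
features = shallow_vector(pair)          # 1096-D, blocks haralick|dna|lbp
print(features.block("dna"))             # prints [0.19 0.06 3.1  0.02]
```

The four DNA features read: the protein mask occupies about a third of
the nuclear mask area (ratio 3.1) and its centroid sits essentially on
top of the DNA centroid (normalized distance 0.02) — a compact
intranuclear pattern. The overlap fractions stay low for this class
because nucleolar protein co-localizes with DNA, so the per-image stain
fit absorbs the mixed color into the protein axis and the unmixed DNA
mask has holes exactly at the nucleoli.

Other subcommands: `har-locator synth` (write a labeled PNG dataset),
`preprocess`, `featurize` (1096-D CSV), `select` (Wilks'-λ subset as
JSON).

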