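# Methods

## Problem

Brightfield immunohistochemistry (IHC) images of human tissue carry two
absorbing stains: brown DAB deposited on a target protein, and purple
hematoxylin marking DNA in nuclei. The task is to classify the protein's
subcellular location into seven classes (cytosol, ER, Golgi, nucleoli,
mitochondria, centrosome, vesicles) from the staining pattern alone. The
package implements a hybrid pipeline: per-image stain unmixing, a
statistical ("shallow") texture feature stack, a hybrid-attention residual
CNN (HARnet) that exposes multi-view abstract features, Wilks'-λ stepwise
feature selection, five one-vs-rest SVM confidence banks, and an ANN
stacking layer that fuses the five 7-D confidence vectors into the final
decision.

## Stain model and unmixing

Stains absorb light, so unmixing operates on inverted intensities
`s = 255 − RGB` ("stain amount"), making the two-stain image a nonnegative
linear mixture `s ≈ a_protein·b_DAB + a_DNA·b_hema` with 3-vector stain
colors `b`. The stain basis is estimated per image from the
saturation-weighted circular hue histogram (256 bins; pixels with
saturation < 0.1 or value > 0.95 are background and excluded): the
histogram is circularly smoothed (Gaussian, σ = 2 bins) and the two most
massive local maxima at least 16 bins apart become the stain peaks. Peaks
are assigned to protein/DNA by circular hue proximity to brown (0.08) and
purple (0.70) — not by peak order, so the assignment is permutation-safe.
Each basis column is the unit-normalized mean inverted RGB over pixels
within ±8 bins of its peak. When peak finding fails (grayscale, blank or
single-stain input) the caller may fall back to the Ruifrok–Johnston H-DAB
optical-density vectors, hematoxylin (0.65, 0.70, 0.29) and DAB
(0.27, 0.57, 0.78).

Per-pixel abundances solve a 2-column nonnegative least-squares problem.
With two columns the optimum has support {1,2}, {1} or {2}; all three are
solved in closed form and vectorized, and the feasible candidate with the
smallest objective is kept — this is exact, not approximate, and is
verified against a generic NNLS solver in the tests.

Border cropping runs Canny on the normalized protein channel at two
Gaussian scales (σ = 1 and 3; hysteresis thresholds from Otsu on the
gradient magnitude, low = high/2), takes the union edge mask's tight
bounding box plus an 8 px margin, and maps it back onto the RGB image and
both channels. Boxes are half-open, row-major, 0-based. With no edges the
input passes through with a flag. Network inputs are bilinear-resized to
512×512 (clipped uint8); the channels fed to the shallow features are
re-unmixed from the resized RGB so that all features share one geometry.

The quality filter keeps an image when the fraction of pixels with HSV
saturation above 0.1 reaches 0.02; both thresholds are configurable, and
the defaults mark only essentially unstained images for deletion.

## Shallow feature stack (1096-D)

Fixed block layout `haralick[836] | dna[4] | lbp[256]`:

* **Wavelet Haralick (836).** The protein channel is decomposed with a
  2-D discrete wavelet transform (Daubechies `db4`, 5 levels), giving 16
  coefficient images (LL₅ plus 15 detail bands). Each band is min–max
  quantized to 32 gray levels and a symmetric, unit-sum co-occurrence
  matrix is built at the four unit offsets (0,1), (1,0), (1,1), (1,−1);
  the 13 classical Haralick statistics are computed per matrix
  (16·4·13 = 832), and the GLCM contrast of the raw channel at the same
  four offsets fills the remaining 4 slots. Entropy-type statistics use
  the natural logarithm with 0·log 0 := 0; on degenerate matrices with
  zero marginal variance, correlation-type statistics are defined as 0;
  sum variance is taken about the sum distribution's own mean. A band
  whose dynamic range is at floating-point noise level (≤ 1e−9 relative)
  is treated as constant before quantization. At image sizes below 512 the
  5-level decomposition exceeds the nominal maximum wavelet level and
  proceeds with boundary effects; the layout is kept fixed at all sizes
  ≥ 64 so the 836-D contract never changes.
* **DNA spatial distribution (4).** Otsu masks of both channels give
  (1) the fraction of protein-positive pixels inside the DNA mask, (2) the
  fraction of DNA-positive pixels inside the protein mask, (3) the DNA/
  protein mask area ratio, and (4) the distance between intensity-weighted
  centroids normalized by the image diagonal. Empty masks fall back to
  (0, 0, 0, 1).
* **LBP (256).** Classic 3×3 local binary pattern per interior pixel: bit
  k is set when the k-th neighbor ≥ center, neighbors ordered clockwise
  from the top-left; the 256-bin code histogram is normalized to unit
  mass.

## HARnet

A pre-activation residual backbone with three hybrid attention modules:
7×7/2 stem convolution + 3×3/2 max pool, three residual stages (widths
256/512/1024, 3/4/6 units by default; the first unit of stages 2–3 has
stride 2), an attention module after each stage, a final stride-2
projection stage widening to 2048, then batch-norm/ReLU, global average
pooling (GAP) and a 7-way softmax. A 512 input is downsampled five times
to a 16×16 map before GAP.

The hybrid attention module gates a refined bottom branch with two context
terms computed from its input X (C×H×W):

    P(X) = p21(ReLU(p11(X)))          pointwise convs, C → C/r → C, r = 4
    G(X) = p22(ReLU(p12(gap(X))))     the same bottleneck on the pooled
                                      vector, broadcast over space
    X' = σ(P(X) + G(X)) ⊙ B(X)

The bottom branch B is variant-specific: H3 is the identity; H2 is one
bottom-up/top-down stage R2(I1(M1(R1(X)))) with a 3×3/2 max pool M1 and
bilinear interpolation I1 (align_corners = false) back to the input size;
H1 nests two such down/up stages with residual units between them. Because
the gate is a sigmoid, every output element is bounded by the matching
bottom-branch element, and with all attention weights zero the module
reduces exactly to 0.5·B(X).

Multi-view features are the per-channel global averages of the three
attention outputs (H1/H2/H3 taps, widths 256/512/1024 by default) plus the
2048-D GAP vector. Pooling the attention maps — rather than flattening
them — keeps the stepwise selection input tractable.

Training uses Adam with cross-entropy, initial learning rate 1e−3
multiplied by 0.1 at epoch 60, 300 epochs and batch 16 by default, He
initialization and batch normalization after every convolution; all
randomness is seeded, and inference is bit-deterministic.

The network and its training loop run on a small in-package numpy engine
(im2col convolutions with explicit backward passes, float32 by default,
dtype-configurable for float64 gradient checks). A `tiny` preset
(128 px input, widths divided by 8, one residual unit per stage) is the
default for cross-validated runs on a single CPU; the methods below state
the exact sizes used.

## Feature selection, confidence banks, stacking

For each of the five feature spaces (H1/H2/H3/G tap concatenated with the
1096-D shallow block, and shallow-only), stepwise discriminant analysis
selects a subset by Wilks' λ = det(W)/det(T) (W pooled within-class
scatter, T total scatter). Forward steps add the candidate minimizing the
partial λ when its partial F exceeds F-enter = 3.84; backward checks
remove any member whose partial F falls below F-remove = 2.71 (the
conventional stepwise defaults). Ties break toward the lowest column
index; the subset size never exceeds n − classes − 1; singular scatter
matrices are ridge-regularized with ε = 1e−8·tr(T)/p.

Each bank standardizes its selected features and fits seven one-vs-rest
RBF SVMs (C = 1, γ = 1/(p·var)) wrapped in Platt sigmoid calibration
(3-fold internal CV), yielding a 7-D per-class probability vector that
need not sum to 1. The five 7-D vectors, in the fixed order H1_S, H2_S,
H3_S, G_S, S, concatenate into the 35-D input of the decision ANN — a
35→256→128→64→7 fully connected network (ReLU hidden, softmax output,
cross-entropy, Adam, lr 1e−3, up to 200–300 epochs, seeded). Ties at the
final argmax break toward the lowest class index. A mean-rule baseline
(average the five blocks, argmax) is kept for comparison.

**Leakage control.** Within each outer cross-validation fold, HARnet, the
SDA subsets and the SVM banks are fit on the training split only. The
stacker is trained on confidences produced *out-of-fold* by an internal
stratified 5-fold CV over the training split: training it on in-sample
confidences would let it exploit overfit sub-classifier outputs. The
internal folds reuse the outer split's HARnet features and SDA subsets —
retraining the CNN five more times per outer fold would be
disproportionate — so the out-of-fold property applies to the confidence
banks, which are the stacker's direct inputs. No fitted object ever sees
test-fold data; the per-image unmix basis is image-local by construction.

## Evaluation

Stratified 10-fold cross-validation; metrics are pooled over folds (one
confusion matrix) with per-fold values also reported. Accuracy is
trace/total of the confusion matrix; precision and recall are unweighted
macro means over the classes present in the truth, with a never-predicted
class contributing precision 0. ROC is micro-averaged over all
(sample, class) pairs of the one-vs-rest decomposition, with AUC by the
trapezoid rule; single-class inputs are rejected as degenerate.

## Synthetic data generator

The generator renders two-stain images under a linear-clip convention,
`image = clip(255 − protein·b_DAB − dna·b_hema + noise)`, chosen over the
exponential Beer–Lambert form because it keeps unmixing a nonnegative
linear problem — exactly the model the unmixer assumes — at the cost of
realism in strongly co-stained pixels. Stain vectors default to the
Ruifrok–Johnston H-DAB colors; Gaussian pixel noise defaults to σ = 3
intensity units; peak abundances (160 protein, 170 DNA, ±10% per image)
keep fully co-stained pixels inside [0, 255] so no clipping occurs.

The DNA channel always contains elliptical nuclei (about 2·(size/64)²
of them, semi-axes 3.5–6.5% of the image side, random orientation). The
protein channel is class-specific: diffuse smoothed noise excluded from
nuclei (cytosol); thin filament webs from the zero crossings of smoothed
noise, concentrated near nuclei (ER); perinuclear arc bands (Golgi);
1–3 small intranuclear blobs per nucleus (nucleoli); dense elongated
granules (mitochondria); 1–2 puncta just outside each nucleus
(centrosome); sparse scattered dots (vesicles). Pattern constants are
fixed in code and fully seeded: the same seed reproduces byte-identical
images.

What the generator emulates: two-stain additive color, class-specific
spatial texture and protein–DNA spatial relations, pixel noise. What it
does not: tissue morphology, staining-intensity grades, out-of-focus blur,
stain variation across labs, multi-cell context, or the intra-class
heterogeneity of real atlas images. Passing tests therefore demonstrate
that the pipeline's machinery recovers known structure under its own
modeling assumptions — not benchmark-level performance on real IHC data,
which requires the external image collection and GPU-scale training and
is out of scope here.

## Problem sizes used in the checked runs

The cross-validated recovery run uses 70 synthetic images (10 per class)
at 128×128 with the tiny HARnet preset trained 6 epochs per fold (batch
8), SDA capped at 40 features per bank, and internal 5-fold stacking CV;
it completes in minutes on one CPU. The dimension contracts are checked on
the full-width network (512×512 input, 2048-D GAP) with a single forward
pass. Training-convergence tests run the tiny preset up to 30 epochs with
early stopping once training accuracy reaches 95%.

## Known limitations

* The exact composition of the published 836-D wavelet Haralick block and
  the 4 DNA features is not specified anywhere; the layouts here are
  documented, configurable interpretations that reproduce the counts.
* The backbone's stage depths/widths and how the 2048-D GAP is reached are
  likewise declared interpretations (ResNet-style defaults).
* SVM hyperparameters and SDA F thresholds use field-conventional
  defaults; published post-selection dimension ratios depend on them and
  are not targets.
* The numpy engine is single-threaded apart from BLAS matmuls; it is
  sized for the scaled-down study conditions, not for training at
  512×512.
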