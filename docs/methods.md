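# Methods

This note records the models, conventions and design choices behind
`grapetex`, the assumptions they rest on, and what the synthetic-data tests
do and do not establish.

## Pipeline overview

An input RGB image passes through: (1) optional threshold segmentation of
the leaf from its background; (2) six-fold augmentation (training only);
(3) bilinear resize to the 50 × 50 network input and per-channel min–max
normalization; (4) GLCM feature-sequence extraction from the grayscale
image (LSTM families only); (5) a classifier from one of four families;
(6) confusion-matrix evaluation with per-class and support-weighted
precision, recall, accuracy, IoU and F-measure.

## Image contract and preprocessing

Images are `(H, W, 3)` float arrays in one of two tagged ranges,
`raw_0_255` or `normalized_0_1`; channel order is fixed R,G,B at the API
boundary. Normalization is per-channel min–max, `x' = (x − min)/(max −
min)`, with a constant channel mapping to all zeros; re-normalizing an
already-normalized image is refused rather than silently accepted.
Resizing is bilinear (the common toolkit default, smooth for the 256 → 50
downscale this pipeline was designed around); resizing to the input's own
shape is short-circuited to an exact identity. Segmentation operates on raw
intensities and normalization is applied last; both orders are available
through the API.

## Segmentation

Leaf/background separation is plain grayscale thresholding: luminance
`0.299 R + 0.587 G + 0.114 B`, then a binary mask with 1 = leaf. Otsu's
rule (maximize between-class variance) is the default because it is
deterministic and parameter-free on the bimodal leaf/background histograms
this pipeline targets; a manual intensity threshold is accepted, and on a
constant image Otsu raises a degenerate-histogram error directing the
caller to a manual value. Foreground polarity (darker vs brighter side of
the threshold) is an explicit flag, defaulting to darker-leaf-on-bright-
background; silently inferring it from field imagery with varied
backgrounds would be fragile. Morphological cleanup (3×3 opening+closing)
is available but off by default.

## GLCM texture statistics

The co-occurrence matrix counts ordered pairs (reference, neighbor) of
quantized gray levels at displacement (distance d, angle θ ∈ {0°, 45°,
90°, 135°}); angles follow the classic orientation on a (row, col) grid —
0° = (0, +d), 45° = (−d, +d), 90° = (−d, 0), 135° = (−d, −d). Symmetric
mode adds the transposed counts before normalizing to probabilities.
Defaults: 32 gray levels (uniform binning of [0, 255]; enough resolution
without making 50 × 50 matrices sparse), distance 1, all four angles,
symmetric. With a segmentation mask, pairs touching any background pixel
are excluded entirely — counting them would concentrate mass in the
(0, ·) bins and swamp the leaf's own statistics.

Six statistics are computed from the normalized matrix: contrast,
dissimilarity, homogeneity, angular second moment (ASM), energy = √ASM,
and correlation with the marginal means/SDs. Two conventions matter:

* **energy** is the square root of ASM (the Hall-Beyer definition); the
  two are computed separately and the identity energy² = ASM is enforced
  to 1e-12 in tests;
* **correlation of a constant region** (σᵢσⱼ = 0) is defined as 1 — a
  constant region is perfectly self-correlated, and the convention keeps
  NaNs out of the LSTM's input sequences.

The LSTM consumes an ordered sequence of six-feature vectors, one per
offset, default distances {1, 2} × four angles (sequence length 8). This
offset-indexed sequence is one defensible way to serialize GLCM information
for a recurrent reader; it is isolated behind `glcm_sequence` so per-region
or other orderings can be swapped in. Per-pixel texture maps (one image per
statistic, reflected-edge padding, global quantization) are provided for
inspection and are computed by direct window enumeration — they are
O(H·W·window²) and intended for small images or offline analysis.

## Augmentation policy

Exactly six outputs per source image: the original plus one sample each of
zoom (scale uniform in 1 ± 0.3), rotation (uniform in ±90°), horizontal
flip, width shift (uniform in ±10% of width) and height shift (uniform in
±20% of height). Emitting exactly one sample per transform — rather than
online per-epoch augmentation — is the only reading consistent with a
six-fold dataset expansion (295 → 1770). Vacated regions are filled by
nearest-edge replication so no artificial black borders leak into texture
statistics; interpolation is bilinear, which keeps values inside the tagged
range. Draws are uniform over the symmetric ranges. The default pipeline
augments before splitting, which reproduces the protocol arithmetic but
lets variants of one source image land in both splits; a split-first
(leakage-safe) order is available via `--split-first`. Validation numbers
on augmented-then-split data should therefore be read as protocol
reproduction, not as leakage-free generalization estimates.

## Dataset handling

Labels are the five classes in fixed alphabetical order, coded 0–4. The
80/20 split takes `floor(0.8 n)` training items by seeded shuffle — floor
is the only rule that reproduces both protocol pairs 1770 → 1416/354 and
295 → 236/59 — and the counts depend only on n and the fraction, never on
the seed. The split is uniform rather than stratified by default (a
stratified option exists). Datasets live on disk as a directory-per-class
image tree plus a manifest CSV, so real survey imagery can be dropped in
unchanged.

## Synthetic leaf generator

The generator emulates a five-class leaf-image survey at a scale where the
whole pipeline runs in seconds: an elliptical leaf (semi-axes ≈ 0.40/0.32
of the image side, jittered ±5%) on a near-white background (245 ± 2), one
recipe per class, default 64 × 64 px images (the pipeline resizes to
50 × 50 regardless, mirroring the downscale it applies to full-size
photographs):

| class          | recipe                                                            | GLCM signature |
|----------------|-------------------------------------------------------------------|----------------|
| healthy        | mid-green (70,145,75) + smooth shading (σ=3 Gaussian field, amp 25)| low contrast   |
| chlorosis      | yellow-green (205,195,90) + very smooth shading (σ=5, amp 10)      | lowest contrast, high level |
| esca           | olive (120,110,60) + vertical square-wave stripes (period 4, amp 55)| high 0° contrast, low 90° |
| black_rot      | green (100,140,90) + dark speckle (Bernoulli p=0.25 → (40,30,20))  | highest distance-1 contrast |
| powdery_mildew | pale (185,200,185) + per-pixel noise (σ=12)                        | moderate contrast, high level |

Every image carries its exact foreground mask, and the whole dataset is a
deterministic function of the seed. The recipes were chosen once so that
the classes are separable in the distance-1 six-feature GLCM vector (a
held-out nearest-centroid rule reaches ≥ 90% at 20 images/class — verified
in the test suite) while remaining non-trivial for the image branch.

What the generator does **not** emulate: real leaf venation and shape,
lighting and viewpoint variation, soil/hand/sky backgrounds, multiple
leaves per frame, intra-class symptom progression, and the class imbalance
of field surveys (a per-class count vector is accepted for the latter).
Passing the end-to-end tests therefore demonstrates that the pipeline's
mechanics — preprocessing, feature extraction, joint training, evaluation —
are correct and that the models can exploit both color and texture
signal; it does not certify field accuracy on real imagery.

## Network families

All networks are built from a numpy layer core written for this package
(Dense, Conv2D 3×3 'same', LeakyReLU, MaxPool 2×2 'valid', BatchNorm,
Dropout, Flatten, LSTM, global average pooling), with full backprop checked
against central-difference gradients in the test suite.

* **dnn** — flattened 50×50×3 image (or backbone features) → dense stack
  512-256-256-64-64-32 (ReLU) → softmax(5).
* **cnn**, no backbone — three blocks of Conv2D → LeakyReLU(0.3) →
  MaxPool(2,2) → BatchNorm → Dropout(0.25), filter widths 1024/512/64,
  then Flatten → softmax(5). Feature-map sizes follow standard convolution
  arithmetic (50 → 25 → 12 → 6).
* **cnn**, with backbone — frozen backbone features → dense(512) →
  dense(256) → softmax(5).
* **dnn_lstm / cnn_lstm** — the image branch's penultimate feature vector
  concatenated with the final hidden state of an LSTM (default 64 units)
  over the GLCM sequence, then a dense softmax head; both branches train
  jointly. Penultimate-feature (not logit) fusion is used: the combined
  representation, not two vote vectors, is what the head learns from.

LeakyReLU slope 0.3 and dropout 0.25 are the common toolkit defaults and
are recorded in the architecture config; every model is reconstructible
bit-for-bit from its config + seed (Glorot-uniform init, forget-gate bias
1). Backbones are frozen feature extractors. The `tiny` backbone — a
16/32/64 conv-pool CNN with fixed seeded random weights and global average
pooling — is first-class so that the entire pipeline, test suite and
acceptance script run with no downloaded weights; random convolutional
features preserve enough color/texture information for the dense head to
learn from. The registry also declares vgg16/vgg19/resnet50/resnet101v2
with their standard feature widths; requesting them raises an explicit
weights-missing error naming `tiny`, since pretrained weights are not
distributable with this package.

## Training protocol

Mini-batches of 5, categorical cross-entropy on softmax outputs, Adadelta
in its classic parameterization (ρ = 0.95, ε = 1e-6, lr = 1.0 — the
original algorithm, designed to run without a tuned learning rate), up to
100 epochs, seeded shuffling. GLCM sequences are min–max scaled per feature
over the training split before entering the LSTM (contrast spans hundreds
while ASM lives in (0, 1]); the scaler state is persisted in checkpoints.
Per-epoch training loss/accuracy are the running batch averages
(training mode); validation metrics are computed at each epoch end in
inference mode. Metrics are reported at the final epoch unless early
stopping (patience on validation loss) is enabled. A non-finite loss raises
a divergence error naming the epoch.

Two optimizer behaviors worth knowing: Adadelta's squared-gradient
accumulators start at zero, so the first epochs on very small datasets
(few batches) can transiently overshoot before the step sizes settle —
the loss-decrease test therefore looks at a five-epoch horizon; and on an
overfit-scale fixture (five images, full-batch steps) the iterate keeps
oscillating around the minimum after first reaching 100% training
accuracy, so memorization is measured as the best epoch-end accuracy
within the epoch budget, not the final one.

## Evaluation

From the 5×5 confusion matrix (rows = true, columns = predicted), one-vs-
rest TP/FP/FN/TN give per-class precision, recall, per-class accuracy
(with TN), IoU = TP/(TP+FP+FN) and F-measure = 2·Pr·Re/(Pr+Re), all on the
0–100 scale. Aggregates are support-weighted means; the single reported
accuracy is the overall trace/total. Support-weighting (not macro) is
deliberate: in single-label multiclass evaluation the support-weighted
recall equals overall accuracy identically, which is the internal
consistency printed validation tables exhibit (Re = Acc while Pr differs).
A class with zero support scores 0 and drops out of the weighted means
(weight zero); zero denominators yield 0 rather than NaN.

## Problem sizes used in tests and the acceptance script

Unit tests use 4–20 images per class at 32–64 px. The end-to-end
learnability run uses 20 images/class, six-fold augmented to 600, split
480/120, `cnn_lstm` + tiny backbone, 30 epochs; the memorization check
uses five images (one per class) for 50 epochs. These sizes were chosen as
the smallest at which the class structure is comfortably learnable and the
statistics stable; results at these scales are properties of the synthetic
task, not estimates of accuracy on real vineyard imagery.

## Known limitations

* Training is CPU-bound numpy; the full 1024/512/64 convolutional family
  is usable at study scale but far slower than a GPU framework. The tiny
  backbone path is the practical default for experimentation.
* Pretrained backbone weights are declared but not shipped; transfer
  learning with real VGG/ResNet features requires the user to provide a
  framework that can produce them.
* The offset-sequence LSTM input is one of several defensible
  serializations of GLCM information; alternatives plug in behind
  `glcm_sequence`.
* EXIF orientation, color profiles, video input, vertical flips, shear and
  photometric jitter are out of scope by design.
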