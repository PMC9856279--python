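# Methods

## Model

The classifier is a five-input convolutional network over one image. The
512×512×3 input is presented twice: once whole ("macroscopic", average-
pooled 2×2 at the front so all branches see 256×256×3) and once as its
four 256×256×3 quadrants ("microscopic", fixed order top-left, top-right,
bottom-left, bottom-right). Each branch applies three rounds of 3×3
convolution (same padding), ReLU and 2×2 max pooling with 32, 64 and 128
filters, producing 32×32×128. Branch outputs are concatenated on channels
(32×32×640), merged by one 3×3 convolution with 128 filters and ReLU,
passed through dropout (rate 0.5) and a 2×2 average pool (16×16×128),
flattened (32 768), and finished by a 128-unit ReLU dense layer and a
4-way softmax over the fixed class order (IPSC, MSC, RGC, RPE). A
single-tensor baseline keeps only the macro branch with an otherwise
identical head. Every intermediate shape is asserted at build time (the
"shape ledger"); configurations that cannot realise the ladder are
rejected with a report.

Unstated details were fixed as follows and are exposed in `ModelConfig`:
same padding (required by the 256→128→64→32 ladder), ReLU activations,
Adam with learning rate 1e-3, categorical cross-entropy. The five branches
have identical topology but independent weights; `tie_branch_weights=True`
gives the weight-shared reading. Weight initialisation (He normal), batch
shuffling and dropout masks all derive from `ModelConfig.seed`, and the
implementation is plain numpy, so training and inference are
bit-reproducible on CPU. Training aborts with a diagnostic on non-finite
loss. Checkpoints are single-file npz archives of weights plus the exact
config; a calibrated (flatten-truncated) checkpoint omits the dense layers
and is strictly smaller.

All shapes scale with `canvas_side` and the filter widths. The defaults
are the published configuration; tests and examples run the same code at
64–128-px canvas with 8/16/32 filters so that CPU training takes seconds
to minutes. Reported test numbers (accuracy thresholds, rank correlations,
heat ratios) are measured at those reduced sizes; the thresholds
themselves are not relaxed.

## Hybrid head

Calibration truncates the trained network at the flatten layer, yielding
32 768-dim features. The head is MaxAbs scaling (per-feature training-set
maximum absolute value; zero-variance features keep factor 1) → PCA to 512
components (capped at the rank bound min(n_samples, n_features) with a
warning; axes ordered by decreasing explained variance) → SVM (RBF kernel,
C = 1, one-vs-one; kernel and C configurable, linear included). The LDA
projector variant is capped at n_classes − 1 = 3 dimensions. All
statistics are fitted on training features only; fitting them on test data
would leak. Evaluation reports the confusion matrix with rows = truth,
per-class recall and standard F1 (harmonic mean of precision and recall),
and overall accuracy = trace/total; percentages are stored at full
precision and printed half-up to one decimal.

## Differentiation-degree scoring

Among the leading eight PCA axes, the separating axis for a class pair
(reference iPSC, target RPE) is the one on which the sign-at-zero rule
sides the most samples correctly, with the absolute standardised mean
difference |μ_t − μ_r|/pooled-sd as tie-break. Sided fraction is the
primary criterion rather than the standardised difference alone because
two clusters can be far apart yet lie on the same side of the PCA origin,
and the zero threshold is the defining property of the axis; empirically
the difference-only rule can pick such an off-origin axis (d ≈ 6 but only
69 % correctly sided) while the sided rule picks an axis with 99 % sided
and rank correlation 0.97 against ground-truth degree. Orientation makes
the target centroid positive. Scoring uses the continuous oriented
coordinate; ranks sort descending with deterministic ties by sample id. A
sided fraction below 0.75 triggers a low-separation warning. Scores are
ordinal: no mapping to "% differentiated" is attempted, since only the
ordering can be validated without reference gradings.

## Class-activation heatmaps

Attention maps are gradient-weighted class-activation maps computed at the
merge convolution's input — the branch concatenation, the last point where
channels are attributable to branches and hence to image regions. Two
departures from the classic formulation, both architecture-driven: (i)
activations are weighted by their gradients element-wise (HiResCAM-style)
rather than by spatially pooled channel weights, because the network has a
flatten head, not a global-average-pool head, so per-position weights are
the faithful first-order attribution — with pooled weights the maps failed
to localise either pigment patches or scale bars; (ii) each branch's
rectified map is painted into the region that branch sees (macro → full
canvas, quadrant → its quadrant) before summing and normalising to [0, 1],
since upsampling the merged map directly smears quadrant evidence across
the whole image. The pooled-weight variant remains available
(`weighting="pooled"`); it is spatially constant on constant inputs, which
the element-wise variant is not (a flatten head genuinely attributes
differently across positions).

The scale-bar confound is demonstrated with a controlled design: two label
groups share the iPSC phenotype and differ only by a stamped corner bar,
making the bar the feature the network must learn; heat mass inside the
bar rectangle then exceeds its area fraction several-fold (≥ 2× is the
tested bound). Stamping bars on ordinary phenotype classes does not
reproduce the effect at this scale because the synthetic phenotypes are
far stronger cues than the bar.

## Synthetic data

The generator renders phenotype sketches on a light-gray background (mean
200/255, Gaussian texture noise, default sd 8/255, clipped at 3.5 sd):
IPSC as bright ellipses (≈235/255) with a darker rim giving a sharp
boundary; MSC as thin mid-gray streak bundles (≈148/255); RGC as dark
branching polyline trees (≈110/255) grown by recursive forking; RPE as
dark-brown ellipse clusters (RGB ≈ 74/52/38, luminance ≈ 57) added until
the covered fraction reaches the requested degree, overshooting by at most
one ellipse (< 3 % of the canvas). Non-RPE intensities sit strictly above
the pigment threshold (luminance 90/255) and pigment strictly below, so
threshold counting is an exact ground-truth probe; the true pigment mask
and degree travel in image metadata, never in anything the models see.
Scale bars are near-white rectangles with tick marks, confined to a
corner rectangle. Per-class structure counts (3 colonies, 25 streaks, 4
neurite trees) were chosen once to give visually plausible, linearly
separable classes (a five-feature logistic probe exceeds 90 % accuracy)
and left alone.

What the generator does not emulate: optics (PSF, defocus), illumination
gradients, stain variability, mixed cultures, magnification differences
beyond the quadrant "cut-image" expansion, or continuous morphological
intermediates. Passing tests therefore show that the pipeline recovers
class structure and a monotone pigment-degree signal it was designed to
expose — not that it reaches any particular accuracy on real microscopy.

## Preprocessing conventions

Row-major arrays, origin top-left, 0-based indices, half-open slices.
Bilinear interpolation for every resize. Scale-bar removal is a
fixed-margin centered crop (default 5 % per edge), not bar detection. Flip
augmentation (4×: original, horizontal, vertical, both) is applied to
training sources only; test images are split off first and never
augmented. Validation is a seeded uniform draw of ⌊val_frac × augmented⌋
samples from the augmented pool, so flip variants of one source can land
in both train and validation — a property of the described procedure,
noted rather than repaired. With 1291 training sources this arithmetic
yields 5164 augmented samples and 1032 validation samples. The
"divide-expand" option appends each image's four quadrants, upscaled to
full size, as independent samples (5×).

## Known limitations

* Training at the full 512-px canvas in numpy is minutes per epoch at
  realistic dataset sizes; the implementation targets CPU reproducibility
  and desk-scale experiments, not GPU throughput.
* PCA dimension is bounded by sample count; small fixtures use fewer than
  512 components (warned, never silent).
* The degree score is validated as an ordering on synthetic degrees;
  absolute calibration would need reference-graded real images.
* Heatmap geometry assumes the fixed quadrant order; swapping the slicing
  convention requires updating the painting regions in `heatmap.py`.
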