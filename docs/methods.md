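# Methods

This note documents the models, the numerical choices and the limits of
what the test suite shows. It is the package's own account of its design;
everything quantitative stated here is computed by the tests or by
`scripts/acceptance.py`.

## Problem and pipeline

A sample is a small grayscale CT patch centred on a candidate region; the
task is binary: nodule (round/oval opacity, positive class) versus
non-nodule. Four feature extractors run per sample, any subset of their
outputs is concatenated into one vector, and a conventional classifier is
trained on the fused vectors. Evaluation crosses nine canonical feature
sets (HOG, ExHOG, LBP, CNN, HOG+CNN, ExHOG+CNN, CNN+LBP, ExHOG+CNN+LBP,
HOG+CNN+LBP) with four classifiers (SVM, 1-NN, decision tree, random
forest).

## Gradient field

All orientation-based descriptors share one gradient definition: centred
(−1 0 1) differences horizontally and vertically with edge replication at
the borders (so a border gradient degenerates to a one-sided difference),
magnitude `M = sqrt(Ix² + Iy²)`, angle from the two-argument arctangent.
The angle is *defined* as 0 wherever `M = 0`; since votes are
magnitude-weighted this convention never influences a histogram.

## HOG (1296-dim)

Working size 28×28. Cells are 4×4 px (7×7 cell grid); blocks are 2×2 cells
(8×8 px) at a 4-px stride, giving 6×6 block positions; each cell holds a
9-bin histogram of *unsigned* orientation ([0°, 180°), opposite directions
share a bin). Votes are magnitude-weighted and linearly interpolated
between the two nearest bin centres (centres at (i+½)·20°, wrapping).
Each 36-value block is L2-normalised with a zero-guard: an all-zero block
(e.g. from a constant patch) stays exactly zero rather than dividing by an
epsilon. 36 blocks × 4 cells × 9 bins = 1296.

## ExHOG (648-dim)

Working size 28×28 with a 6×6 *cell* grid. 28 is not divisible by 6, so a
pixel at row y belongs to cell `floor(6·y/28)` (cells are 4 or 5 px wide);
exact feature-count fidelity was preferred over integer cell sizes. Per
cell an 18-bin *signed* histogram over [0°, 360°) is accumulated with the
same interpolated voting, then opposite bins are folded: difference bins
`|h_i − h_{i+9}|` first, then sum bins `h_i + h_{i+9}`. The sum bins are
exactly an unsigned HOG; the difference bins retain edge-polarity
information while cancelling for balanced bright/dark edges. Each
18-value cell vector is L2-normalised, clipped at 0.2 and renormalised
(the clipping threshold is the conventional value used with clipped block
normalisation; the construction names the method but no parameter).
36 cells × 18 bins = 648.

Using unsigned orientation for HOG and signed-then-folded orientation for
ExHOG reconciles the two angle ranges the two descriptors are defined
over, and is the only reading under which both advertised feature counts
(1296 and 648) come out exactly.

## LBP (256-dim)

For every interior pixel, the eight neighbours are enumerated clockwise
from the top-left with the least significant bit first; a bit is set iff
the neighbour is ≥ the centre (ties set the bit, so a constant patch maps
every pixel to code 255). The descriptor is the 256-bin code histogram
normalised to sum 1. The bit order is an arbitrary but fixed labelling of
the histogram axis; any other fixed order is a permutation of the same
features. LBP is exactly invariant under positive-slope affine intensity
maps; HOG/ExHOG are invariant to intensity shifts and (after
normalisation) to positive scaling.

## CNN (40-dim features, 2-class head)

Architecture: conv(20@5×5, stride 1) → maxpool(2×2, stride 2) →
conv(32@5×5) → maxpool(2×2, stride 2, floor) → conv(32@5×5) → ReLU →
maxpool(2×2, stride 1) → conv(40@4×4) → linear 40→2 → softmax. Spatial
trace on 50×50 input: 50→46→23→19→9→5→5→4→1, ending at 1×1×2. The pool
strides (2, 2, 1) are the unique assignment under which the listed layers
compose to a 1×1 output from a 50×50 input; the final 1×1 linear
projection is treated as part of the softmax layer, since 40 channels
cannot reach 2 classes by softmax alone. The learned feature vector is
the 40 pre-projection activations (the 2 softmax scores would add almost
nothing to fusion).

Training: mini-batch SGD (learning rate 0.01, batch 32, default cap 1770
iterations) on softmax cross-entropy, He-normal initialisation, all seeded
and bit-deterministic given the seed. Arithmetic is single precision by
default (roughly halves the runtime; SGD is insensitive to the difference)
with a float64 mode used by the finite-difference gradient check, which
verifies every parameter gradient of a tiny network against central
differences at 1e-4 relative tolerance. Convolution layers are verified
against an explicit quadruple-loop computation.

## Fusion, classifiers, evaluation protocol

Fusion is plain concatenation in the fixed order HOG, ExHOG, CNN, LBP
restricted to the chosen subset, so mixed descriptors keep stable column
positions. Classifiers: SVC(C=1, RBF, gamma='scale'); 1-NN with Euclidean
distance; decision tree with Gini impurity; random forest with 100 trees.
Every classifier sits behind a per-feature z-scoring step fitted on the
training split only (distance-based classifiers would otherwise be
dominated by the unnormalised CNN activations); hyperparameters
are conventional defaults and are not tuned.

The evaluation scheme is five *independent* stratified splits at train
fractions 10, 20, 30, 40, 50 % (not a rotating k-fold); each model
predicts the complement of its train split and the five held-out
prediction sets are pooled into a single confusion matrix per combination.
Pooled counting is the documented convention here: per-split matrices
would sum to varying test sizes, the pooled matrix sums to the total
number of held-out predictions.

## Metric panel

Confusion counts follow the row-one-true-nodules table layout (see
`nodulefuse.metrics`): within it, `fp` is the count of missed nodules and
`fn` the count of false alarms; standard-convention aliases are exposed.
Formulas (as fractions, reported ×100): accuracy = (tp+tn)/n;
sensitivity = recall = ppv-as-printed = tp/(tp+fp); specificity =
tn/(fp+tn); precision = tp/(tp+fn); F = 2PR/(P+R); npv = tn/(tn+fn);
κ = (p_a − p_e)/(1 − p_e) with chance agreement p_e from the row/column
marginals. Zero denominators define the metric as 0 and are flagged.
Published percentage panels in this literature print to varying precision
and sometimes truncate instead of rounding; `matches_printed` therefore
accepts a value if it is within 0.02 points **or** reproduces the printed
number after truncation/rounding to the printed precision. The bundled
reference tables (`nodulefuse.reference`) carry the 36 published
confusion matrices verbatim, including one internally inconsistent row
(`KNN_HOG_CNN`, nodule row sums to 457 instead of 467) and a list of
every published metric value that actually reproduces; published
specificity values and one precision value are not derivable from the
printed matrices under any candidate ratio and are deliberately excluded
from verification.

## Synthetic data generator

The generator emulates the *structure* of LIDC-style nodule data, not CT
physics. Each sample is a five-slice stack (p2, p1, n, n1, n2) of 50×50
patches in [0, 1]; defaults are 467 nodule and 131 non-nodule stacks with
additive Gaussian noise (σ = 0.05) and clipping to [0, 1].

* Nodules: an anisotropic Gaussian blob (radius U(4, 10) px, axis ratio
  U(0.7, 1), random rotation, centre jitter ±10 % of the patch) with
  amplitude U(0.5, 0.9) over a 0.2 background; the amplitude is scaled by
  (1, 0.7, 0.4) at slice offsets (0, 1, 2), mimicking a 3-D mass sampled
  by five axial slices.
* Non-nodules, two confusable modes at 50/50: an elongated vessel-like
  Gaussian ridge (half-width U(1, 3) px, random orientation and offset,
  slight per-slice drift, amplitude U(0.4, 0.8)) or pure background noise.
  The negative class of the original data is undocumented; this mixture is
  the package's own construction chosen so that negatives share the
  brightness range of positives and the task is not trivially solvable by
  mean intensity.

What passing tests on this data do show: the descriptors measure what they
claim (shape vs texture vs learned structure), the harness is leak-free
and deterministic, and fused features can beat their constituents. What
they do not show: performance on real CT, where negatives are far more
diverse and intensities are calibrated (Hounsfield units); the synthetic
accuracies (>85 % for all 36 combinations) are sanity floors, not claims
about LIDC.

## Sample convention

The classification grid runs at one sample per stack: hand-crafted
descriptors are computed on the centre slice resized (bilinear) to 28×28,
and the CNN contributes centre-slice features. The CNN itself is trained
on all five slices of every stack (each slice inherits the stack label) —
the outer slices act as natural augmentation and expose the through-slice
intensity decay that distinguishes nodules from ridges. Stack-level
samples keep confusion matrices directly comparable with the bundled
reference tables (467 + 131 = 598 rows).

## Problem sizes used by the checks

The oracle-equivalence tests compare the vectorised descriptors with
explicit per-pixel double-loop implementations on 25 random 12×12 patches
(the descriptor geometry scales down cleanly: 2×2 blocks for HOG, 2-px
cells for ExHOG) at 1e-10 absolute tolerance. The end-to-end check runs
the full default conditions — 598 stacks, CNN trained for the full 1770
iterations on 2990 slices, all 36 combinations — once per split seed
(0, 1, 2) for the hybrid-versus-single comparison. The README's worked
example uses 120 stacks and 300 iterations to stay instant.

## Known limitations

* No rotation-invariant/uniform LBP variants, no tri-linear HOG
  interpolation, no data augmentation or GPU path — deliberately outside
  scope.
* The CNN trains from one random initialisation per seed; no restarts.
* DICOM support covers single-frame slices with rescale slope/intercept
  followed by per-patch min-max normalisation; full-scan handling,
  windowing presets and lung segmentation are out of scope.
* Synthetic negatives are a two-mode caricature of real non-nodule
  anatomy (see above).
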