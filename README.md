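# nodulefuse

Hybrid hand-crafted + learned feature extraction for classifying pulmonary
nodule patches in chest CT.

Computer-aided diagnosis systems for lung cancer screening must decide, for
a small grayscale patch around a candidate region, whether it shows a
nodule (a roughly round or oval opacity, here the positive class) or a
non-nodule structure such as a vessel segment or plain parenchyma. This
package implements a classical hybrid pipeline for that decision and an
evaluation harness around it:

* **HOG** — histogram of oriented gradients: 9 unsigned orientation bins
  over [0°, 180°), 4×4-pixel cells, 2×2-cell blocks at stride 4 over a
  28×28 patch (6×6 block positions), per-block L2 normalisation →
  **1296 features**.
* **ExHOG** — extended HOG: an 18-bin *signed* orientation histogram
  (0–360°) per cell of a 6×6 grid; opposite bins *i* and *i*+9 are folded
  into |hᵢ − hᵢ₊₉| and hᵢ + hᵢ₊₉, removing bright-on-dark vs dark-on-bright
  edge-polarity ambiguity; per-cell clipped L2 normalisation →
  **648 features**.
* **LBP** — local binary patterns: each pixel's eight neighbours are
  thresholded against the centre (ties → 1) to an 8-bit code; the
  normalised 256-bin code histogram is the texture descriptor →
  **256 features**.
* **CNN** — a small convolutional network, conv(20@5×5) → pool/2 →
  conv(32@5×5) → pool/2 → conv(32@5×5) → ReLU → pool(2×2, stride 1) →
  conv(40@4×4) → linear → softmax, i.e. spatial trace
  50→46→23→19→9→5→5→4→1 on a 50×50 patch. After supervised training the
  40 activations entering the projection are used as learned features →
  **40 features**. The network (im2col convolutions, analytic backprop,
  mini-batch SGD) is implemented in numpy and gradient-checked.

Descriptor subsets are fused by concatenation (canonical order HOG, ExHOG,
CNN, LBP) and classified with an RBF-kernel SVM, 1-nearest-neighbour, a
Gini decision tree and a 100-tree random forest — nine canonical feature
sets × four classifiers = a 36-combination grid. Evaluation follows a
five-split scheme (stratified train fractions 10–50 %, held-out predictions
pooled into one confusion matrix per combination) and reports accuracy,
sensitivity/recall, specificity, Cohen's κ, precision, F-score and PPV/NPV,
all in percent.

Because the original CT archive (LIDC) cannot be redistributed, the package
ships a deterministic synthetic generator that emulates its structure:
five-slice stacks (p2, p1, n, n1, n2) of 50×50 patches, 467 nodule stacks
(bright Gaussian blobs that peak on the centre slice) and 131 non-nodule
stacks (vessel-like ridges or flat noise), plus a LIDC-style manifest
(patientid, noduleid, slicenumber, zposition, diameter, label).

## Worked example

Recompute the metric panel from a confusion matrix in the row-one-true-
nodules layout (452 of 467 nodules and 118 of 131 non-nodules correct):

```python
from nodulefuse.metrics import ConfusionCounts, panel

report = panel(ConfusionCounts(452, 15, 13, 118))
for k, v in report.as_dict().items():
    print(f"{k:12s} {v:6.2f}%")
```

```
accuracy      95.32%
sensitivity   96.79%
specificity   88.72%
kappa         86.39%
precision     97.20%
recall        96.79%
fscore        97.00%
ppv           96.79%
npv           90.08%
```

95.32 % of all 598 samples are correct; sensitivity (= recall = PPV here,
the fraction of true nodules recovered) is 452/467 = 96.79 %; the F-score
is the harmonic mean of precision and recall.

Run a reduced synthetic experiment end to end (120 stacks, 300 CNN
iterations — the full study conditions use 598 stacks and 1770 iterations):

```python
from nodulefuse.synthetic import SynthConfig, generate_dataset
from nodulefuse import pipeline
from nodulefuse.cnn import TrainConfig
from nodulefuse.fusion import SplitScheme, run_grid, combo_from_name

stacks, _ = generate_dataset(SynthConfig(n_nodule=80, n_nonnodule=40, seed=0))
cnn = pipeline.train_cnn_on_stacks(stacks, TrainConfig(max_iterations=300, seed=0))
desc = pipeline.extract_descriptors(stacks, ("ExHOG", "CNN"), cnn_model=cnn)
labels = pipeline.stack_labels(stacks)
combos = [combo_from_name(n) for n in ("SVM_ExHOG", "SVM_CNN", "SVM_ExHOG_CNN")]
result = run_grid(desc, labels, SplitScheme(seed=0), combos)
print(result.table[["combo", "TP", "FP", "FN", "TN", "accuracy", "fscore"]]
      .round(2).to_string(index=False))
```

```
        combo  TP  FP  FN  TN  accuracy  fscore
    SVM_ExHOG 280   0  73  67     82.62   88.47
      SVM_CNN 280   0  16 124     96.19   97.22
SVM_ExHOG_CNN 280   0  57  83     86.43   90.76
```

Each row pools the five held-out splits (420 predictions from 120 stacks):
all 280 pooled nodule cases are recovered (TP column, FP = missed nodules
is 0) and the classifiers differ in how many ridge/noise negatives they
mistake for nodules (FN column). At this reduced scale the CNN features
dominate; the acceptance suite exercises the full-scale conditions, where
hybrid combinations overtake their constituent single descriptors.

The same pipeline is available from the shell:

```bash
nodulefuse generate --n-nodule 80 --n-nonnodule 40 --seed 0 --outdir data/
nodulefuse train-cnn --datadir data/ --seed 0 --params-out cnn.npz
nodulefuse extract --datadir data/ --descriptors HOG,ExHOG,LBP,CNN \
    --cnn-params cnn.npz --out features.csv
nodulefuse grid --features features.csv --combos all --out grid.csv
nodulefuse report --grid-csv grid.csv
nodulefuse verify-reference     # recompute metrics from the bundled
                                # published confusion matrices
```

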