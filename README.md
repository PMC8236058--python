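# xenoclass

Single-cell classification of xenografted (human) versus host (mouse) cells in
histological images of patient-derived xenografts (PDX).

In intraductal xenograft models, human breast epithelial cells grow inside the
mouse mammary ductal tree, so every H&E-stained section contains a mixture of
human and mouse cells. Quantifying engraftment — or excluding host cells from a
downstream molecular readout — requires classifying cells one by one, a task
that is slow and subjective when done by eye. `xenoclass` automates it: given a
stained image and a nucleus label image from any instance segmenter, it
delineates one cell per nucleus, describes each cell with a 484-value feature
vector, and classifies cells with a small dense neural network. A synthetic
tissue generator makes the whole pipeline testable without any slide data.

## Method

**Cell delineation.** Precise membranes are hard to see in H&E, so cells are
estimated from nuclei under two constraints: cells must not overlap, and the
cell thickness (distance to the nucleus) must not exceed Δ = 2 µm (editable).
Each pixel joins the Voronoi cell of the nearest nucleus *mask* provided it
lies within Δ, so every cell contains exactly its nucleus plus a bounded
cytoplasm rim.

**Features (47 + 376 + 61 = 484 per cell).**

* *Cell-intrinsic* (47): moment-ellipse shape and size of nucleus and cell
  (major/minor axis, elongation, area, cytoplasm/nucleus area ratio); mean and
  standard deviation of each color channel over nucleus and cytoplasm; the 13
  classic Haralick statistics of a masked gray-level co-occurrence matrix
  (GLCM), per region, computed on a PCA gray projection of the image.
* *Neighbor-derived* (376): cells that are physically connected share
  properties, so the mean and variance of each intrinsic feature is taken over
  the K-connected neighborhood — the K cells with smallest Dijkstra
  shortest-path distance on the Delaunay graph of cell centroids — for
  K ∈ {5, 10, 20, 40}: 47 × 2 × 4.
* *Organization* (61): direct Delaunay-neighbor distance statistics; lateral
  (left/right) neighbors selected by the normal-to-major-axis criterion, with
  distance, alignment and orientation difference; chains of mutually-lateral
  cells (size, tortuosity) — arrangements typical of human cells threading
  along ducts; and Euclidean K-nearest / graph K-connected set statistics,
  including the moment ellipse of the neighborhood.

Cells lacking the required neighborhood receive a documented fill (0, or 1 for
tortuosity), keeping every vector finite and exactly 484 long.

**Classifier.** Features are z-scored (statistics from the training set,
zero-variance features masked) and passed to a dense network
484 → 128 → 64 → n_classes (ReLU, softmax, cross-entropy, early stopping on a
10 % validation split). Classes are balanced by seeded downsampling before
training. `CellClassifier` follows the scikit-learn estimator API, so it works
with sklearn pipelines and model selection.

**Evaluation.** Per-class precision, sensitivity, F1 and AUC-ROC; detection
metrics by one-to-one IoU matching of label images with
accuracy = TP/(TP+FP+FN); the feature–class correlation index |Pearson r|; and
feature-family ablation masks (shape-only, intrinsic-only, contextual-without-
texture, all).

## Worked example

Train on two synthetic scenes, evaluate on a held-out third:

```python
import numpy as np
from xenoclass import (SceneSpec, generate_scene, measure_features,
                       CellClassifier, balance_classes, evaluate_classification)

def scene_xy(seed):
    scene = generate_scene(SceneSpec(size_px=768, n_human=80, n_mouse=80,
                                     n_curves=2, seed=seed))
    _, records, features = measure_features(scene.image, scene.nuclei)
    labels = (scene.truth.set_index("cell_id")
              .loc[[r.cell_label for r in records], "class"].to_numpy())
    return features, labels

Xa, ya = scene_xy(0)
Xb, yb = scene_xy(1)
Xtr, ytr, _ = balance_classes(np.vstack([Xa, Xb]), np.concatenate([ya, yb]), seed=0)
clf = CellClassifier(random_state=0).fit(Xtr, ytr)

Xte, yte = scene_xy(2)
proba = clf.predict_proba(Xte.to_numpy())
pred = clf.classes_[proba.argmax(axis=1)]
m = evaluate_classification(yte, pred, proba, list(clf.classes_))
print(f"test accuracy: {m.accuracy:.4f}")
for cls, e in m.per_class.items():
    print(f"{cls}: precision {e['precision']:.4f} sensitivity {e['sensitivity']:.4f} "
          f"F1 {e['f1']:.4f} AUC {e['auc']:.4f}")
```

Output:

```
test accuracy: 0.9625
human: precision 1.0000 sensitivity 0.9250 F1 0.9610 AUC 0.9989
mouse: precision 0.9302 sensitivity 1.0000 F1 0.9639 AUC 0.9989
```

96 % of the held-out cells are classified correctly; the AUC near 1 shows the
predicted probabilities separate the two populations almost perfectly. The
synthetic populations differ in nucleus morphology *and* spatial organization
(chains vs blobs), both of which the descriptor captures.

The same stages are available from the shell:

```sh
xenoclass synth --out scene/ --seed 9 --size-px 768
xenoclass run --image scene/image.tif --nuclei scene/nuclei.tif \
  --model model/ --truth scene/truth.csv --out results/ --um-per-px 0.5
```

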