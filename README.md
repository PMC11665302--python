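# slidemil

Attention-based multiple instance learning (MIL) for whole-slide-image (WSI)
classification, with a complete tile preprocessing/embedding pipeline and
"virtual staining" heatmap outputs.

## The problem

Pathology labels — tumor present, gene mutated — attach to a whole slide (or
patient), not to individual image regions, so a slide must be classified
from a *bag* of unlabeled 512 × 512 tiles. In the standard MIL formulation a
bag $X = \{x_1, \dots, x_n\}$ has one binary label $Y$; the per-instance
labels $y_i$ are latent. `slidemil` implements and compares three
lightweight attention-based MIL architectures over tile embeddings
$h_i = f(x_i)$:

* **AMIL** (attention pooling). Instance scores
  $\psi_a(h_i) = w^\top \tanh(V h_i^\top)$ are softmax-normalized into
  attention weights $a_i$, and a bag classifier scores the pooled embedding:
  $p(h) = \psi_p\!\left(\sum_i a_i h_i\right)$.
* **AdMIL** (additive MIL). Same scorer shape with LeakyReLU in place of
  tanh, and the head moves *inside* the sum:
  $p(h) = \sum_i \psi_p(a_i h_i)$, so every patch owns an explicit
  per-class contribution logit. Sigmoid-bounding a patch's positive-class
  logit gives a score in (0, 1): above 0.5 *excitatory* (pushes toward the
  positive class), at or below 0.5 *inhibitory*.
* **admil_tanh** — the hybrid: AdMIL's additive head with AMIL's tanh
  attention.

All three are permutation-invariant in the instances, trained with binary
cross-entropy on the positive-class probability of a two-class softmax head.

Around the models sits the full experimental apparatus: a pyramidal-slide
tiling pipeline (thumbnail Otsu tissue masking, morphological closing,
color-distance artifact filtering, hierarchical coordinate mapping across
5×/10×/20× magnifications, tile padding/acceptance, fraction and k-means
cluster sampling), a pluggable tile encoder with an HDF5 embedding store,
a replicated cross-validation evaluation protocol, and heatmap rendering.
Synthetic generators (MIL bags with known witness instances; pyramidal
slides with ground-truth masks) make everything testable without any
external data.

## Worked example

`examples/01_mil_variants.py` builds a 10-instance bag (two instances
shifted to act as witnesses) and runs all three variants:

```
amil
  P(class) = [0.281 0.719]
  attention (sums to 1.000000):
    [0.08  0.093 0.096 0.125 0.071 0.111 0.084 0.125 0.115 0.1  ]

admil
  P(class) = [0.312 0.688]
  attention (sums to 1.000000):
    [0.097 0.112 0.108 0.1   0.075 0.115 0.081 0.101 0.108 0.102]
  bounded contributions toward the positive class: [0.513 0.524 0.503 0.565
    0.511 0.501 0.503 0.583 0.504 0.495]
  polarity: ['exc', 'exc', 'exc', 'exc', 'exc', 'exc', 'exc', 'exc', 'exc', 'inh']
```

The attention vector is a distribution over the bag's instances; for the
additive variants each instance also receives a bounded contribution score
whose polarity says whether that patch argued for (red, in heatmaps) or
against (blue) the positive class. `examples/02_protocol_on_synthetic_bags.py`
runs the evaluation protocol (80/20 stratified split, 5-fold CV with
best-fold selection, replicate seeds) on a small synthetic dataset and
prints, e.g.:

```
replicate 0: split seed 1, best fold 0, test AUC 0.938
replicate 1: split seed 2, best fold 0, test AUC 0.828
mean test AUC 0.883 +/- 0.055
```

`examples/03_slide_pipeline.py` and `examples/04_heatmaps.py` walk the
slide pipeline (synthetic pyramid → tissue mask → tiles → embeddings →
HDF5) and the overlay rendering.

## Command line

The same workflow is scriptable from a shell:

```sh
slidemil simulate-slide slides/s0.tiff --seed 5
slidemil prep slides/ store.h5 --config prep.yaml --seed 1
slidemil train store.h5 runs/admil --variant admil --seed 0
slidemil heatmap store.h5 runs/admil/best_model slides/s0.tiff s0 \
    overlay.png --mode contribution_binary
```

Config files are flat YAML key–value mappings; every pipeline threshold
(tissue fraction, color distance, tile limits, k-means settings) and every
training setting (optimizer, epochs, folds, replicates) is a documented key
(see `slidemil.pipeline.PrepConfig` and `slidemil.training.ExperimentConfig`).

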