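# markersel

Differentiable marker-gene panel selection for single-cell expression data.

Given a cells × genes expression matrix `X ∈ ℝ^{n×d}` with optional cell-type
annotations, `markersel` learns a **global** panel `S ⊂ {1,…,d}`, `|S| = k`,
of marker genes that is maximally informative for cell-type classification,
whole-transcriptome reconstruction, or both. Unlike one-vs-all differential
expression, the panel is optimized *jointly*: genes are selected for what
they contribute together, which matters when no single gene separates the
populations (interaction signals, redundant programs, panel design for
spatial transcriptomics probes).

## The model

Selection is a relaxed categorical distribution over genes. A panel of `K`
selector nodes shares one vector of per-gene logits `log π`; node `k` draws

```
γ_j^(k) = exp((log π_j + g_j^(k)) / τ) / Σ_s exp((log π_s + g_s^(k)) / τ),
```

with i.i.d. standard Gumbel noise `g` and temperature `τ`. As `τ → 0` each
`γ^(k)` approaches a hard one-hot draw with `Pr(γ_j = 1) → π_j / Σ_s π_s`,
so the relaxation interpolates between mixing genes (smooth gradients) and
picking single genes (discrete selection); `τ` is annealed geometrically
from 2.0 to 0.01 during training. The combined soft mask scales every cell,
and the masked profile feeds two heads: a softmax classifier `f_W` and a
Gaussian-latent variational autoencoder `f_θ` (latent dimension 16) that
reconstructs the full profile. The training objective is

```
α ‖f_θ(X_S) − X‖²  +  (1 − α) ℓ(f_W(X_S), Y)  +  KL term,
```

with `α = 0` (supervised), `α = 1` (unsupervised) or `α = 0.5` (joint).
The logits are not free parameters: an encoder network `f_π` produces
instance-wise logits whose batch means are pooled across batches by an
exponential moving average (`log π ← β log π + (1−β) mean_i f_π(x_i)`),
making the selection global across cells. After convergence, the `k` genes
with the largest aggregated logits form the panel.

Everything trains end-to-end through the reparameterized sampler with a
small tape-based reverse-mode autodiff core written for this model family
(`markersel.nn`, `markersel._autodiff`); gradients are verified against
finite differences in the test suite.

## Worked example

```python
import numpy as np
from markersel import (gaussian_clusters, select, TrainingConfig,
                       evaluate_markers, split_dataset)

# 1000 cells, 100 genes, 4 cell types; only genes 0-11 carry class signal
ds, truth = gaussian_clusters(n=1000, d=100, C=4, n_informative=12,
                              separation=4.0, seed=0)
markers = select(ds, k=12, config=TrainingConfig(mode="supervised", seed=0))
print("selected genes:", sorted(markers.indices))

split = split_dataset(ds, seed=0)
train = ds.subset_cells(np.concatenate([split.train_idx, split.val_idx]))
test = ds.subset_cells(split.test_idx)
report = evaluate_markers(train, test, markers, classifier="nearest_neighbor")
print(f"test accuracy on the 12-gene panel: {report.accuracy:.3f}")
```

prints

```
selected genes: [0, 1, 2, 3, 4, 6, 7, 8, 9, 10, 11, 13]
test accuracy on the 12-gene panel: 0.860
```

— the selector recovers 11 of the 12 informative genes from the annotations
alone, and a 1-nearest-neighbor classifier restricted to the learned panel
classifies held-out cells at 86% (4 classes, weak per-gene signal). The
marker scores are the softmax selection probabilities of the chosen genes.

## Command line

```sh
markersel simulate --kind parity --out toy.csv --n 4000 --d 500 --seed 0
markersel select --input toy.csv --format csv --label-field label \
    --mode supervised --k 3 --seed 0 --out-dir run
markersel benchmark --input toy.csv --format csv --label-field label \
    --k 3 --methods supervised,random --noise-fractions 0,0.2,0.5 --out-dir bench
markersel reconstruct --checkpoint run/checkpoint.npz --input toy.csv \
    --format csv --label-field label --out-dir rec
```

Each run writes its outputs plus a `manifest.json` (canonical config, hash,
seed, version) under one directory and is reproducible from the manifest
alone. Readers accept h5ad, dense CSV/TSV and MatrixMarket triplets; raw
counts pass through per-cell-type presence filtering, per-cell total-count
scaling, `log2(1+x)` and per-gene standardization (a whole-matrix variant is
used when evaluating reconstructions).

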