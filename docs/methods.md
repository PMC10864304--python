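# Methods

## Model

`markersel` treats marker selection as learning a categorical distribution
over genes. A shared logit vector `log π ∈ ℝ^d` defines the probability
that a gene enters the panel; `K` selector nodes draw relaxed one-hot
vectors from it via the Gumbel-softmax transform

γ_j = exp((log π_j + g_j)/τ) / Σ_s exp((log π_s + g_s)/τ),  g ~ Gumbel(0,1).

The draw is reparameterized — γ is a deterministic, differentiable function
of the logits given the noise — so gradients of any downstream loss reach
the logits. As τ → 0 the draw becomes a hard categorical sample with
probabilities softmax(log π); at large τ it flattens toward the uniform
mixture. The closed-form density of the relaxed draw is implemented as a
testing utility (`gumbel_softmax_log_density`) and Monte-Carlo-checked to
integrate to one; the training path only ever uses the sampler.

### Masked versus compressed representations

The `K` rows are combined into a soft mask `m = max_k γ^(k)` and each cell
is scaled gene-wise, `x ⊙ m`, before entering the task heads
(`representation="masked"`, the default). In the low-temperature limit the
mask is k-hot and this is exact feature selection with gene positions
preserved. An alternative compressed representation
(`representation="compressed"`) instead feeds the K inner products
`⟨x, γ^(k)⟩`. Both are implemented; the masked form is the default for a
dynamical reason: the K nodes share one logit vector and are resampled
every batch, so under the compressed form "feature k" has no stable
identity across batches — the heads can only learn exchangeable functions
of the features, gradient feedback to individual genes is weak, and on the
fixtures below selection collapses onto a few genes. With the masked form
each gene keeps its coordinate, the classifier's batch-norm input layer
rescales even weakly masked genes back into view, and selection spreads
correctly over complementary gene sets. The compressed path remains
available and tested.

### Networks

* `f_π` (logit encoder): d → h → h → d, producing instance-wise logits.
* `f_W` (classifier): feature → h → C with a softmax head.
* `f_θ` (reconstructor): feature → h → h → Gaussian latent (dimension 16,
  mean and log-variance heads) → h → d, identity output.

Hidden layers are Linear → BatchNorm → LeakyReLU (negative slope 0.01)
throughout; h defaults to round(d/10) clamped to [64, 512]. Linear weights
use Kaiming-normal initialization with the leaky-ReLU gain; batch-norm
scales start at 1, biases at 0. Batch norm runs on batch statistics during
fitting and on running statistics during evaluation.

### Objective

loss = α · mean_i ‖x̂_i − x_i‖²  +  (1−α) · CE(f_W(x_S), y)  +  w_KL · KL.

* The reconstruction term is the squared ℓ2 error summed over genes,
  averaged over the batch (so it scales like d and the per-cell KL term,
  summed over the 16 latent dimensions, does not dominate).
* The classification term is categorical cross-entropy, the canonical loss
  for a softmax head; a squared-error-on-one-hot variant is available via
  `classification_loss="squared"` for strict ℓ2 reading of the objective.
* `kl_weight` defaults to 1 and may be set to 0 for a plain autoencoder.
* α = 0, 1, 0.5 correspond to the supervised, unsupervised and joint modes.
  With α = 0 no reconstructor is built (and vice versa), so the unused head
  trivially receives no gradient.

### Optimization loop

Per batch: instance logits → batch mean → EMA blend into the global logits
(momentum β = 0.9; only the current batch's contribution carries gradient,
the previous logits are treated as a constant, as in batch-norm running
moments) → K Gumbel-softmax draws at the current temperature → masking →
heads → Adam step. Batches are sampled without replacement; a trailing
singleton batch is merged into its predecessor so batch norm always sees at
least two rows. Temperature decays geometrically per step from τ₀ = 2.0 to
τ₁ = 0.01 across the full max-epoch budget (per-epoch decay is available).
A `logit_mode="free"` ablation replaces the f_π/EMA pathway with directly
learned logit parameters — the local-logit baseline used to isolate the
effect of batch aggregation.

Training runs at least 25 and at most 100 epochs (batch size 64) and stops
early when the validation loss has not improved by at least 1e-5 for 3
consecutive epochs. Validation loss is computed in evaluation mode with one
fixed Gumbel draw sampled at the start of the run, so epoch-to-epoch
differences reflect the parameters and the annealed temperature rather
than fresh sampling noise; the VAE is evaluated at the posterior mean.

The learning rate comes from a finder: 8 candidates on a linear grid in
[1e-8, 1e-3], each short-fitted for 40 batches from a fresh initialization;
the candidate with the largest drop of the smoothed training-loss curve
wins. Adam uses default moment parameters; only the learning rate is tuned.

One integer seed drives everything through independent derived streams
(initialization, batch order, Gumbel noise, latent noise, validation
noise), so runs are bitwise reproducible and components are individually
replayable.

### Extraction

After training, the panel is the global top-k of the aggregated logits
(ties toward the lower gene index), with softmax selection probabilities as
scores. Top-k over the shared logits — rather than per-node argmax —
guarantees k distinct genes even when nodes duplicate.

## Preprocessing

"Present" means a strictly positive raw count. `filter_genes` keeps a gene
iff it is present in ≥ 30% of cells of at least one cell type and present
in > 75% of cells in fewer than half of the cell types (both thresholds
configurable); an optional user-supplied exclusion list removes named
housekeeping/general-function genes, and an optional coarse pre-filter for
very large sparse matrices (presence ≥ 0.05%, and presence ≥ 3% or
mean-when-present > 1.12) is off by default. Standard normalization scales
each cell to the median pre-normalization total (the target is
configurable; the method only requires a common total), applies log2(1+x),
and standardizes each gene; constant genes are left at zero after centering
rather than propagating NaNs. Generative normalization — used when
evaluating reconstructions, where between-gene variance differences are the
signal — applies log2(1+x) and standardizes the whole matrix globally.
Splits are cell-wise uniform at 70/10/20 by largest-remainder
apportionment, without label stratification.

## Synthetic fixtures

`parity_toy`: every gene is an i.i.d. ±1 signal; a cell is in state A iff
genes 0–2 agree in sign. Every gene has zero per-state mean, so the task is
a pure three-way interaction — the hardest case for marginal methods and
the cleanest demonstration that joint selection works. Gaussian jitter
(sd 0.1 by default; 0 gives the literal ±1 values) keeps the data
continuous for gradient training, and the returned matrix is per-gene
standardized. Desk-scale defaults are n = 4000 cells × d = 500 genes.
Convergence on this task is an exploration lottery: roughly half of the
random seeds concentrate the selection distribution on the informative
triple (approaching the (1/3, 1/3, 1/3, 0, …) limit with residual mass
below 0.01), while the rest stall at the class-prior plateau and never
recover once the temperature has annealed down — running to the full
100-epoch budget does not rescue a stalled run. The parity experiment is
therefore defined, and reproduced, at a fixed seed.

`gaussian_clusters`: balanced classes whose mean vectors, restricted to the
first `n_informative` genes, form a regular simplex with pairwise distance
`separation` in within-class standard-deviation units, randomly rotated
within the informative subspace; remaining genes are standard normal noise.
Columns are mean-centered but not re-standardized — rescaling would shrink
the very separation the parameter specifies — so signal-bearing columns
retain their extra between-class variance; the dataset is marked
model-ready (`normalized_standard`) and is consumed as-is. Recovery
experiments use n = 3000 cells, matching the scale of classic annotated
scRNA-seq resources (~3000 cells).

`count_matrix`: Bernoulli presence per cell type × (Poisson + 1) magnitude,
so realized presence matches the requested profile exactly in expectation —
the fixture for the preprocessing filters. None of the generators model
dropout calibration, library-size variation or batch effects; passing tests
demonstrate the mechanics of selection, not performance on real tissue.

## Evaluation harness

Classification: panels are judged by refitting a standard downstream
classifier (1-nearest-neighbor by default, or a seeded 100-tree random
forest) on the marker columns. Per-class misclassification is the
precision complement M_c = 1 − TP_c/(TP_c + FP_c), averaged unweighted; a
class never predicted gets M_c = 1 with a warning. F1 is reported both
macro-averaged and support-weighted, and plain 1 − accuracy is included
alongside the precision-complement average. Reconstruction: Jaccard overlap
of the top-⌊d/5⌋ variance gene sets, Spearman correlation of variance ranks
(average ranks on ties), and mean per-cell ℓ2 and ℓ1 distances, optionally
broken down by cell type plus an overall row.

Label-noise protocols: a chosen fraction of training cells has labels
resampled uniformly over all observed labels (so the expected changed
fraction is `fraction · (1 − 1/C)`). Under `noisy_both` the corrupted
labels drive both marker selection and the downstream classifier; under
`noisy_selection_only` only the selection step sees them. Accuracy is
always measured on clean test labels. Label-independent selections give
exactly flat curves under the selection-only protocol; under `noisy_both`
even they decay, because the downstream classifier itself is corrupted.

Baselines: uniformly random panels, and the free-logit ablation described
above. Any callable `(dataset, k, seed) → MarkerSet` plugs into the same
harness.

## Numerical choices

* Gumbel draws clip the uniform variate away from {0, 1} at machine
  precision; all softmaxes subtract the row maximum.
* The relaxed-density evaluation uses a log-sum-exp and rejects boundary
  points, where the density is undefined.
* EMA momentum β = 0.9; the admissible range is (0, 1) exclusive.
* Early-stopping "improvement" means a strict decrease ≥ 1e-5.
* Marker extraction ties break to the lower gene index; `k = d` returns all
  genes without training.
* Checkpoints serialize every parameter and batch-norm buffer plus the
  selector state and configuration to a single `.npz`, round-tripping
  bitwise.
* All arithmetic is float64.

## Known limitations

* The parity-toy seed dependence described above.
* Selection quality is reported for the synthetic fixtures; real-tissue
  performance depends on preprocessing choices (especially the presence
  filters) that the fixtures only exercise mechanically.
* The VAE reconstructions show strong variance shrinkage — on the cluster
  fixture the reconstructed per-gene variance is about 1–2% of the original
  — which is expected behaviour for Gaussian VAEs trained on weak-structure
  data and is measured, not corrected, here.
* The reconstruction decoder is Gaussian; count likelihoods (negative
  binomial / ZINB) are out of scope.
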