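"""The batch training loop that drives marker selection.

Each batch runs the six-step update: (1) instance-wise logits from the logit
network, (2) their batch mean blended into the global logits by exponential
moving average, (3) K relaxed one-hot draws from the aggregated logits at
the current temperature, (4) compression of the batch onto those draws,
(5) the classification and/or reconstruction heads, (6) an adaptive-moment
gradient step on the combined objective.  The temperature decays
geometrically across the run; training stops early when validation loss
stops improving.

One global seed drives parameter initialization, batch order, Gumbel noise,
latent noise and validation noise through independent derived streams, so
every component is individually reproducible.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from ._autodiff import Tensor, constant, log_softmax
from .data_io import ExpressionDataset, SplitAssignment, normalize, split_dataset
from .models import (ModelBundle, ModelConfig, combined_loss, instance_logits)
from .nn import Adam
from .selector import (MarkerSet, SelectorState, TemperatureSchedule, anneal,
                       extract_markers, sample_gumbel)

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "TrainingDivergedError",
    "EarlyStopper",
    "MODE_ALPHA",
    "initialize",
    "find_learning_rate",
    "fit",
    "select",
]

MODE_ALPHA = {"supervised": 0.0, "unsupervised": 1.0, "joint": 0.5}


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite; carries epoch, tau and lr."""


@dataclasses.dataclass
class TrainingConfig:
    """Everything the optimization loop needs besides the data."""

    mode: str = "supervised"
    batch_size: int = 64
    max_epochs: int = 100
    min_epochs: int = 25
    patience: int = 3
    lr_range: tuple[float, float] = (1e-8, 1e-3)
    lr_candidates: int = 8
    lr_finder_batches: int = 40
    learning_rate: float | None = None
    seed: int = 0
    prior_logits: np.ndarray | None = None
    ema_momentum: float = 0.9
    tau_initial: float = 2.0
    tau_final: float = 0.01
    anneal_granularity: str = "step"  # or "epoch"
    improvement_tol: float = 1e-5
    logit_mode: str = "ema"  # "free" learns the logits as a direct parameter
    kl_weight: float = 1.0
    classification_loss: str = "cross_entropy"
    alpha: float | None = None  # derived from mode when None

    def __post_init__(self):
        if self.mode not in MODE_ALPHA:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.min_epochs > self.max_epochs:
            raise ValueError("min_epochs must not exceed max_epochs")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.lr_range[0] > self.lr_range[1]:
            raise ValueError("lr_range must be ordered")
        if self.logit_mode not in ("ema", "free"):
            raise ValueError("logit_mode must be 'ema' or 'free'")
        if self.anneal_granularity not in ("step", "epoch"):
            raise ValueError("anneal_granularity must be 'step' or 'epoch'")

    @property
    def effective_alpha(self) -> float:
        return MODE_ALPHA[self.mode] if self.alpha is None else self.alpha


@dataclasses.dataclass
class TrainingHistory:
    train_loss: list[float] = dataclasses.field(default_factory=list)
    val_loss: list[float] = dataclasses.field(default_factory=list)
    temperature: list[float] = dataclasses.field(default_factory=list)
    logit_entropy: list[float] = dataclasses.field(default_factory=list)
    learning_rate: float | None = None
    stopped_epoch: int | None = None


class EarlyStopper:
    """Stop when validation loss has not improved by ``tol`` for ``patience`` epochs."""

    def __init__(self, patience: int, min_epochs: int, tol: float = 1e-5):
        self.patience = patience
        self.min_epochs = min_epochs
        self.tol = tol
        self.best = math.inf
        self.since_improvement = 0

    def update(self, val_loss: float, epoch: int) -> bool:
        """Record this epoch's validation loss; return True to stop now."""
        if val_loss < self.best - self.tol:
            self.best = val_loss
            self.since_improvement = 0
        else:
            self.since_improvement += 1
        return (epoch + 1 >= self.min_epochs
                and self.since_improvement >= self.patience)


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(5)
    names = ("init", "batch", "gumbel", "latent", "val")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def initialize(model_config: ModelConfig, config: TrainingConfig
               ) -> tuple[ModelBundle, SelectorState]:
    """Build the networks and the selector state.

    Linear weights are Kaiming-initialized under the derived init stream;
    batch-norm scales start at 1 and biases at 0.  The logits start
    constant — a uniform selection distribution over all genes — unless
    ``prior_logits`` encodes an informed guess.
    """
    rng = _streams(config.seed)["init"]
    bundle = ModelBundle.create(model_config, rng)
    d = model_config.input_dim
    if config.prior_logits is not None:
        logits = np.asarray(config.prior_logits, dtype=np.float64)
        if logits.shape != (d,):
            raise ValueError(f"prior_logits must have length {d}")
    else:
        logits = np.zeros(d)
    state = SelectorState(logits=logits, ema_momentum=config.ema_momentum,
                          num_selectors=model_config.num_selectors,
                          temperature=config.tau_initial)
    return bundle, state


def _batches(train_idx: np.ndarray, batch_size: int,
             rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffled batches without replacement; a trailing singleton is merged
    into the previous batch so batch normalization always sees >= 2 rows."""
    order = rng.permutation(train_idx)
    chunks = [order[i:i + batch_size] for i in range(0, len(order), batch_size)]
    if len(chunks) > 1 and len(chunks[-1]) == 1:
        chunks[-2] = np.concatenate([chunks[-2], chunks[-1]])
        chunks.pop()
    return chunks


# ---------------------------------------------------------------------------
# the loop
# ---------------------------------------------------------------------------

def _forward_loss(bundle: ModelBundle, Xb: np.ndarray, yb: np.ndarray | None,
                  sampling_logits: Tensor, noise: np.ndarray, tau: float,
                  config: TrainingConfig, latent_rng: np.random.Generator | None
                  ) -> Tensor:
    """Steps 3-5 for one batch: sample, compress, heads, combined loss."""
    alpha = config.effective_alpha
    d = sampling_logits.data.size
    z = (sampling_logits.reshape(1, d) + constant(noise)) * (1.0 / tau)
    gamma = log_softmax(z, axis=1).exp()
    xb_t = constant(Xb)
    if bundle.config.representation == "masked":
        features = xb_t * gamma.max(axis=0).reshape(1, d)
    else:
        features = xb_t @ gamma.T
    scores = None
    x_hat = None
    kl: Tensor | float = 0.0
    if alpha < 1.0:
        scores = bundle.classifier(features)
    if alpha > 0.0:
        from .models import reconstruct

        x_hat, kl = reconstruct(bundle, features, latent_rng)
    return combined_loss(xb_t, x_hat, yb, scores, alpha, kl,
                         kl_weight=config.kl_weight if alpha > 0 else 0.0,
                         classification_loss=config.classification_loss)


def fit(bundle: ModelBundle, state: SelectorState, ds: ExpressionDataset,
        split: SplitAssignment, config: TrainingConfig,
        log_fn=None, _batch_limit: int | None = None) -> TrainingHistory:
    """Train ``bundle`` and ``state`` in place; returns the epoch history."""
    alpha = config.effective_alpha
    if config.learning_rate is None:
        raise ValueError("fit requires config.learning_rate (see find_learning_rate)")
    if alpha < 1.0 and ds.labels is None:
        raise ValueError(f"mode {config.mode!r} needs labels")
    y_codes = None
    if ds.labels is not None and alpha < 1.0:
        _, y_codes = np.unique(ds.labels, return_inverse=True)
    X = ds.matrix
    if len(split.train_idx) < 2:
        raise ValueError("need at least 2 training cells")

    streams = _streams(config.seed)
    rng_batch, rng_gumbel = streams["batch"], streams["gumbel"]
    rng_latent, rng_val = streams["latent"], streams["val"]

    K, d = state.num_selectors, state.logits.size
    bpe = max(1, math.ceil(len(split.train_idx) / config.batch_size))
    total_steps = (config.max_epochs * bpe if config.anneal_granularity == "step"
                   else config.max_epochs)
    schedule = TemperatureSchedule(config.tau_initial, config.tau_final,
                                   total_steps=max(total_steps, 1))

    free_logits = None
    params = bundle.parameters()
    if config.logit_mode == "free":
        free_logits = Tensor(state.logits.copy(), requires_grad=True)
        params = [p for p in params] + [free_logits]
    opt = Adam(params, lr=config.learning_rate)

    # fixed validation noise: epoch-to-epoch val-loss differences then
    # reflect the parameters, not fresh sampling noise
    val_noise = sample_gumbel((K, d), rng_val)
    stopper = EarlyStopper(config.patience, config.min_epochs, config.improvement_tol)
    history = TrainingHistory(learning_rate=config.learning_rate)
    beta = state.ema_momentum
    step = 0

    for epoch in range(config.max_epochs):
        bundle.train()
        epoch_losses = []
        for batch_idx in _batches(split.train_idx, config.batch_size, rng_batch):
            tick = step if config.anneal_granularity == "step" else epoch
            tau = anneal(schedule, min(tick, schedule.total_steps))
            state.temperature = tau
            Xb = X[batch_idx]
            yb = None if y_codes is None else y_codes[batch_idx]
            if config.logit_mode == "ema":
                _, mean_logits = instance_logits(bundle, Xb)
                ema_t = constant(beta * state.logits) + (1.0 - beta) * mean_logits
                state.logits = ema_t.data.copy()
                sampling_logits = ema_t
            else:
                sampling_logits = free_logits
            noise = sample_gumbel((K, d), rng_gumbel)
            loss = _forward_loss(bundle, Xb, yb, sampling_logits, noise, tau,
                                 config, rng_latent)
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, tau {tau:.4g}, "
                    f"lr {config.learning_rate:.3g}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            if config.logit_mode == "free":
                state.logits = free_logits.data.copy()
            epoch_losses.append(float(loss.data))
            step += 1
            if _batch_limit is not None and step >= _batch_limit:
                history.train_loss.extend(epoch_losses)
                return history

        val_loss = _validation_loss(bundle, state, X, y_codes, split.val_idx,
                                    val_noise, config)
        probs = state.selection_probabilities
        entropy = float(-(probs * np.log(probs + 1e-300)).sum())
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        history.temperature.append(state.temperature)
        history.logit_entropy.append(entropy)
        if log_fn is not None:
            log_fn({"epoch": epoch, "tau": state.temperature,
                    "train_loss": history.train_loss[-1], "val_loss": val_loss,
                    "logit_entropy": entropy})
        if stopper.update(val_loss, epoch):
            history.stopped_epoch = epoch
            break
    return history


def _validation_loss(bundle: ModelBundle, state: SelectorState, X: np.ndarray,
                     y_codes: np.ndarray | None, val_idx: np.ndarray,
                     val_noise: np.ndarray, config: TrainingConfig) -> float:
    from .models import reconstruct
    from .selector import relaxed_one_hot

    alpha = config.effective_alpha
    bundle.eval()
    gamma = relaxed_one_hot(state.logits[None, :], val_noise, state.temperature)
    Xv = X[val_idx]
    if bundle.config.representation == "masked":
        features = constant(Xv * gamma.max(axis=0)[None, :])
    else:
        features = constant(Xv @ gamma.T)
    scores = bundle.classifier(features) if alpha < 1.0 else None
    x_hat, kl = (None, 0.0)
    if alpha > 0.0:
        x_hat, kl = reconstruct(bundle, features, rng=None, sample=False)
    yv = None if y_codes is None else y_codes[val_idx]
    loss = combined_loss(constant(Xv), x_hat, yv, scores, alpha, kl,
                         kl_weight=config.kl_weight if alpha > 0 else 0.0,
                         classification_loss=config.classification_loss)
    bundle.train()
    return float(loss.data)


# ---------------------------------------------------------------------------
# learning-rate finder
# ---------------------------------------------------------------------------

def _smooth(x: np.ndarray, window: int = 5) -> np.ndarray:
    if len(x) < window:
        return np.asarray(x)
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="valid")


def find_learning_rate(ds: ExpressionDataset, split: SplitAssignment,
                       model_config: ModelConfig, config: TrainingConfig) -> float:
    """Sweep a linear grid of learning rates; return the steepest descender.

    Each candidate gets a freshly initialized model trained for a short
    burst of batches; the candidate whose smoothed training-loss curve
    drops the most is returned.  All candidates lie inside ``lr_range``.
    """
    lo, hi = config.lr_range
    candidates = np.linspace(lo, hi, config.lr_candidates)
    best_lr, best_drop = None, -np.inf
    for lr in candidates:
        trial_cfg = dataclasses.replace(config, learning_rate=float(lr),
                                        max_epochs=config.max_epochs,
                                        min_epochs=0)
        bundle, state = initialize(model_config, trial_cfg)
        try:
            hist = fit(bundle, state, ds, split, trial_cfg,
                       _batch_limit=config.lr_finder_batches)
        except TrainingDivergedError:
            continue
        losses = _smooth(np.asarray(hist.train_loss))
        drop = float(losses[0] - losses[-1])
        if drop > best_drop:
            best_drop, best_lr = drop, float(lr)
    if best_lr is None:
        raise TrainingDivergedError(
            "every candidate learning rate diverged; check the input data")
    return best_lr


# ---------------------------------------------------------------------------
# one-call facade
# ---------------------------------------------------------------------------

def select(ds: ExpressionDataset, k: int, mode: str | None = None,
           config: TrainingConfig | None = None,
           model_config: ModelConfig | None = None,
           return_model: bool = False):
    """Select a k-gene marker panel from a dataset.

    Normalizes raw input (standard pipeline), splits 70/10/20 under the
    config seed, initializes, finds a learning rate if none is given, fits,
    and extracts the top-k genes by aggregated logit.  Returns the
    :class:`~markersel.selector.MarkerSet`, or ``(markers, bundle, state,
    history)`` when ``return_model`` is set.
    """
    if config is None:
        config = TrainingConfig(mode=mode or "supervised")
    elif mode is not None and mode != config.mode:
        config = dataclasses.replace(config, mode=mode)
    mode = config.mode
    if mode != "unsupervised":
        if ds.labels is None:
            raise ValueError(f"mode {mode!r} requires labeled data")
    else:
        ds = ds.drop_labels()
    if ds.stage == "raw":
        ds = normalize(ds, "standard")
    if k > ds.n_genes:
        raise ValueError(f"k={k} exceeds d={ds.n_genes}")
    if k == ds.n_genes and not return_model:
        return MarkerSet(indices=list(range(k)), scores=[1.0 / k] * k, budget=k)
    split = split_dataset(ds, (0.70, 0.10, 0.20), seed=config.seed)
    if model_config is None:
        model_config = ModelConfig(
            input_dim=ds.n_genes, num_selectors=k,
            num_classes=None if ds.labels is None else len(ds.classes),
            alpha=config.effective_alpha, kl_weight=config.kl_weight,
            classification_loss=config.classification_loss)
    bundle, state = initialize(model_config, config)
    if config.learning_rate is None:
        lr = find_learning_rate(ds, split, model_config, config)
        config = dataclasses.replace(config, learning_rate=lr)
        bundle, state = initialize(model_config, config)
    history = fit(bundle, state, ds, split, config)
    markers = extract_markers(state, k)
    if return_model:
        return markers, bundle, state, history
    return markers
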