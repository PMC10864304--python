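"""Model architectures and the combined selection objective.

Three networks share the work.  ``LogitNetwork`` (two hidden layers, d -> d)
produces instance-wise per-gene scores whose batch means feed the selector's
exponential moving average.  ``Classifier`` (one hidden layer, K -> C,
softmax head) predicts cell type from the K compressed features.
``VAEReconstructor`` (two hidden encoder layers into a 16-dimensional
Gaussian latent, one hidden decoder layer, identity output) reconstructs the
full d-gene profile from the same K features.  Hidden layers everywhere are
Linear -> BatchNorm -> LeakyReLU.

The training objective blends the two heads:

    loss = alpha * recon + (1 - alpha) * classification + kl_weight * kl

where ``recon`` is the mean over cells of the squared l2 reconstruction
error, ``classification`` is categorical cross-entropy on the softmax head
(a squared-error-on-one-hot alternative is available), and ``kl`` is the
standard-normal KL of the latent posterior.  alpha = 0 is the supervised
objective, alpha = 1 the unsupervised one, alpha = 0.5 the joint one.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from ._autodiff import Tensor, constant, log_softmax, softmax
from .nn import Adam, HiddenBlock, Linear, Module
from .selector import SelectorState

__all__ = [
    "ModelConfig",
    "ModelBundle",
    "LogitNetwork",
    "Classifier",
    "VAEReconstructor",
    "instance_logits",
    "select_and_compress",
    "apply_mask",
    "reconstruct",
    "classify",
    "combined_loss",
    "save_checkpoint",
    "load_checkpoint",
    "default_hidden_size",
]


def default_hidden_size(n_genes: int) -> int:
    """Hidden width heuristic: about a tenth of the gene count, in [64, 512]."""
    return int(np.clip(round(n_genes / 10), 64, 512))


@dataclasses.dataclass
class ModelConfig:
    """Architecture and loss hyperparameters.

    ``alpha`` balances reconstruction (weight ``alpha``) against
    classification (weight ``1 - alpha``); ``kl_weight`` scales the VAE's
    KL term and may be set to 0 for a plain autoencoding objective.
    """

    input_dim: int
    num_selectors: int
    hidden_size: int | None = None
    latent_dim: int = 16
    num_classes: int | None = None
    alpha: float = 0.0
    kl_weight: float = 1.0
    classification_loss: str = "cross_entropy"  # or "squared"
    negative_slope: float = 0.01
    representation: str = "masked"  # or "compressed"

    def __post_init__(self):
        if self.representation not in ("masked", "compressed"):
            raise ValueError("representation must be 'masked' or 'compressed'")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be non-negative")
        if self.hidden_size is None:
            self.hidden_size = default_hidden_size(self.input_dim)
        if self.alpha < 1.0 and self.num_classes is None:
            raise ValueError("num_classes required whenever alpha < 1")
        if self.classification_loss not in ("cross_entropy", "squared"):
            raise ValueError("classification_loss must be cross_entropy or squared")

    @property
    def feature_dim(self) -> int:
        """Input width of the task heads: d for the masked representation
        (selection is an element-wise soft mask over all genes), K for the
        compressed one (each selector node contributes one mixture feature)."""
        return self.input_dim if self.representation == "masked" else self.num_selectors


class LogitNetwork(Module):
    """Instance-wise logit encoder f_pi: d -> h -> h -> d."""

    def __init__(self, d: int, hidden: int, rng: np.random.Generator, slope: float = 0.01):
        self.block1 = HiddenBlock(d, hidden, rng, slope)
        self.block2 = HiddenBlock(hidden, hidden, rng, slope)
        self.out = Linear(hidden, d, rng, slope)

    def __call__(self, x: Tensor) -> Tensor:
        return self.out(self.block2(self.block1(x)))


class Classifier(Module):
    """Cell-type head f_W: K -> h -> C; returns unnormalized class scores."""

    def __init__(self, k: int, hidden: int, n_classes: int,
                 rng: np.random.Generator, slope: float = 0.01):
        self.block = HiddenBlock(k, hidden, rng, slope)
        self.out = Linear(hidden, n_classes, rng, slope)

    def __call__(self, compressed: Tensor) -> Tensor:
        return self.out(self.block(compressed))


class VAEReconstructor(Module):
    """Gaussian-latent reconstructor f_theta: K -> h -> h -> z(16) -> h -> d."""

    def __init__(self, k: int, hidden: int, latent: int, d: int,
                 rng: np.random.Generator, slope: float = 0.01):
        self.enc1 = HiddenBlock(k, hidden, rng, slope)
        self.enc2 = HiddenBlock(hidden, hidden, rng, slope)
        self.mu_head = Linear(hidden, latent, rng, slope)
        self.logvar_head = Linear(hidden, latent, rng, slope)
        self.dec = HiddenBlock(latent, hidden, rng, slope)
        self.out = Linear(hidden, d, rng, slope)
        self.latent = latent

    def encode(self, compressed: Tensor) -> tuple[Tensor, Tensor]:
        h = self.enc2(self.enc1(compressed))
        return self.mu_head(h), self.logvar_head(h)

    def decode(self, z: Tensor) -> Tensor:
        return self.out(self.dec(z))


@dataclasses.dataclass
class ModelBundle:
    """The trainable networks plus their configuration."""

    config: ModelConfig
    logit_net: LogitNetwork
    classifier: Classifier | None
    reconstructor: VAEReconstructor | None

    @classmethod
    def create(cls, config: ModelConfig, rng: np.random.Generator) -> "ModelBundle":
        h, s = config.hidden_size, config.negative_slope
        logit_net = LogitNetwork(config.input_dim, h, rng, s)
        classifier = None
        reconstructor = None
        feat = config.feature_dim
        if config.alpha < 1.0:
            classifier = Classifier(feat, h, config.num_classes, rng, s)
        if config.alpha > 0.0:
            reconstructor = VAEReconstructor(feat, h, config.latent_dim,
                                             config.input_dim, rng, s)
        return cls(config, logit_net, classifier, reconstructor)

    def modules(self) -> list[Module]:
        mods: list[Module] = [self.logit_net]
        if self.classifier is not None:
            mods.append(self.classifier)
        if self.reconstructor is not None:
            mods.append(self.reconstructor)
        return mods

    def parameters(self) -> list[Tensor]:
        return [p for m in self.modules() for p in m.parameters()]

    def train(self) -> None:
        for m in self.modules():
            m.train()

    def eval(self) -> None:
        for m in self.modules():
            m.eval()


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else constant(np.asarray(x, dtype=float))


def instance_logits(bundle: ModelBundle, batch) -> tuple[Tensor, Tensor]:
    """Per-cell logits f_pi(x_i) and their arithmetic mean over the batch."""
    batch = _as_tensor(batch)
    if batch.shape[1] != bundle.config.input_dim:
        raise ValueError(f"batch has {batch.shape[1]} genes, "
                         f"model expects {bundle.config.input_dim}")
    rows = bundle.logit_net(batch)
    return rows, rows.mean(axis=0)


def select_and_compress(batch, selection) -> Tensor:
    """Project a batch onto K relaxed selections: entry (i, k) = <x_i, gamma_k>.

    With one-hot gamma rows this is exact feature selection; with diffuse
    rows each compressed feature is a convex mixture of genes.
    """
    batch = _as_tensor(batch)
    gamma = selection if isinstance(selection, Tensor) else constant(
        np.asarray(getattr(selection, "gamma", selection), dtype=float))
    return batch @ gamma.T


def apply_mask(batch, selection) -> Tensor:
    """Masked representation: every cell scaled gene-wise by the combined mask.

    The K relaxed one-hot rows are combined by an element-wise maximum into a
    single soft mask over the d genes, and the batch is multiplied by it
    row-wise.  In the low-temperature limit the mask is k-hot and this is
    exact feature selection with gene positions preserved, so the task heads
    see a stable gene identity across batches.
    """
    batch = _as_tensor(batch)
    gamma = selection if isinstance(selection, Tensor) else constant(
        np.asarray(getattr(selection, "gamma", selection), dtype=float))
    mask = gamma.max(axis=0).reshape(1, gamma.shape[1])
    return batch * mask


def reconstruct(bundle: ModelBundle, compressed,
                rng: np.random.Generator | None = None,
                sample: bool = True) -> tuple[Tensor, Tensor]:
    """Reparameterized encode/decode; returns (x_hat, kl_term).

    kl_term is the mean over cells of the KL divergence between the
    diagonal-Gaussian posterior and the standard-normal prior, summed over
    the latent dimensions.  With ``sample=False`` the decoder sees the
    posterior mean (used for deterministic evaluation).
    """
    if bundle.reconstructor is None:
        raise ValueError("bundle has no reconstructor head (supervised-only model)")
    compressed = _as_tensor(compressed)
    mu, logvar = bundle.reconstructor.encode(compressed)
    if sample:
        eps = constant(rng.standard_normal(mu.shape))
        z = mu + (logvar * 0.5).exp() * eps
    else:
        z = mu
    x_hat = bundle.reconstructor.decode(z)
    kl = ((mu * mu + logvar.exp() - logvar - 1.0) * 0.5).sum(axis=1).mean()
    return x_hat, kl


def classify(bundle: ModelBundle, compressed) -> Tensor:
    """Class-probability rows (softmax head); rows sum to one."""
    if bundle.classifier is None:
        raise ValueError("bundle has no classifier head (unsupervised model)")
    return softmax(bundle.classifier(_as_tensor(compressed)), axis=1)


def _one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((y.size, n_classes))
    out[np.arange(y.size), y] = 1.0
    return out


def combined_loss(x, x_hat, y, class_scores, alpha: float, kl_term,
                  kl_weight: float = 1.0,
                  classification_loss: str = "cross_entropy") -> Tensor:
    """alpha * reconstruction + (1 - alpha) * classification + kl_weight * kl.

    Parameters
    ----------
    x, x_hat
        Original and reconstructed batches (ignored when ``alpha == 0``).
    y
        Integer class codes; required whenever ``alpha < 1``.
    class_scores
        Unnormalized classifier outputs (pre-softmax), one row per cell.
    kl_term
        Scalar latent KL (0 when there is no reconstructor).
    """
    terms = []
    if alpha > 0.0:
        x = _as_tensor(x)
        x_hat = _as_tensor(x_hat)
        diff = x_hat - x
        recon = (diff * diff).sum(axis=1).mean()
        terms.append(alpha * recon)
    if alpha < 1.0:
        if y is None:
            raise ValueError("labels required whenever alpha < 1")
        scores = _as_tensor(class_scores)
        y = np.asarray(y, dtype=int)
        n_classes = scores.shape[1]
        if classification_loss == "cross_entropy":
            logp = log_softmax(scores, axis=1)
            picked = (logp * constant(_one_hot(y, n_classes))).sum(axis=1)
            terms.append((1.0 - alpha) * (-picked.mean()))
        else:
            probs = softmax(scores, axis=1)
            diff = probs - constant(_one_hot(y, n_classes))
            terms.append((1.0 - alpha) * (diff * diff).sum(axis=1).mean())
    loss = terms[0]
    for t in terms[1:]:
        loss = loss + t
    if kl_weight != 0.0:
        loss = loss + kl_weight * _as_tensor(kl_term)
    return loss


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, bundle: ModelBundle, state: SelectorState) -> None:
    """Serialize networks, selector state and config to one ``.npz`` file."""
    arrays: dict[str, np.ndarray] = {}
    names = ("logit_net", "classifier", "reconstructor")
    for name in names:
        mod = getattr(bundle, name)
        if mod is not None:
            arrays.update(mod.state_arrays(prefix=name + "."))
    arrays["selector.logits"] = state.logits
    meta = {
        "model_config": dataclasses.asdict(bundle.config),
        "selector": {"ema_momentum": state.ema_momentum,
                     "num_selectors": state.num_selectors,
                     "temperature": state.temperature},
    }
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[ModelBundle, SelectorState]:
    with np.load(path) as data:
        arrays = {k: data[k] for k in data.files}
    meta = json.loads(bytes(arrays.pop("meta_json")).decode("utf-8"))
    config = ModelConfig(**meta["model_config"])
    bundle = ModelBundle.create(config, np.random.default_rng(0))
    for name in ("logit_net", "classifier", "reconstructor"):
        mod = getattr(bundle, name)
        if mod is not None:
            sub = {k[len(name) + 1:]: v for k, v in arrays.items()
                   if k.startswith(name + ".")}
            mod.load_state_arrays(sub)
    state = SelectorState(logits=arrays["selector.logits"],
                          ema_momentum=meta["selector"]["ema_momentum"],
                          num_selectors=meta["selector"]["num_selectors"],
                          temperature=meta["selector"]["temperature"])
    return bundle, state
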