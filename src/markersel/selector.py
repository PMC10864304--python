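"""The relaxed subset-sampling core of the marker selector.

A panel of K selector nodes shares one vector of per-gene logits log(pi).
Each node draws a relaxed one-hot vector over the d genes by perturbing the
logits with standard Gumbel noise and applying a temperature-tau softmax; as
tau -> 0 each draw approaches a hard categorical sample with probabilities
softmax(logits), so the relaxation interpolates between mixing genes (high
tau, smooth gradients) and picking single genes (low tau, discrete
selection).  The logits themselves are an exponential moving average of
batch-level scores produced during training, so selection is global across
cells rather than instance-wise.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.special import softmax as _softmax

__all__ = [
    "SelectorState",
    "TemperatureSchedule",
    "RelaxedSelection",
    "MarkerSet",
    "sample_gumbel",
    "relaxed_one_hot",
    "relaxed_subset",
    "gumbel_softmax_log_density",
    "update_logits_ema",
    "anneal",
    "extract_markers",
]


@dataclasses.dataclass
class SelectorState:
    """Aggregated selection distribution: logits plus sampling hyper-state."""

    logits: np.ndarray
    ema_momentum: float = 0.9
    num_selectors: int = 1
    temperature: float = 2.0

    def __post_init__(self):
        self.logits = np.asarray(self.logits, dtype=np.float64)
        if not np.isfinite(self.logits).all():
            raise ValueError("logits must be finite")
        if not 0.0 < self.ema_momentum < 1.0:
            raise ValueError("ema_momentum must lie strictly inside (0, 1)")
        if self.num_selectors < 1:
            raise ValueError("num_selectors must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def selection_probabilities(self) -> np.ndarray:
        return _softmax(self.logits)


@dataclasses.dataclass(frozen=True)
class TemperatureSchedule:
    """Geometric decay from ``tau_initial`` to ``tau_final`` over ``total_steps``."""

    tau_initial: float = 2.0
    tau_final: float = 0.01
    total_steps: int = 1000
    decay_mode: str = "geometric"

    def __post_init__(self):
        if self.tau_initial <= self.tau_final:
            raise ValueError("tau_initial must exceed tau_final")
        if self.tau_final <= 0:
            raise ValueError("tau_final must be positive")
        if self.decay_mode != "geometric":
            raise ValueError("only geometric decay is supported")
        if self.total_steps < 1:
            raise ValueError("total_steps must be positive")


def anneal(schedule: TemperatureSchedule, step: int) -> float:
    """Temperature at ``step``: tau_i * (tau_f / tau_i) ** (step / total)."""
    if not 0 <= step <= schedule.total_steps:
        raise ValueError(f"step {step} outside [0, {schedule.total_steps}]")
    frac = step / schedule.total_steps
    return float(schedule.tau_initial
                 * (schedule.tau_final / schedule.tau_initial) ** frac)


@dataclasses.dataclass(frozen=True)
class RelaxedSelection:
    """K relaxed one-hot rows over d genes, with the Gumbel draws that made them."""

    gamma: np.ndarray
    noise: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.gamma)
        if np.abs(g.sum(axis=-1) - 1.0).max() > 1e-6:
            raise ValueError("each gamma row must sum to 1")


@dataclasses.dataclass
class MarkerSet:
    """Ordered marker panel: distinct gene indices with non-increasing scores."""

    indices: list[int]
    scores: list[float]
    budget: int

    def __post_init__(self):
        if len(self.indices) != len(set(self.indices)):
            raise ValueError("marker indices must be distinct")
        if len(self.indices) > self.budget:
            raise ValueError("more markers than budget")
        if len(self.indices) != len(self.scores):
            raise ValueError("indices and scores must have equal length")
        if any(a < b - 1e-12 for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("scores must be non-increasing")


def sample_gumbel(shape, rng: np.random.Generator) -> np.ndarray:
    """Standard Gumbel(0, 1) draws: -log(-log(U)) with U ~ Uniform(0, 1)."""
    u = rng.random(shape)
    u = np.clip(u, np.finfo(float).tiny, 1.0 - np.finfo(float).epsneg)
    return -np.log(-np.log(u))


def relaxed_one_hot(logits: np.ndarray, noise: np.ndarray, tau: float) -> np.ndarray:
    """softmax((logits + noise) / tau) along the last axis, max-stabilized."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    z = (np.asarray(logits, dtype=float) + np.asarray(noise, dtype=float)) / tau
    return _softmax(z, axis=-1)


def relaxed_subset(state: SelectorState, rng: np.random.Generator) -> RelaxedSelection:
    """K independent relaxed one-hot draws from the shared aggregated logits."""
    noise = sample_gumbel((state.num_selectors, state.logits.size), rng)
    gamma = relaxed_one_hot(state.logits[None, :], noise, state.temperature)
    return RelaxedSelection(gamma=gamma, noise=noise)


def gumbel_softmax_log_density(gamma: np.ndarray, pi: np.ndarray, tau: float) -> float:
    """Log density of a relaxed categorical sample on the interior of the simplex.

    For a point gamma on the (m-1)-simplex and positive class weights pi,

        log p = log (m-1)! + (m-1) log tau - m log sum_i pi_i / gamma_i^tau
                + sum_i [log pi_i - (tau+1) log gamma_i],

    with respect to Lebesgue measure on the first m-1 coordinates.  The
    density is invariant to rescaling pi and is a testing utility only; the
    training path uses the reparameterized sampler.
    """
    gamma = np.asarray(gamma, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if tau <= 0:
        raise ValueError("tau must be positive")
    if (gamma <= 0).any() or (gamma >= 1).any():
        raise ValueError("density is undefined on the simplex boundary")
    if (pi <= 0).any():
        raise ValueError("pi must be strictly positive")
    m = gamma.size
    log_pi = np.log(pi)
    log_gamma = np.log(gamma)
    # log-sum-exp of log(pi_i) - tau*log(gamma_i)
    terms = log_pi - tau * log_gamma
    peak = terms.max()
    lse = peak + np.log(np.exp(terms - peak).sum())
    return float(math.lgamma(m) + (m - 1) * np.log(tau) - m * lse
                 + (log_pi - (tau + 1) * log_gamma).sum())


def update_logits_ema(state: SelectorState, batch_mean_logits: np.ndarray) -> SelectorState:
    """Blend a new batch-mean logit vector into the aggregated logits.

    new = beta * old + (1 - beta) * batch_mean, the exponential moving
    average that makes the selection distribution global across batches.
    """
    batch_mean_logits = np.asarray(batch_mean_logits, dtype=np.float64)
    if batch_mean_logits.shape != state.logits.shape:
        raise ValueError("batch logits shape mismatch")
    if not np.isfinite(batch_mean_logits).all():
        raise ValueError("non-finite batch logits (training divergence)")
    beta = state.ema_momentum
    return dataclasses.replace(
        state, logits=beta * state.logits + (1.0 - beta) * batch_mean_logits)


def extract_markers(state: SelectorState, k: int) -> MarkerSet:
    """The k genes with the largest aggregated logits.

    Ties break toward the lower gene index; scores are the softmax selection
    probabilities of the chosen genes.  Invariant to adding a constant to
    all logits.
    """
    d = state.logits.size
    if k > d:
        raise ValueError(f"k={k} exceeds number of genes d={d}")
    order = np.argsort(-state.logits, kind="stable")[:k]
    probs = state.selection_probabilities
    return MarkerSet(indices=[int(i) for i in order],
                     scores=[float(probs[i]) for i in order], budget=k)
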