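"""Self-supervised training loops.

Both loops minimize KL(P || Q) per batch with Adam, where Q is the
Student-t distribution over the current 2-D embeddings.  They differ in P:

* :func:`train_cnn_encoder` — P is the rank-distance distribution computed
  from the encoder's *own latent space* for every batch (the latent
  representation changes as training proceeds, so P must be regenerated per
  batch).  P is held constant within a step — no gradient flows through the
  ranking — and the update adjusts the parameters of both encoder parts.
* :func:`train_parametric_tsne` — classic parametric t-SNE: P is the
  Gaussian/perplexity distribution of the *fixed* input features of the
  batch, and only the embedding network learns.

The last batch of an epoch is dropped when smaller than the batch size
(the neighbor distributions are defined over full batches), and the data
order is reshuffled every epoch with a seeded generator.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

from .encoders import CnnEncoder, MlpEncoder
from .nn import Adam, l2_penalty
from .objective import (
    NeighborDistribution,
    PerplexitySpec,
    RankSpec,
    gaussian_neighbor_probs,
    kl_loss_grad_y,
    rank_neighbor_probs,
)
from .windows import WindowSet


@dataclass
class TrainConfig:
    batch_size: int = 500
    n_neighbors: int = 5
    perplexity: float = 5.0
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    epochs: int = 200
    seed: int = 0
    shuffle: bool = True
    early_stop_patience: int = 20
    early_stop_min_delta: float = 1e-4

    def validate(self) -> None:
        if self.batch_size <= self.n_neighbors + 1:
            raise ValueError(
                f"batch_size={self.batch_size} must exceed n_neighbors+1="
                f"{self.n_neighbors + 1}"
            )
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class TrainLog:
    """Per-step and per-epoch loss history of one training run."""

    step_losses: list[float] = field(default_factory=list)
    epoch_losses: list[float] = field(default_factory=list)
    wall_time_s: float = 0.0
    seed: int = 0
    config: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"epoch": range(len(self.epoch_losses)), "mean_loss": self.epoch_losses}
        )


StepCallback = Callable[[int, NeighborDistribution, float], None]


def _run_loop(
    forward_backward: Callable[[np.ndarray, int], float],
    data: np.ndarray,
    config: TrainConfig,
) -> TrainLog:
    config.validate()
    n = len(data)
    if config.batch_size > n:
        raise ValueError(f"batch_size={config.batch_size} exceeds n_train={n}")
    rng = np.random.default_rng(config.seed)
    log = TrainLog(seed=config.seed, config=asdict(config))
    t0 = time.perf_counter()
    step = 0
    best, best_epoch = np.inf, 0
    for epoch in range(config.epochs):
        idx = rng.permutation(n) if config.shuffle else np.arange(n)
        epoch_losses = []
        for start in range(0, n - config.batch_size + 1, config.batch_size):
            batch = data[idx[start : start + config.batch_size]]
            loss = forward_backward(batch, step)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss {loss} at step {step} (epoch {epoch}); "
                    "try a smaller learning rate"
                )
            log.step_losses.append(loss)
            epoch_losses.append(loss)
            step += 1
        mean_loss = float(np.mean(epoch_losses))
        log.epoch_losses.append(mean_loss)
        if mean_loss < best - config.early_stop_min_delta:
            best, best_epoch = mean_loss, epoch
        elif epoch - best_epoch >= config.early_stop_patience:
            break
    log.wall_time_s = time.perf_counter() - t0
    return log


def train_cnn_encoder(
    model: CnnEncoder,
    train: WindowSet,
    config: TrainConfig,
    step_callback: StepCallback | None = None,
) -> tuple[CnnEncoder, TrainLog]:
    """Train the CNN encoder end to end on raw (preprocessed) windows."""
    params = model.parameters()
    opt = Adam(params, lr=config.learning_rate)
    rank_spec = RankSpec(n_neighbors=config.n_neighbors)
    l2 = model.config.l2_weight

    def step_fn(batch: np.ndarray, step: int) -> float:
        z, y = model.forward(batch)
        P = rank_neighbor_probs(z, rank_spec)  # constant target for this step
        loss, dy = kl_loss_grad_y(P, y)
        opt.zero_grad()
        loss += l2_penalty(params, l2)
        model.backward(dy)
        opt.step()
        if step_callback is not None:
            step_callback(step, P, loss)
        return loss

    log = _run_loop(step_fn, train.data, config)
    return model, log


def train_parametric_tsne(
    model: MlpEncoder,
    features: np.ndarray,
    config: TrainConfig,
    step_callback: StepCallback | None = None,
) -> tuple[MlpEncoder, TrainLog]:
    """Train a baseline parametric t-SNE on fixed (z-scored) feature vectors."""
    features = np.asarray(features, dtype=np.float64)
    params = model.parameters()
    opt = Adam(params, lr=config.learning_rate)
    perp_spec = PerplexitySpec(perplexity=config.perplexity)
    l2 = model.config.l2_weight

    def step_fn(batch: np.ndarray, step: int) -> float:
        P = gaussian_neighbor_probs(batch, perp_spec)
        _, y = model.forward(batch)
        loss, dy = kl_loss_grad_y(P, y)
        opt.zero_grad()
        loss += l2_penalty(params, l2)
        model.backward(dy)
        opt.step()
        if step_callback is not None:
            step_callback(step, P, loss)
        return loss

    log = _run_loop(step_fn, features, config)
    return model, log
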