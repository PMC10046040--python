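"""Encoder architectures.

Two families are provided:

* :class:`CnnEncoder` — the two-part convolutional encoder for raw EEG
  windows.  Part 1 analyzes each channel separately with shared weights:
  a cascade of convolution + stride-2 max-pooling blocks produces
  ``n_levels`` progressively downsampled views of the signal (fields of
  view doubling per level); each level is reduced by a convolution, a
  global max-pool over time, and a small dense layer to
  ``features_per_level`` values.  Concatenating over levels and channels
  yields the high-dimensional latent z (21 channels x 6 levels x 10
  features = 1260 dimensions in the reference configuration).  Part 2 is a
  fully connected stack mapping z to the 2-D embedding y.
* :class:`MlpEncoder` — a four-layer fully connected encoder used with the
  fixed STFT/CWT feature representations, where the input feature vector
  itself plays the role of z.

Both are built on :mod:`neurotsne.nn` and expose ``forward`` returning the
pair (z, y) and ``backward`` accepting the loss gradient with respect to y.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import (
    Adam,
    Conv1d,
    Dense,
    ELU,
    GlobalMaxPool,
    Layer,
    MaxPool1d,
    Parameter,
    Sequential,
)


@dataclass
class CnnEncoderConfig:
    n_channels: int = 21
    n_samples: int = 250
    n_levels: int = 6
    convs_per_level: int = 1
    kernel_size: int = 5
    trunk_filters: int = 16
    head_filters: int = 16
    features_per_level: int = 10
    head_widths: tuple[int, ...] = (500, 500, 250)
    embed_dim: int = 2
    l2_weight: float = 1e-5

    @property
    def latent_dim(self) -> int:
        return self.n_channels * self.n_levels * self.features_per_level

    def validate(self) -> None:
        if self.n_samples < 2 ** (self.n_levels - 1):
            raise ValueError(
                f"n_samples={self.n_samples} too short for n_levels={self.n_levels}: "
                f"need at least 2**(n_levels-1) = {2 ** (self.n_levels - 1)} samples"
            )
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")


@dataclass
class MlpEncoderConfig:
    input_dim: int = 630
    hidden_widths: tuple[int, ...] = (1000, 500, 250)
    embed_dim: int = 2
    l2_weight: float = 1e-5

    def validate(self) -> None:
        if self.input_dim <= 0:
            raise ValueError("input_dim must be positive")
        if len(self.hidden_widths) + 1 != 4:
            raise ValueError("the baseline encoder is a 4-layer network")


def _mlp_stack(widths: list[int], rng: np.random.Generator) -> Sequential:
    layers: list[Layer] = []
    for i in range(len(widths) - 1):
        layers.append(Dense(widths[i], widths[i + 1], rng))
        if i < len(widths) - 2:
            layers.append(ELU())
    return Sequential(layers)


class CnnEncoder:
    """Two-part CNN encoder: raw window -> latent z -> embedding y."""

    def __init__(self, config: CnnEncoderConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        first: list[Layer] = [Conv1d(1, c.trunk_filters, c.kernel_size, rng), ELU()]
        for _ in range(c.convs_per_level - 1):
            first += [Conv1d(c.trunk_filters, c.trunk_filters, c.kernel_size, rng), ELU()]
        self.first = Sequential(first)
        self.down: list[Sequential] = []
        for _ in range(c.n_levels - 1):
            blk: list[Layer] = [MaxPool1d()]
            for _ in range(c.convs_per_level):
                blk += [Conv1d(c.trunk_filters, c.trunk_filters, c.kernel_size, rng), ELU()]
            self.down.append(Sequential(blk))
        self.heads = [
            Sequential(
                [
                    Conv1d(c.trunk_filters, c.head_filters, c.kernel_size, rng),
                    ELU(),
                    GlobalMaxPool(),
                    Dense(c.head_filters, c.features_per_level, rng),
                ]
            )
            for _ in range(c.n_levels)
        ]
        self.part2 = _mlp_stack(
            [c.latent_dim, *c.head_widths, c.embed_dim], rng
        )

    # -- parameters ---------------------------------------------------------
    def part1_parameters(self) -> list[Parameter]:
        params = list(self.first.parameters())
        for blk in self.down:
            params += blk.parameters()
        for head in self.heads:
            params += head.parameters()
        return params

    def parameters(self) -> list[Parameter]:
        return self.part1_parameters() + self.part2.parameters()

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """x: (B, n_channels, n_samples) -> (z: (B, latent_dim), y: (B, embed_dim))."""
        c = self.config
        B, C, T = x.shape
        if C != c.n_channels or T != c.n_samples:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match model input "
                f"({c.n_channels}, {c.n_samples})"
            )
        s = self.first.forward(x.reshape(B * C, 1, T))
        levels = [s]
        for blk in self.down:
            s = blk.forward(s)
            levels.append(s)
        feats = [head.forward(lv) for head, lv in zip(self.heads, levels)]
        zc = np.concatenate(feats, axis=1)  # (B*C, n_levels * fpl)
        self._B = B
        z = zc.reshape(B, c.latent_dim)
        y = self.part2.forward(z)
        return z, y

    def backward(self, dy: np.ndarray) -> None:
        """Backpropagate the loss gradient w.r.t. y through both parts."""
        c = self.config
        B = self._B
        dz = self.part2.backward(dy)
        dzc = dz.reshape(B * c.n_channels, c.n_levels * c.features_per_level)
        fpl = c.features_per_level
        dlevels = [
            head.backward(dzc[:, i * fpl : (i + 1) * fpl])
            for i, head in enumerate(self.heads)
        ]
        g = dlevels[-1]
        for l in range(c.n_levels - 1, 0, -1):
            g = self.down[l - 1].backward(g)
            g = g + dlevels[l - 1]
        self.first.backward(g)


class MlpEncoder:
    """Feature-vector encoder: z is the input itself; y = MLP(z)."""

    def __init__(self, config: MlpEncoderConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        self.net = _mlp_stack(
            [config.input_dim, *config.hidden_widths, config.embed_dim], rng
        )

    def parameters(self) -> list[Parameter]:
        return self.net.parameters()

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if x.ndim != 2 or x.shape[1] != self.config.input_dim:
            raise ValueError(
                f"expected (B, {self.config.input_dim}) features, got {x.shape}"
            )
        return x, self.net.forward(x)

    def backward(self, dy: np.ndarray) -> None:
        self.net.backward(dy)


EncoderModel = CnnEncoder | MlpEncoder


def build_cnn_encoder(config: CnnEncoderConfig | None = None, seed: int = 0) -> CnnEncoder:
    return CnnEncoder(config or CnnEncoderConfig(), seed=seed)


def build_mlp_encoder(config: MlpEncoderConfig | None = None, seed: int = 0) -> MlpEncoder:
    return MlpEncoder(config or MlpEncoderConfig(), seed=seed)


def encode(
    model: EncoderModel, inputs: np.ndarray, batch_size: int = 500
) -> tuple[np.ndarray, np.ndarray]:
    """Run ``inputs`` through the encoder in batches.

    Row order is preserved and results are batch-size invariant (there are
    no batch-dependent layers).  ``inputs`` is (n, channels, samples) for a
    CNN encoder or (n, input_dim) for an MLP encoder.
    """
    zs, ys = [], []
    for start in range(0, len(inputs), batch_size):
        z, y = model.forward(inputs[start : start + batch_size])
        zs.append(z)
        ys.append(y)
    return np.concatenate(zs), np.concatenate(ys)


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(model: EncoderModel, path: str | Path) -> None:
    """Save parameters (.npz) plus a self-describing architecture manifest."""
    path = Path(path)
    params = {f"param_{i}": p.value for i, p in enumerate(model.parameters())}
    np.savez_compressed(path.with_suffix(".npz"), **params)
    manifest = {
        "kind": "cnn" if isinstance(model, CnnEncoder) else "mlp",
        "config": asdict(model.config),
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_checkpoint(path: str | Path) -> EncoderModel:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    cfg = manifest["config"]
    for key in ("head_widths", "hidden_widths"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    if manifest["kind"] == "cnn":
        model: EncoderModel = CnnEncoder(CnnEncoderConfig(**cfg))
    else:
        model = MlpEncoder(MlpEncoderConfig(**cfg))
    with np.load(path.with_suffix(".npz")) as arc:
        for i, p in enumerate(model.parameters()):
            p.value[...] = arc[f"param_{i}"]
    return model
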