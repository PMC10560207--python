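"""Siamese encoder, cosine similarity and the contrastive cosine loss.

Both branches of the Siamese network are literally the same encoder f(.;Θ):
a heartbeat window of n_beats raw RR values (seconds) passes through three
convolution / batch-norm / max-pool / ReLU blocks and three linear layers
(the first two with dropout, batch norm and ReLU; the last purely linear)
into an embedding.  Verification compares two embeddings by their cosine
similarity c = cos(γ) ∈ [-1, 1].

Training minimizes, over a balanced batch of B labeled pairs,

    L(Θ) = (1/B) Σ_i (1 - y_i) c_i  -  λ y_i (b + c_i),

which pushes genuine pairs (y=1) toward c = 1 and impostor pairs (y=0)
toward c = -1.  λ > 0 and b ∈ [-1, 1] tilt the trade-off between false
acceptance and false rejection: b > 0 weights false rejections more, b < 0
false acceptances.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from rrverify import _nn
from rrverify.pairing import balanced_minibatches
from rrverify.types import DegenerateEmbeddingError, WindowPair

_NORM_EPS = 1e-12


@dataclass(frozen=True)
class SiameseConfig:
    """Architecture of the shared encoder branch.

    The convolution kernel defaults to one tenth of the window length
    (floored, at least 1); pooling halves the length after each of the
    three conv blocks, so n_beats must survive three pool-by-2 stages.
    """

    n_beats: int
    conv_channels: Tuple[int, int, int] = (16, 32, 64)
    kernel_size: Optional[int] = None  # default: max(1, n_beats // 10)
    pool_size: int = 2
    linear_dims: Tuple[int, int, int] = (128, 64, 32)
    dropout_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.n_beats < 2:
            raise ValueError("n_beats must be at least 2")
        if self.kernel_size is not None and self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        if len(self.conv_channels) != 3 or len(self.linear_dims) != 3:
            raise ValueError("expect three conv channel counts and three linear dims")
        if self.embedding_dim < 2:
            raise ValueError("embedding dimension must be >= 2")
        if self._pooled_length() < 1:
            raise ValueError(
                f"n_beats={self.n_beats} is too short for three pool-by-{self.pool_size} stages"
            )

    @property
    def effective_kernel(self) -> int:
        if self.kernel_size is not None:
            return self.kernel_size
        return max(1, self.n_beats // 10)

    @property
    def embedding_dim(self) -> int:
        return self.linear_dims[-1]

    def _pooled_length(self) -> int:
        length = self.n_beats
        for _ in range(3):
            length //= self.pool_size
        return length

    @property
    def flat_features(self) -> int:
        return self.conv_channels[-1] * self._pooled_length()


@dataclass(frozen=True)
class LossParams:
    """λ and b of the contrastive cosine loss."""

    lam: float = 1.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if not (-1.0 <= self.b <= 1.0):
            raise ValueError("b must lie in [-1, 1]")


@dataclass(frozen=True)
class TrainHyperparams:
    """Optimization settings (tuned per condition in practice)."""

    batch_size: int = 32
    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    epochs: int = 15
    seed: int = 0


class SiameseEncoder:
    """The shared branch f(.;Θ); both pair members pass through this object,
    so weight sharing holds by construction."""

    def __init__(self, config: SiameseConfig, rng: np.random.Generator) -> None:
        self.config = config
        k = config.effective_kernel
        layers: List[_nn.Layer] = []
        in_ch = 1
        for out_ch in config.conv_channels:
            layers.append(_nn.Conv1d(in_ch, out_ch, k, rng))
            layers.append(_nn.BatchNorm(out_ch))
            layers.append(_nn.MaxPool1d(config.pool_size))
            layers.append(_nn.ReLU())
            in_ch = out_ch
        layers.append(_nn.Flatten())
        in_f = config.flat_features
        d1, d2, d_emb = config.linear_dims
        for out_f in (d1, d2):
            layers.append(_nn.Dropout(config.dropout_rate, rng))
            layers.append(_nn.Linear(in_f, out_f, rng))
            layers.append(_nn.BatchNorm(out_f))
            layers.append(_nn.ReLU())
            in_f = out_f
        layers.append(_nn.Linear(in_f, d_emb, rng))  # final layer purely linear
        self.net = _nn.Sequential(layers)

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Embed a (batch, n_beats) matrix of RR windows."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.config.n_beats:
            raise ValueError(
                f"input length {x.shape[1]} does not match n_beats={self.config.n_beats}"
            )
        return self.net.forward(x[:, None, :], train)

    def backward(self, d_emb: np.ndarray) -> np.ndarray:
        return self.net.backward(d_emb)

    # -- parameter state ---------------------------------------------------
    def state_arrays(self) -> List[np.ndarray]:
        arrays = list(self.net.parameters())
        for layer in self.net.layers:
            if isinstance(layer, _nn.BatchNorm):
                arrays.extend([layer.running_mean, layer.running_var])
        return arrays

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError("checkpoint does not match this architecture")
        for dst, src in zip(own, arrays):
            dst[...] = np.asarray(src)


@dataclass
class TrainedModel:
    """Encoder plus its training provenance."""

    config: SiameseConfig
    encoder: SiameseEncoder
    loss_params: LossParams
    seed: int
    epochs_run: int
    loss_history: List[float] = field(default_factory=list)

    @property
    def final_loss(self) -> Optional[float]:
        return self.loss_history[-1] if self.loss_history else None


def build_encoder(config: SiameseConfig, seed: int = 0) -> SiameseEncoder:
    """Instantiate the encoder with seeded He-initialized weights."""
    return SiameseEncoder(config, np.random.default_rng(seed))


def cosine_similarity(e1: np.ndarray, e2: np.ndarray) -> float:
    """Normalized inner product of two embeddings, cos(γ) ∈ [-1, 1]."""
    e1 = np.asarray(e1, dtype=float).ravel()
    e2 = np.asarray(e2, dtype=float).ravel()
    n1 = float(np.linalg.norm(e1))
    n2 = float(np.linalg.norm(e2))
    if n1 < _NORM_EPS or n2 < _NORM_EPS:
        raise DegenerateEmbeddingError("cosine similarity undefined for zero-norm embedding")
    return float(np.clip(np.dot(e1, e2) / (n1 * n2), -1.0, 1.0))


def _batch_cosine(E1: np.ndarray, E2: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    n1 = np.linalg.norm(E1, axis=1)
    n2 = np.linalg.norm(E2, axis=1)
    if np.any(n1 < _NORM_EPS) or np.any(n2 < _NORM_EPS):
        raise DegenerateEmbeddingError("zero-norm embedding in batch")
    c = np.einsum("bd,bd->b", E1, E2) / (n1 * n2)
    return c, n1, n2


def contrastive_cosine_loss(
    batch: Sequence[Tuple[np.ndarray, np.ndarray, int]],
    params: LossParams = LossParams(),
) -> float:
    """Mean over B pairs of (1 - y)·c - λ·y·(b + c)."""
    if not batch:
        raise ValueError("batch must be non-empty")
    total = 0.0
    for e1, e2, y in batch:
        c = cosine_similarity(e1, e2)
        total += (1 - y) * c - params.lam * y * (params.b + c)
    return total / len(batch)


def _loss_and_grads(
    E1: np.ndarray, E2: np.ndarray, y: np.ndarray, params: LossParams
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Batched loss with analytic gradients w.r.t. both embedding matrices."""
    B = E1.shape[0]
    c, n1, n2 = _batch_cosine(E1, E2)
    loss = float(np.mean((1 - y) * c - params.lam * y * (params.b + c)))
    dc = ((1 - y) - params.lam * y) / B  # dL/dc_i
    # dc/dE1 = E2/(|E1||E2|) - c E1/|E1|^2  (and symmetrically for E2)
    inv12 = 1.0 / (n1 * n2)
    dE1 = dc[:, None] * (E2 * inv12[:, None] - E1 * (c / n1**2)[:, None])
    dE2 = dc[:, None] * (E1 * inv12[:, None] - E2 * (c / n2**2)[:, None])
    return loss, dE1, dE2


def score_pair(model: TrainedModel, pair: WindowPair) -> float:
    """Similarity score c(f(x1), f(x2)) for one window pair (eval mode)."""
    if pair.first.n_beats != model.config.n_beats:
        raise ValueError("pair window length does not match the model's n_beats")
    E = model.encoder(np.stack([pair.first.intervals, pair.second.intervals]), train=False)
    return cosine_similarity(E[0], E[1])


def score_pairs(model: TrainedModel, pairs: Sequence[WindowPair]) -> np.ndarray:
    """Vectorized scoring of many pairs; returns one score per pair."""
    if not pairs:
        return np.empty(0)
    for p in pairs:
        if p.first.n_beats != model.config.n_beats:
            raise ValueError("pair window length does not match the model's n_beats")
    X1 = np.stack([p.first.intervals for p in pairs])
    X2 = np.stack([p.second.intervals for p in pairs])
    E1 = model.encoder(X1, train=False)
    E2 = model.encoder(X2, train=False)
    c, _, _ = _batch_cosine(E1, E2)
    return np.clip(c, -1.0, 1.0)


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


def train(
    model_config: SiameseConfig,
    loss_params: LossParams,
    pairs: Sequence[WindowPair],
    hyperparams: TrainHyperparams = TrainHyperparams(),
) -> TrainedModel:
    """Train the Siamese encoder by SGD on balanced minibatches.

    Each batch's 2B windows pass through the shared encoder in a single
    forward (so batch normalization sees both pair members); gradients flow
    back from the contrastive cosine loss through both branches and are
    summed into the shared parameters.  ``epochs=0`` returns the freshly
    initialized model untouched.
    """
    rng = np.random.default_rng(hyperparams.seed)
    encoder = build_encoder(model_config, seed=hyperparams.seed)
    opt = _nn.SGD(
        encoder.net.parameters(),
        encoder.net.gradients(),
        lr=hyperparams.learning_rate,
        momentum=hyperparams.momentum,
        weight_decay=hyperparams.weight_decay,
    )
    history: List[float] = []
    for epoch in range(hyperparams.epochs):
        epoch_losses: List[float] = []
        for batch in balanced_minibatches(pairs, hyperparams.batch_size, rng):
            X1 = np.stack([p.first.intervals for p in batch])
            X2 = np.stack([p.second.intervals for p in batch])
            y = np.array([p.y for p in batch], dtype=float)
            B = len(batch)
            E = encoder(np.concatenate([X1, X2]), train=True)
            loss, dE1, dE2 = _loss_and_grads(E[:B], E[B:], y, loss_params)
            if not math.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}; reduce the learning rate"
                )
            encoder.net.zero_grad()
            encoder.backward(np.concatenate([dE1, dE2]))
            opt.step()
            epoch_losses.append(loss)
        history.append(float(np.mean(epoch_losses)))
    return TrainedModel(
        config=model_config,
        encoder=encoder,
        loss_params=loss_params,
        seed=hyperparams.seed,
        epochs_run=hyperparams.epochs,
        loss_history=history,
    )


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(model: TrainedModel, path: str) -> None:
    """Persist config, loss params, Θ and provenance to a .npz checkpoint."""
    meta = {
        "config": asdict(model.config),
        "loss_params": asdict(model.loss_params),
        "seed": model.seed,
        "epochs_run": model.epochs_run,
        "loss_history": model.loss_history,
    }
    arrays = {f"arr_{i}": a for i, a in enumerate(model.encoder.state_arrays())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str) -> TrainedModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        arrays = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
    cfg_d = meta["config"]
    cfg_d["conv_channels"] = tuple(cfg_d["conv_channels"])
    cfg_d["linear_dims"] = tuple(cfg_d["linear_dims"])
    config = SiameseConfig(**cfg_d)
    encoder = build_encoder(config, seed=int(meta["seed"]))
    encoder.load_state_arrays(arrays)
    return TrainedModel(
        config=config,
        encoder=encoder,
        loss_params=LossParams(**meta["loss_params"]),
        seed=int(meta["seed"]),
        epochs_run=int(meta["epochs_run"]),
        loss_history=list(meta["loss_history"]),
    )
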