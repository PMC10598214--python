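"""Per-position interface classifier.

A four-weight-layer fully connected head (three hidden layers plus a
sigmoid output) is applied independently at every residue position of a
backend embedding and trained with masked, per-sequence-weighted binary
cross entropy:

    L = w * mean_{i in mask} -( y_i log p_i + (1 - y_i) log(1 - p_i) )

where p_i is the predicted probability that residue i belongs to a
binding interface.  Training is minibatch Adam with early stopping on
validation loss and best-checkpoint restore; with the backend's
``trainable_last_k > 0`` its final blocks fine-tune jointly with the
head, otherwise the backend stays frozen.  Everything is seeded and
reproducible.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset import LabeledSequence
from .embedder import (
    EmbeddingBackend,
    OneHotContextBackend,
    TinyTransformerBackend,
    load_backend,
)
from .seqio import ProteinSequence, ScoreTrack

logger = logging.getLogger("pepprior")

EPS = 1e-7  # probability clamp inside the loss


@dataclass
class HeadConfig:
    """Three hidden layer widths plus the implicit 1-unit sigmoid output."""

    hidden_sizes: tuple[int, int, int] = (256, 128, 64)
    activation: str = "relu"

    def __post_init__(self) -> None:
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if len(self.hidden_sizes) != 3 or any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be three positive integers")
        if self.activation not in ("relu", "gelu"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-3
    batch_size: int = 8
    max_epochs: int = 50
    patience: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("learning_rate, batch_size, max_epochs must be positive")
        if self.patience < 1:
            raise ValueError("patience must be positive")


@dataclass
class TrainReport:
    train_losses: list[float]
    val_losses: list[float]
    best_epoch: int  # 1-based
    stop_reason: str


@dataclass
class PredictionTrack:
    """Per-position interface probabilities p for one sequence."""

    sequence_id: str
    p: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.mask is None:
            self.mask = np.ones(len(self.p), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)

    def as_score_track(self) -> ScoreTrack:
        return ScoreTrack(self.sequence_id, self.p, kind="probability")


def bce_loss(
    p: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray | None = None,
    weight: float = 1.0,
) -> float:
    """Masked, weighted binary cross entropy, averaged over valid positions.

    Probabilities are clamped to [EPS, 1-EPS]; inputs outside [0, 1]
    pre-clamp are a contract violation.  An all-masked input yields 0.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1] before clamping")
    if weight <= 0:
        raise ValueError("weight must be positive")
    if mask is None:
        mask = np.ones(len(p), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    pc = np.clip(p[mask], EPS, 1.0 - EPS)
    ym = y[mask]
    return float(weight * np.mean(-(ym * np.log(pc) + (1 - ym) * np.log(1 - pc))))


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + np.tanh(np.sqrt(2 / np.pi) * (x + 0.044715 * x**3)))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    t = np.tanh(np.sqrt(2 / np.pi) * (x + 0.044715 * x**3))
    dt = (1 - t**2) * np.sqrt(2 / np.pi) * (1 + 3 * 0.044715 * x**2)
    return 0.5 * (1 + t) + 0.5 * x * dt


class MLPHead:
    """Position-wise MLP: input_dim -> h1 -> h2 -> h3 -> 1 (sigmoid)."""

    def __init__(self, input_dim: int, config: HeadConfig | None = None, seed: int = 0):
        self.config = config or HeadConfig()
        self.input_dim = input_dim
        rng = np.random.default_rng(seed)
        sizes = [input_dim, *self.config.hidden_sizes, 1]
        self.weights = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), (sizes[i], sizes[i + 1]))
            for i in range(4)
        ]
        self.biases = [np.zeros(sizes[i + 1]) for i in range(4)]

    def _act(self, x: np.ndarray) -> np.ndarray:
        return np.maximum(x, 0.0) if self.config.activation == "relu" else _gelu(x)

    def _act_grad(self, x: np.ndarray) -> np.ndarray:
        return (x > 0).astype(float) if self.config.activation == "relu" else _gelu_grad(x)

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list]:
        """Return per-position probabilities and a backprop cache."""
        cache = []
        h = X
        for i in range(3):
            z = h @ self.weights[i] + self.biases[i]
            cache.append((h, z))
            h = self._act(z)
        logits = (h @ self.weights[3] + self.biases[3]).ravel()
        cache.append((h, logits))
        p = 1.0 / (1.0 + np.exp(-logits))
        return p, cache

    def backward(self, cache: list, d_logits: np.ndarray):
        """Backprop a per-position logit gradient.

        Returns (weight grads, bias grads, gradient w.r.t. the input
        embedding) — the latter feeds backend fine-tuning.
        """
        gw = [None] * 4
        gb = [None] * 4
        h3 = cache[3][0]
        d = d_logits[:, None]
        gw[3] = h3.T @ d
        gb[3] = d.sum(axis=0)
        dh = d @ self.weights[3].T
        for i in range(2, -1, -1):
            h_in, z = cache[i]
            dz = dh * self._act_grad(z)
            gw[i] = h_in.T @ dz
            gb[i] = dz.sum(axis=0)
            dh = dz @ self.weights[i].T
        return gw, gb, dh

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for i in range(4):
            out[f"W{i}"] = self.weights[i]
            out[f"b{i}"] = self.biases[i]
        return out

    def load_parameters(self, params: dict[str, np.ndarray]) -> None:
        for i in range(4):
            self.weights[i] = np.asarray(params[f"W{i}"])
            self.biases[i] = np.asarray(params[f"b{i}"])


class InterfaceModel:
    """Backend + head bundle with prediction and checkpointing."""

    def __init__(self, backend: EmbeddingBackend, head: MLPHead):
        if head.input_dim != backend.dim:
            raise ValueError(
                f"head input dim {head.input_dim} != backend dim {backend.dim}"
            )
        self.backend = backend
        self.head = head

    def predict(self, sequence: ProteinSequence) -> PredictionTrack:
        X = self.backend.embed(sequence)
        p, _ = self.head.forward(X)
        return PredictionTrack(sequence.id, p)

    def predict_many(self, sequences: Sequence[ProteinSequence]) -> list[PredictionTrack]:
        return [self.predict(s) for s in sequences]

    # -- checkpointing --------------------------------------------------

    def save(self, path: str | Path, meta: dict | None = None) -> None:
        arrays = {f"head.{k}": v for k, v in self.head.parameters().items()}
        arrays.update({f"backend.{k}": v for k, v in self.backend.state().items()})
        backend_cfg: dict = {"kind": self.backend.name}
        if isinstance(self.backend, OneHotContextBackend):
            backend_cfg["radius"] = self.backend.radius
        elif isinstance(self.backend, TinyTransformerBackend):
            backend_cfg.update(
                dim=self.backend.dim,
                n_blocks=self.backend.n_blocks,
                ffn_dim=self.backend.ffn_dim,
                seed=self.backend.seed,
                trainable_last_k=self.backend.trainable_last_k,
            )
        config = {
            "backend": backend_cfg,
            "head": {"input_dim": self.head.input_dim, **asdict(self.head.config)},
            "meta": meta or {},
        }
        np.savez(path, __config__=np.frombuffer(json.dumps(config).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "InterfaceModel":
        data = np.load(path)
        config = json.loads(bytes(data["__config__"]).decode())
        bc = dict(config["backend"])
        kind = bc.pop("kind")
        backend = load_backend(kind, **bc)
        backend.load_state(
            {k.removeprefix("backend."): data[k] for k in data.files if k.startswith("backend.")}
        )
        hc = config["head"]
        head = MLPHead(hc["input_dim"], HeadConfig(tuple(hc["hidden_sizes"]), hc["activation"]))
        head.load_parameters(
            {k.removeprefix("head."): data[k] for k in data.files if k.startswith("head.")}
        )
        return cls(backend, head)


class EarlyStopping:
    """Stop when validation loss fails to improve ``patience`` epochs running.

    ``update`` is called once per completed epoch with that epoch's
    validation loss and returns True when training should stop.  The
    best epoch is the argmin of validation losses seen so far.
    """

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be positive")
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = 0  # 1-based
        self.epochs_since_best = 0
        self.epoch = 0

    def update(self, val_loss: float) -> bool:
        self.epoch += 1
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = self.epoch
            self.epochs_since_best = 0
        else:
            self.epochs_since_best += 1
        return self.epochs_since_best >= self.patience


class _Adam:
    def __init__(self, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for key, g in grads.items():
            if key not in self.m:
                self.m[key] = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1**self.t)
            vhat = self.v[key] / (1 - self.b2**self.t)
            params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _sequence_loss_and_grads(
    model: InterfaceModel, ls: LabeledSequence, want_grads: bool
):
    """Loss (and gradients) for one labelled sequence.

    Uses the sigmoid-BCE identity d(loss)/d(logit) = (p - y) scaled by
    weight / n_unmasked, matching the mean-over-positions loss.
    """
    seq = ProteinSequence(ls.sequence_id, ls.residues)
    backend_trainable = want_grads and model.backend.trainable_last_k > 0
    if backend_trainable:
        X, bcache = model.backend.forward(seq)
    else:
        X = model.backend.embed(seq)
        bcache = None
    p, hcache = model.head.forward(X)
    loss = bce_loss(p, ls.labels, ls.mask, ls.weight)
    if not want_grads:
        return loss, None
    n_valid = int(ls.mask.sum())
    d_logits = np.zeros_like(p)
    if n_valid > 0:
        y = ls.labels.astype(float)
        pc = np.clip(p, EPS, 1.0 - EPS)
        d_logits[ls.mask] = ls.weight * (pc[ls.mask] - y[ls.mask]) / n_valid
    gw, gb, dX = model.head.backward(hcache, d_logits)
    grads = {f"head.W{i}": gw[i] for i in range(4)}
    grads.update({f"head.b{i}": gb[i] for i in range(4)})
    if backend_trainable:
        for k, g in model.backend.backward(bcache, dX).items():
            grads[f"backend.{k}"] = g
    return loss, grads


def dataset_loss(model: InterfaceModel, data: Sequence[LabeledSequence]) -> float:
    """Mean per-sequence weighted BCE over a dataset."""
    return float(np.mean([_sequence_loss_and_grads(model, ls, False)[0] for ls in data]))


def train(
    backend: EmbeddingBackend,
    head_config: HeadConfig | None,
    train_set: Sequence[LabeledSequence],
    val_set: Sequence[LabeledSequence],
    cfg: TrainingConfig | None = None,
) -> tuple[InterfaceModel, TrainReport]:
    """Fit the head (and any trainable backend blocks) on labelled data.

    Minibatch Adam on the masked weighted BCE; after each epoch the
    validation loss is computed and early stopping with best-checkpoint
    restore is applied.  Fully reproducible given ``cfg.seed``.
    """
    cfg = cfg or TrainingConfig()
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be nonempty")
    train_ids = {ls.sequence_id for ls in train_set}
    overlap = train_ids & {ls.sequence_id for ls in val_set}
    if overlap:
        raise ValueError(f"train/val ids overlap: {sorted(overlap)[:5]}")
    if not any(ls.mask.any() for ls in train_set):
        raise ValueError("all training positions are masked")

    rng = np.random.default_rng(cfg.seed)
    head = MLPHead(backend.dim, head_config, seed=int(rng.integers(2**31)))
    model = InterfaceModel(backend, head)
    optimizer = _Adam(cfg.learning_rate)
    stopper = EarlyStopping(cfg.patience)

    def all_params() -> dict[str, np.ndarray]:
        params = {f"head.{k}": v for k, v in head.parameters().items()}
        params.update(
            {f"backend.{k}": v for k, v in backend.trainable_parameters().items()}
        )
        return params

    def snapshot() -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in all_params().items()}

    def restore(snap: dict[str, np.ndarray]) -> None:
        head.load_parameters(
            {k.removeprefix("head."): v for k, v in snap.items() if k.startswith("head.")}
        )
        for k, v in snap.items():
            if k.startswith("backend."):
                backend._set_parameter(k.removeprefix("backend."), v.copy())  # type: ignore[attr-defined]

    train_losses: list[float] = []
    val_losses: list[float] = []
    best_snap = snapshot()
    stop_reason = "max_epochs"
    order = np.arange(len(train_set))
    for epoch in range(1, cfg.max_epochs + 1):
        rng.shuffle(order)
        epoch_losses = []
        for lo in range(0, len(order), cfg.batch_size):
            batch = [train_set[i] for i in order[lo : lo + cfg.batch_size]]
            batch_grads: dict[str, np.ndarray] = {}
            for ls in batch:
                loss, grads = _sequence_loss_and_grads(model, ls, True)
                epoch_losses.append(loss)
                for k, g in grads.items():
                    if k in batch_grads:
                        batch_grads[k] += g
                    else:
                        batch_grads[k] = g.copy()
            for k in batch_grads:
                batch_grads[k] /= len(batch)
            params = all_params()
            optimizer.step(params, batch_grads)
            head.load_parameters(
                {k.removeprefix("head."): v for k, v in params.items() if k.startswith("head.")}
            )
            # backend params are updated in place by the optimizer

        train_losses.append(float(np.mean(epoch_losses)))
        val_loss = dataset_loss(model, val_set)
        val_losses.append(val_loss)
        logger.info(
            "epoch %d: train loss %.4f, val loss %.4f", epoch, train_losses[-1], val_loss
        )
        if val_loss < stopper.best_loss:
            best_snap = snapshot()
        if stopper.update(val_loss):
            stop_reason = "early_stop"
            break

    restore(best_snap)
    report = TrainReport(train_losses, val_losses, stopper.best_epoch, stop_reason)
    return model, report
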