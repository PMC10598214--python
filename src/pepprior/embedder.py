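"""Per-residue embedding backends.

The interface classifier consumes one real vector per residue.  In
production such vectors come from a pretrained protein language model
whose final few blocks may be fine-tuned together with the head; here
two self-contained backends implement the same contract so the whole
pipeline is trainable and testable at desk scale:

``onehot``
    One-hot residue encodings concatenated over a symmetric context
    window of radius ``r`` (dim = 21*(2r+1)); parameter-free, linear
    time, deterministic.

``tinytransformer``
    A small single-head self-attention encoder with seeded random
    initialisation.  Its last ``trainable_last_k`` blocks participate in
    fine-tuning; with ``trainable_last_k = 0`` the backend is frozen and
    its outputs are bit-identical before and after any training run.

A pretrained model is plugged in via ``plugin:<module>:<factory>`` and
must satisfy the same contract; no core functionality requires it.
"""

from __future__ import annotations

import importlib
from typing import Any

import numpy as np

from .seqio import ALPHABET, ProteinSequence

_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
N_SYMBOLS = len(ALPHABET)  # 21


def tokenize(sequence: ProteinSequence) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in sequence.residues], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - ProteinSequence already validates
        raise ValueError(f"unknown residue symbol {exc.args[0]!r}") from exc


def one_hot(sequence: ProteinSequence) -> np.ndarray:
    """(n, 21) one-hot matrix over the amino-acid alphabet plus X."""
    tokens = tokenize(sequence)
    mat = np.zeros((len(tokens), N_SYMBOLS))
    mat[np.arange(len(tokens)), tokens] = 1.0
    return mat


class EmbeddingBackend:
    """Contract shared by all backends.

    ``embed`` maps a sequence to an (n, dim) matrix, deterministically
    for fixed parameters.  ``n_blocks`` counts the fine-tunable blocks;
    ``set_trainable(k)`` marks exactly the final ``k`` of them as
    trainable.  Backends without parameters have zero blocks.
    """

    name: str = "base"
    dim: int = 0
    n_blocks: int = 0
    trainable_last_k: int = 0

    def embed(self, sequence: ProteinSequence) -> np.ndarray:
        raise NotImplementedError

    def set_trainable(self, last_k: int) -> "EmbeddingBackend":
        if last_k < 0:
            raise ValueError("last_k must be nonnegative")
        if last_k > self.n_blocks:
            raise ValueError(
                f"last_k={last_k} exceeds backend block count {self.n_blocks}"
            )
        self.trainable_last_k = last_k
        return self

    # -- fine-tuning hooks; parameter-free backends use the defaults --

    def trainable_parameters(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of the parameters that fine-tune."""
        return {}

    def forward(self, sequence: ProteinSequence) -> tuple[np.ndarray, Any]:
        """Embed with a cache for a later backward pass."""
        return self.embed(sequence), None

    def backward(self, cache: Any, d_out: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. trainable parameters."""
        return {}

    def state(self) -> dict[str, np.ndarray]:
        return {}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        if state:
            raise ValueError(f"backend {self.name!r} carries no parameters")


class OneHotContextBackend(EmbeddingBackend):
    """Concatenated one-hot encodings over a +/- r residue window.

    Boundary positions are padded with all-zero context blocks, so the
    embedding of a residue depends only on residues within radius r.
    """

    name = "onehot"
    n_blocks = 0

    def __init__(self, radius: int = 7) -> None:
        if radius < 0:
            raise ValueError("radius must be nonnegative")
        self.radius = radius
        self.dim = N_SYMBOLS * (2 * radius + 1)

    def embed(self, sequence: ProteinSequence) -> np.ndarray:
        base = one_hot(sequence)
        n = len(sequence)
        blocks = []
        for offset in range(-self.radius, self.radius + 1):
            shifted = np.zeros_like(base)
            if offset >= 0:
                shifted[: n - offset] = base[offset:]
            else:
                shifted[-offset:] = base[: n + offset]
            blocks.append(shifted)
        return np.concatenate(blocks, axis=1)


def _positional_encoding(n: int, dim: int) -> np.ndarray:
    pos = np.arange(n)[:, None]
    i = np.arange(dim // 2)[None, :]
    angles = pos / (10000.0 ** (2 * i / dim))
    enc = np.zeros((n, dim))
    enc[:, 0::2] = np.sin(angles)
    enc[:, 1::2] = np.cos(angles[:, : dim - dim // 2])
    return enc


class TinyTransformerBackend(EmbeddingBackend):
    """A small self-attention encoder with fine-tunable final blocks.

    Each block is single-head scaled dot-product attention followed by a
    position-wise two-layer feed-forward net, both with residual
    connections (no layer norm; initial weights are scaled small enough
    that activations stay well-conditioned at this depth).  Gradients
    flow only through the last ``trainable_last_k`` blocks, mirroring
    partial fine-tuning of a pretrained language model.
    """

    name = "tinytransformer"

    def __init__(
        self,
        dim: int = 32,
        n_blocks: int = 4,
        ffn_dim: int | None = None,
        seed: int = 0,
        trainable_last_k: int = 0,
    ) -> None:
        if dim % 2 != 0:
            raise ValueError("dim must be even (sinusoidal positional encoding)")
        self.dim = dim
        self.n_blocks = n_blocks
        self.ffn_dim = ffn_dim or 2 * dim
        self.seed = seed
        rng = np.random.default_rng(seed)
        scale = 1.0 / np.sqrt(dim)
        self.token_embedding = rng.normal(0.0, scale, (N_SYMBOLS, dim))
        self.blocks: list[dict[str, np.ndarray]] = []
        for _ in range(n_blocks):
            self.blocks.append(
                {
                    "Wq": rng.normal(0.0, scale, (dim, dim)),
                    "Wk": rng.normal(0.0, scale, (dim, dim)),
                    "Wv": rng.normal(0.0, scale, (dim, dim)),
                    "Wo": rng.normal(0.0, scale, (dim, dim)),
                    "W1": rng.normal(0.0, scale, (dim, self.ffn_dim)),
                    "b1": np.zeros(self.ffn_dim),
                    "W2": rng.normal(0.0, scale, (self.ffn_dim, dim)),
                    "b2": np.zeros(dim),
                }
            )
        self.set_trainable(trainable_last_k)

    # -- forward --------------------------------------------------------

    def _block_forward(self, X: np.ndarray, P: dict[str, np.ndarray]):
        d = self.dim
        Q, K, V = X @ P["Wq"], X @ P["Wk"], X @ P["Wv"]
        S = Q @ K.T / np.sqrt(d)
        S -= S.max(axis=1, keepdims=True)
        E = np.exp(S)
        A = E / E.sum(axis=1, keepdims=True)
        H = A @ V
        X1 = X + H @ P["Wo"]
        Zpre = X1 @ P["W1"] + P["b1"]
        Z = np.maximum(Zpre, 0.0)
        X2 = X1 + Z @ P["W2"] + P["b2"]
        cache = {"X": X, "Q": Q, "K": K, "V": V, "A": A, "H": H, "X1": X1, "Z": Z}
        return X2, cache

    def forward(self, sequence: ProteinSequence) -> tuple[np.ndarray, Any]:
        tokens = tokenize(sequence)
        X = self.token_embedding[tokens] + _positional_encoding(len(tokens), self.dim)
        caches = []
        first_trainable = self.n_blocks - self.trainable_last_k
        for b, P in enumerate(self.blocks):
            X, cache = self._block_forward(X, P)
            caches.append(cache if b >= first_trainable else None)
        return X, caches

    def embed(self, sequence: ProteinSequence) -> np.ndarray:
        out, _ = self.forward(sequence)
        return out

    # -- backward -------------------------------------------------------

    def _block_backward(self, P, cache, dX2):
        d = self.dim
        grads = {}
        dX1 = dX2.copy()
        grads["W2"] = cache["Z"].T @ dX2
        grads["b2"] = dX2.sum(axis=0)
        dZ = dX2 @ P["W2"].T
        dZpre = dZ * (cache["Z"] > 0)
        grads["W1"] = cache["X1"].T @ dZpre
        grads["b1"] = dZpre.sum(axis=0)
        dX1 += dZpre @ P["W1"].T

        dX = dX1.copy()
        dHWo = dX1
        grads["Wo"] = cache["H"].T @ dHWo
        dH = dHWo @ P["Wo"].T
        dA = dH @ cache["V"].T
        dV = cache["A"].T @ dH
        A = cache["A"]
        dS = A * (dA - (dA * A).sum(axis=1, keepdims=True))
        dQ = dS @ cache["K"] / np.sqrt(d)
        dK = dS.T @ cache["Q"] / np.sqrt(d)
        grads["Wq"] = cache["X"].T @ dQ
        grads["Wk"] = cache["X"].T @ dK
        grads["Wv"] = cache["X"].T @ dV
        dX += dQ @ P["Wq"].T + dK @ P["Wk"].T + dV @ P["Wv"].T
        return grads, dX

    def backward(self, caches: Any, d_out: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        first_trainable = self.n_blocks - self.trainable_last_k
        dX = d_out
        for b in range(self.n_blocks - 1, first_trainable - 1, -1):
            block_grads, dX = self._block_backward(self.blocks[b], caches[b], dX)
            for name, g in block_grads.items():
                grads[f"block{b}.{name}"] = g
        return grads

    # -- parameter plumbing --------------------------------------------

    def trainable_parameters(self) -> dict[str, np.ndarray]:
        first_trainable = self.n_blocks - self.trainable_last_k
        out = {}
        for b in range(first_trainable, self.n_blocks):
            for name, arr in self.blocks[b].items():
                out[f"block{b}.{name}"] = arr
        return out

    def _set_parameter(self, key: str, value: np.ndarray) -> None:
        block, name = key.split(".")
        self.blocks[int(block.removeprefix("block"))][name] = value

    def state(self) -> dict[str, np.ndarray]:
        out = {"token_embedding": self.token_embedding}
        for b, P in enumerate(self.blocks):
            for name, arr in P.items():
                out[f"block{b}.{name}"] = arr
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        self.token_embedding = np.asarray(state["token_embedding"])
        for key, value in state.items():
            if key.startswith("block"):
                self._set_parameter(key, np.asarray(value))


def load_backend(spec: str, **kwargs: Any) -> EmbeddingBackend:
    """Instantiate a backend from a config key.

    ``onehot`` and ``tinytransformer`` are built in;
    ``plugin:<module>:<factory>`` imports ``<factory>`` from
    ``<module>`` and calls it with the remaining keyword arguments —
    the hook for a pretrained language-model adapter.
    """
    if spec == "onehot":
        return OneHotContextBackend(**kwargs)
    if spec == "tinytransformer":
        return TinyTransformerBackend(**kwargs)
    if spec.startswith("plugin:"):
        try:
            _, module_path, factory_name = spec.split(":")
        except ValueError as exc:
            raise ValueError(
                f"plugin spec must be 'plugin:<module>:<factory>', got {spec!r}"
            ) from exc
        module = importlib.import_module(module_path)
        backend = getattr(module, factory_name)(**kwargs)
        if not isinstance(backend, EmbeddingBackend):
            raise TypeError(f"plugin {spec!r} did not return an EmbeddingBackend")
        return backend
    raise ValueError(f"unknown backend spec {spec!r}")
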