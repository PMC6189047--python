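"""Bidirectional GRU classifier for k-mer index sequences.

One GRU direction carries a hidden state h_t of ``units`` dimensions across
the k-mer sequence. Per step, with x_t the embedded k-mer:

    z_t = sigmoid(W_z x_t + U_z h_{t-1} + b_z)        (update gate)
    r_t = sigmoid(W_r x_t + U_r h_{t-1} + b_r)        (reset gate)
    m_t = tanh(W_h x_t + U_h (r_t * h_{t-1}) + b_h)   (candidate state)
    h_t = (1 - z_t) * h_{t-1} + z_t * m_t

with ``*`` element-wise and h_0 = 0. A forward layer consumes steps 1..N and
a backward layer consumes N..1; their final states are merged (concatenate /
sum / average / multiplication) and a dense layer plus logistic sigmoid maps
the merged vector to P(bound). Training minimizes the negative Bernoulli
log-likelihood

    phi = - sum_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ].

Everything here is plain NumPy: the forward pass caches gate activations and
the backward pass implements backpropagation through time exactly on the
equations above, including pass-through behaviour at masked (padding) steps,
so variable-length sequences batched with right padding give identical
results to unpadded ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .embedding import EmbeddingLayer
from .tokenizer import PAD_INDEX

MERGE_MODES = ("concatenate", "sum", "average", "multiplication")
LOSS_EPS = 1e-7


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _orthogonal(n: int, rng: np.random.Generator) -> np.ndarray:
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))  # fix sign so the factorization is unique


def _glorot_uniform(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape)


@dataclass
class GRUCellParams:
    """The nine tensors of one GRU direction.

    W_* are units x d input transforms, U_* are units x units recurrent
    transforms, b_* are length-units biases, for the update gate (z), reset
    gate (r) and candidate state (h).
    """

    W_z: np.ndarray
    U_z: np.ndarray
    b_z: np.ndarray
    W_r: np.ndarray
    U_r: np.ndarray
    b_r: np.ndarray
    W_h: np.ndarray
    U_h: np.ndarray
    b_h: np.ndarray

    def __post_init__(self) -> None:
        units, d = self.W_z.shape
        expect = {
            "W_z": (units, d), "W_r": (units, d), "W_h": (units, d),
            "U_z": (units, units), "U_r": (units, units), "U_h": (units, units),
            "b_z": (units,), "b_r": (units,), "b_h": (units,),
        }
        for name, shape in expect.items():
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")
            setattr(self, name, arr)

    @property
    def units(self) -> int:
        return self.W_z.shape[0]

    @property
    def d(self) -> int:
        return self.W_z.shape[1]

    @classmethod
    def initialize(cls, units: int, d: int, rng: np.random.Generator) -> "GRUCellParams":
        """Uniform (Glorot) input transforms, orthogonal recurrent, zero bias."""
        return cls(
            W_z=_glorot_uniform((units, d), rng), U_z=_orthogonal(units, rng),
            b_z=np.zeros(units),
            W_r=_glorot_uniform((units, d), rng), U_r=_orthogonal(units, rng),
            b_r=np.zeros(units),
            W_h=_glorot_uniform((units, d), rng), U_h=_orthogonal(units, rng),
            b_h=np.zeros(units),
        )

    def param_dict(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in
                ("W_z", "U_z", "b_z", "W_r", "U_r", "b_r", "W_h", "U_h", "b_h")}


def gru_step(
    x_t: np.ndarray, h_prev: np.ndarray, params: GRUCellParams
) -> np.ndarray:
    """One GRU recurrence on a single time step (vectors, no batch)."""
    x_t = np.asarray(x_t, dtype=np.float64)
    h_prev = np.asarray(h_prev, dtype=np.float64)
    if x_t.shape != (params.d,) or h_prev.shape != (params.units,):
        raise ValueError(
            f"expected x_t shape {(params.d,)} and h_prev shape "
            f"{(params.units,)}, got {x_t.shape} and {h_prev.shape}"
        )
    if not (np.all(np.isfinite(x_t)) and np.all(np.isfinite(h_prev))):
        raise ValueError("non-finite input to gru_step")
    z = sigmoid(params.W_z @ x_t + params.U_z @ h_prev + params.b_z)
    r = sigmoid(params.W_r @ x_t + params.U_r @ h_prev + params.b_r)
    m = np.tanh(params.W_h @ x_t + params.U_h @ (r * h_prev) + params.b_h)
    return (1.0 - z) * h_prev + z * m


# ---------------------------------------------------------------------------
# Batched forward / backward over time (the training engine)
# ---------------------------------------------------------------------------

def _gru_forward_batch(X, mask, cell, reverse):
    """Run one direction over a padded batch.

    X: (B, T, d); mask: (B, T) boolean. Masked steps leave the state
    untouched. Returns (final state (B, units), states (B, T, units) in
    storage order, cache for backprop).
    """
    B, T, _ = X.shape
    H = cell.units
    h = np.zeros((B, H))
    states = np.zeros((B, T, H))
    cache = []
    times = range(T - 1, -1, -1) if reverse else range(T)
    for t in times:
        x = X[:, t]
        z = sigmoid(x @ cell.W_z.T + h @ cell.U_z.T + cell.b_z)
        r = sigmoid(x @ cell.W_r.T + h @ cell.U_r.T + cell.b_r)
        m = np.tanh(x @ cell.W_h.T + (r * h) @ cell.U_h.T + cell.b_h)
        h_new = (1.0 - z) * h + z * m
        mt = mask[:, t][:, None]
        cache.append((t, x, h, z, r, m))
        h = np.where(mt, h_new, h)
        states[:, t] = h
    return h, states, cache


def _gru_backward_batch(dstates, dh_final, cache, cell, mask, T, d):
    """Backpropagation through time for one direction.

    dstates: (B, T, units) gradient on each stored state (may be zeros);
    dh_final: (B, units) gradient on the final state. Returns (dX, grads)
    where grads keys match GRUCellParams.param_dict().
    """
    B = dh_final.shape[0]
    grads = {k: np.zeros_like(v) for k, v in cell.param_dict().items()}
    dX = np.zeros((B, T, d))
    dh = dh_final.copy()
    for t, x, h_prev, z, r, m in reversed(cache):
        dh = dh + dstates[:, t]
        mt = mask[:, t][:, None]
        dh_upd = dh * mt          # gradient through the state update
        dh_pass = dh * (1.0 - mt)  # masked steps pass the state through
        dz = dh_upd * (m - h_prev)
        dm = dh_upd * z
        dh_prev = dh_upd * (1.0 - z)
        dm_pre = dm * (1.0 - m * m)
        grads["W_h"] += dm_pre.T @ x
        grads["U_h"] += dm_pre.T @ (r * h_prev)
        grads["b_h"] += dm_pre.sum(axis=0)
        drh = dm_pre @ cell.U_h            # grad wrt (r * h_prev)
        dr = drh * h_prev
        dh_prev = dh_prev + drh * r
        dz_pre = dz * z * (1.0 - z)
        dr_pre = dr * r * (1.0 - r)
        grads["W_z"] += dz_pre.T @ x
        grads["U_z"] += dz_pre.T @ h_prev
        grads["b_z"] += dz_pre.sum(axis=0)
        grads["W_r"] += dr_pre.T @ x
        grads["U_r"] += dr_pre.T @ h_prev
        grads["b_r"] += dr_pre.sum(axis=0)
        dh_prev = dh_prev + dz_pre @ cell.U_z + dr_pre @ cell.U_r
        dX[:, t] = dz_pre @ cell.W_z + dr_pre @ cell.W_r + dm_pre @ cell.W_h
        dh = dh_pass + dh_prev
    return dX, grads


def _merge(f: np.ndarray, b: np.ndarray, mode: str) -> np.ndarray:
    if mode == "concatenate":
        return np.concatenate([f, b], axis=-1)
    if mode == "sum":
        return f + b
    if mode == "average":
        return (f + b) / 2.0
    if mode == "multiplication":
        return f * b
    raise ValueError(f"unknown merge mode {mode!r}; choose from {MERGE_MODES}")


def _merge_backward(dout, f, b, mode):
    if mode == "concatenate":
        H = f.shape[-1]
        return dout[..., :H], dout[..., H:]
    if mode == "sum":
        return dout, dout
    if mode == "average":
        return dout / 2.0, dout / 2.0
    if mode == "multiplication":
        return dout * b, dout * f
    raise ValueError(f"unknown merge mode {mode!r}")


@dataclass
class BiGRUClassifier:
    """Embedding -> (stacked) BiGRU -> dense -> sigmoid."""

    layers: list[tuple[GRUCellParams, GRUCellParams]]  # (forward, backward)
    merge_mode: str
    head_beta: np.ndarray
    head_bias: np.ndarray  # shape (1,)
    embedding: EmbeddingLayer
    head_input: str = "final"  # or "mean_pool"

    def __post_init__(self) -> None:
        if self.merge_mode not in MERGE_MODES:
            raise ValueError(f"unknown merge mode {self.merge_mode!r}")
        if self.head_input not in ("final", "mean_pool"):
            raise ValueError(f"unknown head input {self.head_input!r}")
        if self.head_beta.shape != (self.merged_dim,):
            raise ValueError(
                f"head weight length {self.head_beta.shape} does not match "
                f"merged dimension {self.merged_dim}"
            )

    @property
    def units(self) -> int:
        return self.layers[0][0].units

    @property
    def merged_dim(self) -> int:
        u = self.layers[-1][0].units
        return 2 * u if self.merge_mode == "concatenate" else u

    @classmethod
    def initialize(
        cls,
        units: int,
        embedding: EmbeddingLayer,
        merge_mode: str = "concatenate",
        num_layers: int = 1,
        seed: int = 0,
        head_input: str = "final",
    ) -> "BiGRUClassifier":
        if num_layers < 1:
            raise ValueError("num_layers must be >= 1")
        rng = np.random.default_rng(seed)
        layers = []
        in_dim = embedding.d
        for _ in range(num_layers):
            fwd = GRUCellParams.initialize(units, in_dim, rng)
            bwd = GRUCellParams.initialize(units, in_dim, rng)
            layers.append((fwd, bwd))
            in_dim = 2 * units if merge_mode == "concatenate" else units
        merged_dim = in_dim
        beta = _glorot_uniform((1, merged_dim), rng)[0]
        return cls(
            layers=layers,
            merge_mode=merge_mode,
            head_beta=beta,
            head_bias=np.zeros(1),
            embedding=embedding,
            head_input=head_input,
        )

    # -- parameter access ---------------------------------------------------

    def param_dict(self) -> dict[str, np.ndarray]:
        """Flat name -> live array map (optimizers update these in place)."""
        params: dict[str, np.ndarray] = {}
        for li, (fwd, bwd) in enumerate(self.layers):
            for name, arr in fwd.param_dict().items():
                params[f"l{li}.f.{name}"] = arr
            for name, arr in bwd.param_dict().items():
                params[f"l{li}.b.{name}"] = arr
        params["head.beta"] = self.head_beta
        params["head.bias"] = self.head_bias
        if self.embedding.trainable:
            params["embedding"] = self.embedding.weights
        return params

    # -- forward ------------------------------------------------------------

    def _forward_batch(self, idx: np.ndarray, mask: np.ndarray, need_cache: bool):
        X = self.embedding.weights[idx]  # (B, T, d)
        caches = []
        layer_inputs = []
        for li, (fwd, bwd) in enumerate(self.layers):
            layer_inputs.append(X)
            hf, Hf, cf = _gru_forward_batch(X, mask, fwd, reverse=False)
            hb, Hb, cb = _gru_forward_batch(X, mask, bwd, reverse=True)
            if need_cache:
                caches.append((cf, cb, Hf, Hb, hf, hb))
            else:
                caches.append((None, None, Hf, Hb, hf, hb))
            if li < len(self.layers) - 1:
                X = _merge(Hf, Hb, self.merge_mode)
        _, _, Hf, Hb, hf, hb = caches[-1]
        if self.head_input == "final":
            merged = _merge(hf, hb, self.merge_mode)
        else:  # mean_pool over unmasked steps
            per_step = _merge(Hf, Hb, self.merge_mode)
            w = mask.astype(np.float64)
            denom = np.maximum(w.sum(axis=1, keepdims=True), 1.0)
            merged = (per_step * w[:, :, None]).sum(axis=1) / denom
        logit = merged @ self.head_beta + self.head_bias
        p = sigmoid(logit)
        return p, merged, caches, layer_inputs

    def predict_proba_batch(
        self, sequences: Sequence[Sequence[int]]
    ) -> np.ndarray:
        """P(bound) for a batch of index sequences (right-padded internally)."""
        idx, mask = pad_batch(sequences)
        p, _, _, _ = self._forward_batch(idx, mask, need_cache=False)
        return p

    # -- backward -----------------------------------------------------------

    def forward_backward(
        self, idx: np.ndarray, mask: np.ndarray, y: np.ndarray
    ) -> tuple[float, np.ndarray, dict[str, np.ndarray]]:
        """Mean-loss forward pass plus gradients for every trainable array.

        Returns (mean loss over the batch, predicted probabilities, flat
        gradient dict matching :meth:`param_dict`).
        """
        B, T = idx.shape
        p, merged, caches, layer_inputs = self._forward_batch(idx, mask, True)
        y = np.asarray(y, dtype=np.float64)
        pc = np.clip(p, LOSS_EPS, 1.0 - LOSS_EPS)
        mean_loss = float(-np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc)))

        grads: dict[str, np.ndarray] = {}
        dlogit = (p - y) / B  # sigmoid + Bernoulli likelihood, mean reduction
        grads["head.beta"] = merged.T @ dlogit
        grads["head.bias"] = np.array([dlogit.sum()])
        dmerged = np.outer(dlogit, self.head_beta)  # (B, merged_dim)

        # Gradient on the last layer's states.
        _, _, Hf, Hb, hf, hb = caches[-1]
        u_last = self.layers[-1][0].units
        if self.head_input == "final":
            dhf, dhb = _merge_backward(dmerged, hf, hb, self.merge_mode)
            dHf = np.zeros_like(Hf)
            dHb = np.zeros_like(Hb)
            # final forward state is stored at t = T-1, final backward at t = 0
            dHf_fin, dHb_fin = dhf, dhb
        else:
            w = mask.astype(np.float64)
            denom = np.maximum(w.sum(axis=1, keepdims=True), 1.0)
            dper = dmerged[:, None, :] * (w / denom)[:, :, None]
            dHf, dHb = _merge_backward(dper, Hf, Hb, self.merge_mode)
            dHf_fin = np.zeros((B, u_last))
            dHb_fin = np.zeros((B, u_last))

        dhf_fin, dhb_fin = dHf_fin, dHb_fin
        for li in range(len(self.layers) - 1, -1, -1):
            fwd, bwd = self.layers[li]
            cf, cb, Hf, Hb, hf, hb = caches[li]
            X = layer_inputs[li]
            d_in = X.shape[2]
            dXf, gf = _gru_backward_batch(dHf, dhf_fin, cf, fwd, mask, T, d_in)
            dXb, gb = _gru_backward_batch(dHb, dhb_fin, cb, bwd, mask, T, d_in)
            for name, arr in gf.items():
                grads[f"l{li}.f.{name}"] = arr
            for name, arr in gb.items():
                grads[f"l{li}.b.{name}"] = arr
            dX = dXf + dXb
            if li > 0:
                # dX is the gradient on the previous layer's merged per-step
                # output; split it back onto that layer's state sequences.
                _, _, Hf_prev, Hb_prev, _, _ = caches[li - 1]
                dHf, dHb = _merge_backward(dX, Hf_prev, Hb_prev, self.merge_mode)
                dhf_fin = np.zeros((B, self.layers[li - 1][0].units))
                dhb_fin = np.zeros((B, self.layers[li - 1][1].units))
            else:
                if self.embedding.trainable:
                    demb = np.zeros_like(self.embedding.weights)
                    np.add.at(demb, idx.ravel(), dX.reshape(-1, d_in))
                    demb[PAD_INDEX] = 0.0  # pad/OOV row is pinned at zero
                    grads["embedding"] = demb
        return mean_loss, p, grads

    # -- persistence --------------------------------------------------------

    def save(self, prefix: str | Path, meta: dict | None = None) -> None:
        """Write ``<prefix>.npz`` (weights) + ``<prefix>.json`` (architecture)."""
        prefix = Path(prefix)
        arrays = dict(self.param_dict())
        arrays["embedding.weights"] = self.embedding.weights
        np.savez(prefix.with_suffix(".npz"), **arrays)
        sidecar = {
            "units": self.units,
            "num_layers": len(self.layers),
            "merge_mode": self.merge_mode,
            "head_input": self.head_input,
            "head_bias": float(self.head_bias[0]),
            "embedding_strategy": self.embedding.strategy.name,
            "V": self.embedding.V,
            "d": self.embedding.d,
        }
        if meta:
            sidecar.update(meta)
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")

    @classmethod
    def load(cls, prefix: str | Path) -> "BiGRUClassifier":
        from .embedding import EmbeddingStrategy

        prefix = Path(prefix)
        sidecar = json.loads(prefix.with_suffix(".json").read_text())
        data = np.load(prefix.with_suffix(".npz"))
        strategy = EmbeddingStrategy(sidecar["embedding_strategy"])
        emb = EmbeddingLayer(
            weights=data["embedding.weights"],
            trainable=strategy.trainable,
            strategy=strategy,
        )
        layers = []
        for li in range(sidecar["num_layers"]):
            cells = []
            for dir_ in ("f", "b"):
                kw = {
                    name: data[f"l{li}.{dir_}.{name}"]
                    for name in ("W_z", "U_z", "b_z", "W_r", "U_r", "b_r",
                                 "W_h", "U_h", "b_h")
                }
                cells.append(GRUCellParams(**kw))
            layers.append((cells[0], cells[1]))
        return cls(
            layers=layers,
            merge_mode=sidecar["merge_mode"],
            head_beta=data["head.beta"],
            head_bias=np.array([float(sidecar["head_bias"])]),
            embedding=emb,
            head_input=sidecar["head_input"],
        )


def pad_batch(
    sequences: Sequence[Sequence[int]],
) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad index sequences with the pad index; mask marks real steps."""
    if not sequences:
        raise ValueError("empty batch")
    T = max(len(s) for s in sequences)
    B = len(sequences)
    idx = np.full((B, T), PAD_INDEX, dtype=np.int64)
    mask = np.zeros((B, T), dtype=bool)
    for i, s in enumerate(sequences):
        if len(s) == 0:
            raise ValueError("empty sequence in batch (all steps masked)")
        idx[i, : len(s)] = s
        mask[i, : len(s)] = True
    return idx, mask


def run_bigru(
    embedded: np.ndarray, mask: np.ndarray, model: BiGRUClassifier
) -> np.ndarray:
    """Merged BiGRU state for one pre-embedded sequence (N x d)."""
    embedded = np.asarray(embedded, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if embedded.ndim != 2 or embedded.shape[0] < 1:
        raise ValueError("embedded input must be a non-empty N x d matrix")
    if mask.shape != (embedded.shape[0],):
        raise ValueError("mask length must equal the number of steps")
    if not mask.any():
        raise ValueError("all steps are masked")
    X = embedded[None]
    M = mask[None]
    fwd, bwd = model.layers[0]
    hf, Hf, _ = _gru_forward_batch(X, M, fwd, reverse=False)
    hb, Hb, _ = _gru_forward_batch(X, M, bwd, reverse=True)
    for li in range(1, len(model.layers)):
        X = _merge(Hf, Hb, model.merge_mode)
        fwd, bwd = model.layers[li]
        hf, Hf, _ = _gru_forward_batch(X, M, fwd, reverse=False)
        hb, Hb, _ = _gru_forward_batch(X, M, bwd, reverse=True)
    return _merge(hf, hb, model.merge_mode)[0]


def predict_proba(kmer_indices: Sequence[int], model: BiGRUClassifier) -> float:
    """P(bound) for a single k-mer index sequence."""
    return float(model.predict_proba_batch([list(kmer_indices)])[0])


def loss(p: np.ndarray, y: np.ndarray) -> float:
    """Negative Bernoulli log-likelihood, summed over instances.

    Probabilities are clipped to [1e-7, 1 - 1e-7] before the logs.
    """
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    if np.any((y != 0) & (y != 1)):
        raise ValueError("labels must be 0 or 1")
    pc = np.clip(p, LOSS_EPS, 1.0 - LOSS_EPS)
    return float(-np.sum(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))
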