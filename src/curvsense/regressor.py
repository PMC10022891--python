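"""Sequence-to-ddF regression with a small 1-D convolutional network.

Peptides of 7-24 residues are one-hot encoded over the 20-letter
alphabet (channels in alphabetical order ``ACDEFGHIKLMNPQRSTVWY``) and
zero-padded at the tail to the 24-position reference length.  The
network is two convolution + max-pooling blocks followed by a dense
hidden layer and a single linear output neuron, trained by minimizing
the mean square error against labels in kJ/mol, with a 25% random
validation split and early stopping on validation MSE.

Because labeled data exist only at the 24-residue reference length, the
training set is augmented by splitting each 24-mer at a random position
into two fragments of at least seven residues and interpolating the
labels proportionally to fragment length (the same linear length model
used by :func:`curvsense.thermo.length_adjust`), tripling the dataset up
to duplicate removal.  The model must not be used outside the 7-24
residue range it was trained on, and it assumes helical folding.

The network itself is implemented directly on numpy (forward and
backward passes, Adam optimizer); at these tensor sizes (24 x 20 inputs,
~80k parameters) it trains in about a minute on one CPU core.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .peptides import AA20, MAX_LENGTH, MIN_MODEL_LENGTH, Peptide, as_peptide
from .surrogate import LabeledSequence

__all__ = [
    "LabeledSequence",
    "CNNSpec",
    "TrainConfig",
    "CNNModel",
    "TrainingMetrics",
    "encode",
    "decode",
    "encode_batch",
    "augment_split",
    "train",
    "predict",
    "evaluate",
    "save_model",
    "load_model",
]

_CHANNEL = {a: i for i, a in enumerate(AA20)}


# ---------------------------------------------------------------------------
# encoding

def encode(seq: "Peptide | str") -> np.ndarray:
    """One-hot/zero-pad a 7-24 residue peptide to a (24, 20) 0/1 matrix.

    Row n is the one-hot vector of residue n; rows beyond the sequence
    length are all zero (tail padding).
    """
    p = as_peptide(seq)
    L = len(p)
    if not MIN_MODEL_LENGTH <= L <= MAX_LENGTH:
        raise ValueError(
            f"model inputs must be {MIN_MODEL_LENGTH}-{MAX_LENGTH} residues, got {L}"
        )
    mat = np.zeros((MAX_LENGTH, len(AA20)), dtype=np.float64)
    for n, r in enumerate(p.sequence):
        mat[n, _CHANNEL[r]] = 1.0
    return mat


def decode(mat: np.ndarray) -> str:
    """Invert :func:`encode` (zero rows terminate the sequence)."""
    chars = []
    for row in np.asarray(mat):
        s = row.sum()
        if s == 0:
            break
        if s != 1:
            raise ValueError("row is not one-hot")
        chars.append(AA20[int(row.argmax())])
    return "".join(chars)


def encode_batch(seqs: Sequence["Peptide | str"]) -> np.ndarray:
    return np.stack([encode(s) for s in seqs]) if len(seqs) else np.zeros((0, MAX_LENGTH, len(AA20)))


# ---------------------------------------------------------------------------
# augmentation

def augment_split(
    data: Sequence[LabeledSequence],
    rng: np.random.Generator | int | None = None,
) -> list[LabeledSequence]:
    """Split-and-interpolate augmentation of a reference-length dataset.

    Every input 24-mer is split once at a position drawn uniformly from
    [7, 17], yielding two fragments of at least seven residues whose
    lengths sum to 24; fragment labels are interpolated proportionally,
    ddf * L_frag / 24.  Originals are kept and exact duplicate sequences
    (first occurrence wins) are discarded, so the result holds at most
    3n records.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    for rec in data:
        if len(rec.peptide) != MAX_LENGTH:
            raise ValueError("augmentation requires all inputs at the reference length 24")

    out: list[LabeledSequence] = []
    seen: set[str] = set()

    def push(seq: str, ddf: float, alphabet) -> None:
        if seq not in seen:
            seen.add(seq)
            out.append(LabeledSequence(Peptide(seq, alphabet), ddf))

    for rec in data:
        push(rec.sequence, rec.ddf, rec.peptide.alphabet)
        p = int(rng.integers(MIN_MODEL_LENGTH, MAX_LENGTH - MIN_MODEL_LENGTH + 1))
        for frag in (rec.sequence[:p], rec.sequence[p:]):
            push(frag, rec.ddf * len(frag) / MAX_LENGTH, rec.peptide.alphabet)
    return out


# ---------------------------------------------------------------------------
# network definition

@dataclass(frozen=True)
class CNNSpec:
    """Architecture: two conv blocks, a dense layer, one linear output.

    Each conv block is (filters, kernel, pool); convolutions are
    same-padded along the position axis, pooling is max with
    non-overlapping windows.
    """

    conv_blocks: tuple[tuple[int, int, int], tuple[int, int, int]] = (
        (64, 5, 2),
        (64, 5, 2),
    )
    dense_units: int = 128

    def __post_init__(self) -> None:
        if len(self.conv_blocks) != 2:
            raise ValueError("the architecture has exactly two conv blocks")
        for f, k, p in self.conv_blocks:
            if f < 1 or k < 1 or p < 1:
                raise ValueError("filters, kernel and pool must be >= 1")
        if self.dense_units < 1:
            raise ValueError("dense_units must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    val_fraction: float = 0.25
    max_epochs: int = 100
    patience: int = 30
    batch_size: int = 32
    learning_rate: float = 3e-3
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")


def _conv_cols(x: np.ndarray, k: int) -> np.ndarray:
    """im2col for same-padded 1-D convolution: (B,P,C) -> (B,P,k*C)."""
    B, P, C = x.shape
    left = (k - 1) // 2
    xp = np.zeros((B, P + k - 1, C), dtype=x.dtype)
    xp[:, left:left + P, :] = x
    return np.concatenate([xp[:, j:j + P, :] for j in range(k)], axis=2)


def _conv_cols_backward(dcols: np.ndarray, P: int, C: int, k: int) -> np.ndarray:
    B = dcols.shape[0]
    left = (k - 1) // 2
    dxp = np.zeros((B, P + k - 1, C), dtype=dcols.dtype)
    for j in range(k):
        dxp[:, j:j + P, :] += dcols[:, :, j * C:(j + 1) * C]
    return dxp[:, left:left + P, :]


class _ConvBlock:
    """Same-padded conv -> ReLU -> non-overlapping max pool."""

    def __init__(self, c_in: int, filters: int, kernel: int, pool: int,
                 rng: np.random.Generator):
        self.k, self.pool, self.c_in = kernel, pool, c_in
        fan_in = kernel * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, filters))
        self.b = np.zeros(filters)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cols = _conv_cols(x, self.k)                     # (B,P,kC)
        pre = cols @ self.W + self.b                     # (B,P,F)
        act = np.maximum(pre, 0.0)
        B, P, F = act.shape
        Pp = P // self.pool
        win = act[:, :Pp * self.pool, :].reshape(B, Pp, self.pool, F)
        out = win.max(axis=2)
        if train:
            self._cache = (cols, pre, win, out, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, pre, win, out, xshape = self._cache
        B, P, C = xshape
        # route gradient through the pooling argmax
        mask = win == out[:, :, None, :]
        mask = mask / mask.sum(axis=2, keepdims=True)    # split ties evenly
        dact = np.zeros_like(pre)
        Pp = win.shape[1]
        dwin = mask * dout[:, :, None, :]
        dact[:, :Pp * self.pool, :] = dwin.reshape(B, Pp * self.pool, -1)
        dpre = dact * (pre > 0.0)
        F = dpre.shape[2]
        self.dW = cols.reshape(-1, self.W.shape[0]).T @ dpre.reshape(-1, F)
        self.db = dpre.sum(axis=(0, 1))
        dcols = dpre @ self.W.T
        return _conv_cols_backward(dcols, P, C, self.k)

    @property
    def params(self):
        return [("W", self), ("b", self)]


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 relu: bool = True):
        self.relu = relu
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        pre = x @ self.W + self.b
        out = np.maximum(pre, 0.0) if self.relu else pre
        if train:
            self._cache = (x, pre)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, pre = self._cache
        dpre = dout * (pre > 0.0) if self.relu else dout
        self.dW = x.T @ dpre
        self.db = dpre.sum(axis=0)
        return dpre @ self.W.T


class CNNModel:
    """Trained regressor: encoded (24, 20) peptides -> ddF in kJ/mol.

    Labels are standardized internally (``y_mean``/``y_std`` stored with
    the model); :func:`predict` returns values on the original kJ/mol
    scale.
    """

    def __init__(self, spec: CNNSpec, seed: int | None = None):
        self.spec = spec
        rng = np.random.default_rng(seed)
        (f1, k1, p1), (f2, k2, p2) = spec.conv_blocks
        P = MAX_LENGTH
        self.block1 = _ConvBlock(len(AA20), f1, k1, p1, rng)
        P //= p1
        self.block2 = _ConvBlock(f1, f2, k2, p2, rng)
        P //= p2
        if P < 1:
            raise ValueError("pooling collapsed the position axis; reduce pool sizes")
        self.flat_dim = P * f2
        self.dense = _Dense(self.flat_dim, spec.dense_units, rng, relu=True)
        self.head = _Dense(spec.dense_units, 1, rng, relu=False)
        self.y_mean, self.y_std = 0.0, 1.0

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.block1.forward(x, train)
        h = self.block2.forward(h, train)
        B = h.shape[0]
        self._h_shape = h.shape
        h = h.reshape(B, -1)
        h = self.dense.forward(h, train)
        return self.head.forward(h, train)[:, 0]

    def backward(self, dloss: np.ndarray) -> None:
        d = self.head.backward(dloss[:, None])
        d = self.dense.backward(d)
        d = d.reshape(self._h_shape)
        d = self.block2.backward(d)
        self.block1.backward(d)

    # -- parameter plumbing ------------------------------------------------
    def _layers(self):
        return [self.block1, self.block2, self.dense, self.head]

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers():
            out += [layer.W.copy(), layer.b.copy()]
        return out

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self._layers():
            layer.W = np.array(next(it), dtype=float)
            layer.b = np.array(next(it), dtype=float)


@dataclass
class TrainingMetrics:
    train_mse: list[float] = field(default_factory=list)  # kJ^2/mol^2
    val_mse: list[float] = field(default_factory=list)
    best_epoch: int = 0
    final_r2: float = float("nan")  # on the validation split

    def to_dict(self) -> dict:
        return {
            "train_mse": self.train_mse,
            "val_mse": self.val_mse,
            "best_epoch": self.best_epoch,
            "final_r2": self.final_r2,
        }


class _Adam:
    def __init__(self, model: CNNModel, lr: float):
        self.model, self.lr = model, lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.state = {}

    def step(self) -> None:
        self.t += 1
        for li, layer in enumerate(self.model._layers()):
            for name in ("W", "b"):
                g = getattr(layer, "d" + name)
                p = getattr(layer, name)
                m, v = self.state.get((li, name), (np.zeros_like(p), np.zeros_like(p)))
                m = self.beta1 * m + (1 - self.beta1) * g
                v = self.beta2 * v + (1 - self.beta2) * g * g
                self.state[(li, name)] = (m, v)
                mhat = m / (1 - self.beta1 ** self.t)
                vhat = v / (1 - self.beta2 ** self.t)
                setattr(layer, name, p - self.lr * mhat / (np.sqrt(vhat) + self.eps))


def train(
    data: Sequence[LabeledSequence],
    spec: CNNSpec = CNNSpec(),
    cfg: TrainConfig = TrainConfig(),
) -> tuple[CNNModel, TrainingMetrics]:
    """Fit the regressor by MSE minimization with early stopping.

    A ``val_fraction`` random sample is held out for validation; training
    stops when validation MSE has not improved for ``cfg.patience``
    epochs (or at ``max_epochs``) and the best-validation weights are
    restored.  Fully deterministic given ``cfg.seed``.
    """
    if len(data) < 100:
        raise ValueError(f"need at least 100 records to train, got {len(data)}")
    rng = np.random.default_rng(cfg.seed)

    X = encode_batch([r.peptide for r in data])
    y = np.array([r.ddf for r in data], dtype=float)
    order = rng.permutation(len(y))
    n_val = max(1, int(round(cfg.val_fraction * len(y))))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    Xtr, ytr, Xval, yval = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]

    model = CNNModel(spec, seed=int(rng.integers(2**31)))
    model.y_mean, model.y_std = float(ytr.mean()), float(ytr.std() or 1.0)
    ztr = (ytr - model.y_mean) / model.y_std

    opt = _Adam(model, cfg.learning_rate)
    metrics = TrainingMetrics()
    best_val, best_weights, stale = np.inf, model.get_weights(), 0

    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(len(ztr))
        sse = 0.0
        for start in range(0, len(ztr), cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            xb, zb = Xtr[idx], ztr[idx]
            pred = model.forward(xb, train=True)
            err = pred - zb
            sse += float((err * err).sum())
            model.backward(2.0 * err / len(err))
            opt.step()
        metrics.train_mse.append(sse / len(ztr) * model.y_std**2)

        val_pred = predict_encoded(model, Xval)
        val_mse = float(np.mean((val_pred - yval) ** 2))
        metrics.val_mse.append(val_mse)
        if val_mse < best_val - 1e-12:
            best_val, best_weights, stale = val_mse, model.get_weights(), 0
            metrics.best_epoch = epoch
        else:
            stale += 1
            if stale >= cfg.patience:
                break

    model.set_weights(best_weights)
    val_pred = predict_encoded(model, Xval)
    ss_tot = float(np.sum((yval - yval.mean()) ** 2))
    metrics.final_r2 = 1.0 - float(np.sum((yval - val_pred) ** 2)) / ss_tot if ss_tot else float("nan")
    return model, metrics


def predict_encoded(model: CNNModel, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
    preds = [
        model.forward(X[i:i + batch_size])
        for i in range(0, len(X), batch_size)
    ]
    z = np.concatenate(preds) if preds else np.zeros(0)
    return z * model.y_std + model.y_mean


def predict(model: CNNModel, seqs: Sequence["Peptide | str"] | "Peptide | str") -> np.ndarray:
    """Predict ddF (kJ/mol) for one peptide or a batch of 7-24-mers."""
    single = isinstance(seqs, (str, Peptide))
    batch = [seqs] if single else list(seqs)
    out = predict_encoded(model, encode_batch(batch))
    return out


def evaluate(model: CNNModel, data: Sequence[LabeledSequence]) -> dict[str, float]:
    """MSE (kJ^2/mol^2), RMSE (kJ/mol, = sqrt(MSE)) and R^2 on a dataset."""
    if not data:
        raise ValueError("evaluate requires a non-empty dataset")
    y = np.array([r.ddf for r in data], dtype=float)
    pred = predict(model, [r.peptide for r in data])
    mse = float(np.mean((pred - y) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    return {"mse": mse, "rmse": float(np.sqrt(mse)), "r2": r2}


# ---------------------------------------------------------------------------
# model persistence

_CONVENTIONS = (
    "one-hot channels in alphabetical order ACDEFGHIKLMNPQRSTVWY; "
    "zero padding at the tail to 24 positions; valid input lengths 7-24; "
    "predictions in kJ/mol (labels standardized internally)"
)


def save_model(model: CNNModel, path: "str | Path") -> None:
    """Write a model directory: spec.json (text) + weights.npz."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    spec = {
        "conventions": _CONVENTIONS,
        "conv_blocks": [list(b) for b in model.spec.conv_blocks],
        "dense_units": model.spec.dense_units,
        "y_mean": model.y_mean,
        "y_std": model.y_std,
    }
    (path / "spec.json").write_text(json.dumps(spec, indent=2) + "\n")
    weights = model.get_weights()
    np.savez(path / "weights.npz", **{f"p{i}": w for i, w in enumerate(weights)})


def load_model(path: "str | Path") -> CNNModel:
    path = Path(path)
    spec = json.loads((path / "spec.json").read_text())
    model = CNNModel(
        CNNSpec(
            conv_blocks=tuple(tuple(b) for b in spec["conv_blocks"]),
            dense_units=spec["dense_units"],
        )
    )
    model.y_mean, model.y_std = spec["y_mean"], spec["y_std"]
    with np.load(path / "weights.npz") as npz:
        model.set_weights([npz[f"p{i}"] for i in range(len(npz.files))])
    return model
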