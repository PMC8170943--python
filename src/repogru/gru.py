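"""Gated recurrent unit binary classifier, implemented in NumPy.

The cell follows the standard GRU equations.  With input i_t, previous
hidden state h_{t-1}, elementwise product ``*`` and logistic sigmoid:

    z_t = sigmoid(W_z i_t + U_z h_{t-1} + b_z)        (update gate)
    r_t = sigmoid(W_r i_t + U_r h_{t-1} + b_r)        (reset gate)
    c_t = tanh(W_h i_t + U_h (r_t * h_{t-1}) + b_h)   (candidate state)
    h_t = (1 - z_t) * h_{t-1} + z_t * c_t

A dense sigmoid head maps the final hidden state to a probability
p = sigmoid(w . h_T + b); training minimises binary cross-entropy

    L(t, p) = -( (1 - t) log(1 - p) + t log p )

with the Adam optimizer, inverted-dropout regularisation on h_T, and full
backpropagation through time.  A flat per-pair feature vector is presented
to the recurrence as ``timesteps`` equal chunks (default 1: a single step
over the whole vector).

Everything is deterministic given the seed: fixed initialisation, fixed
shuffling, fixed dropout masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .features import PairFeatureTable

__all__ = [
    "GruParameters",
    "TrainConfig",
    "GruState",
    "gru_step",
    "forward",
    "bce_loss",
    "train",
    "predict",
    "save_parameters",
    "load_parameters",
]

_BCE_EPS = 1e-7

_PARAM_NAMES = ("W_z", "W_r", "W_h", "U_z", "U_r", "U_h", "b_z", "b_r", "b_h",
                "dense_w", "dense_b")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class GruParameters:
    """The nine gate matrices/biases plus the dense head."""

    W_z: np.ndarray
    W_r: np.ndarray
    W_h: np.ndarray
    U_z: np.ndarray
    U_r: np.ndarray
    U_h: np.ndarray
    b_z: np.ndarray
    b_r: np.ndarray
    b_h: np.ndarray
    dense_w: np.ndarray
    dense_b: float

    def __post_init__(self) -> None:
        h, d = self.W_z.shape
        for name in ("W_r", "W_h"):
            if getattr(self, name).shape != (h, d):
                raise ValueError(f"{name} must have shape {(h, d)}")
        for name in ("U_z", "U_r", "U_h"):
            if getattr(self, name).shape != (h, h):
                raise ValueError(f"{name} must have shape {(h, h)}")
        for name in ("b_z", "b_r", "b_h", "dense_w"):
            if getattr(self, name).shape != (h,):
                raise ValueError(f"{name} must have shape {(h,)}")
        for name in _PARAM_NAMES:
            if not np.all(np.isfinite(np.asarray(getattr(self, name)))):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def hidden(self) -> int:
        return self.W_z.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_z.shape[1]

    @classmethod
    def zeros(cls, input_dim: int, hidden: int) -> "GruParameters":
        h, d = hidden, input_dim
        return cls(
            W_z=np.zeros((h, d)), W_r=np.zeros((h, d)), W_h=np.zeros((h, d)),
            U_z=np.zeros((h, h)), U_r=np.zeros((h, h)), U_h=np.zeros((h, h)),
            b_z=np.zeros(h), b_r=np.zeros(h), b_h=np.zeros(h),
            dense_w=np.zeros(h), dense_b=0.0,
        )

    @classmethod
    def init(cls, input_dim: int, hidden: int, seed: int) -> "GruParameters":
        """Scaled-uniform (Glorot) input matrices, orthogonal recurrent
        matrices, zero biases — the conventional GRU initialisation."""
        rng = np.random.default_rng(seed)
        h, d = hidden, input_dim

        def glorot(rows: int, cols: int) -> np.ndarray:
            lim = np.sqrt(6.0 / (rows + cols))
            return rng.uniform(-lim, lim, size=(rows, cols))

        def orthogonal(n: int) -> np.ndarray:
            a = rng.standard_normal((n, n))
            q, r = np.linalg.qr(a)
            return q * np.sign(np.diag(r))

        return cls(
            W_z=glorot(h, d), W_r=glorot(h, d), W_h=glorot(h, d),
            U_z=orthogonal(h), U_r=orthogonal(h), U_h=orthogonal(h),
            b_z=np.zeros(h), b_r=np.zeros(h), b_h=np.zeros(h),
            dense_w=glorot(1, h)[0], dense_b=0.0,
        )

    def copy(self) -> "GruParameters":
        return GruParameters(
            **{n: np.array(getattr(self, n)) for n in _PARAM_NAMES[:-1]},
            dense_b=float(self.dense_b),
        )


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    ``hidden`` and ``dropout`` follow the published model configuration
    (128 hidden units, dropout 0.25 on the final hidden state); the
    remaining values are conventional Adam/minibatch defaults.  The
    feature width must be divisible by ``timesteps``.
    """

    hidden: int = 128
    dropout: float = 0.25
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    timesteps: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.hidden < 1:
            raise ValueError("hidden must be >= 1")
        if self.timesteps < 1:
            raise ValueError("timesteps must be >= 1")


@dataclass(frozen=True)
class GruState:
    """One recurrence step's gates and hidden state, kept for inspection."""

    h: np.ndarray
    z: np.ndarray
    r: np.ndarray
    c: np.ndarray


def gru_step(p: GruParameters, i_t: np.ndarray, h_prev: np.ndarray) -> GruState:
    """One GRU cell step.  Accepts a single vector or a (batch, dim) array."""
    i_t = np.atleast_2d(np.asarray(i_t, dtype=np.float64))
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=np.float64))
    if i_t.shape[1] != p.input_dim:
        raise ValueError(f"input width {i_t.shape[1]} != parameter input_dim {p.input_dim}")
    if h_prev.shape[1] != p.hidden:
        raise ValueError(f"hidden width {h_prev.shape[1]} != parameter hidden {p.hidden}")
    z = _sigmoid(i_t @ p.W_z.T + h_prev @ p.U_z.T + p.b_z)
    r = _sigmoid(i_t @ p.W_r.T + h_prev @ p.U_r.T + p.b_r)
    c = np.tanh(i_t @ p.W_h.T + (r * h_prev) @ p.U_h.T + p.b_h)
    h = (1.0 - z) * h_prev + z * c
    squeeze = h.shape[0] == 1
    if squeeze:
        return GruState(h[0], z[0], r[0], c[0])
    return GruState(h, z, r, c)


def _reshape_steps(X: np.ndarray, timesteps: int) -> np.ndarray:
    """(batch, width) -> (timesteps, batch, width // timesteps)."""
    b, w = X.shape
    if w % timesteps != 0:
        raise ValueError(f"feature width {w} is not divisible by timesteps {timesteps}")
    return X.reshape(b, timesteps, w // timesteps).transpose(1, 0, 2)


def _forward_batch(
    p: GruParameters,
    X: np.ndarray,
    timesteps: int,
    dropout: float = 0.0,
    dropout_active: bool = False,
    rng: Optional[np.random.Generator] = None,
    keep_cache: bool = False,
):
    """Batched forward pass; optionally returns the cache needed by BPTT."""
    steps = _reshape_steps(X, timesteps)
    b = X.shape[0]
    h = np.zeros((b, p.hidden))
    cache = []
    for t in range(timesteps):
        h_prev = h
        st = gru_step(p, steps[t], h_prev)
        h = np.atleast_2d(st.h)
        if keep_cache:
            cache.append((steps[t], h_prev, np.atleast_2d(st.z),
                          np.atleast_2d(st.r), np.atleast_2d(st.c)))
    mask = np.ones_like(h)
    if dropout_active and dropout > 0.0:
        if rng is None:
            raise ValueError("dropout_active requires an rng")
        mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
    h_drop = h * mask
    logits = h_drop @ p.dense_w + p.dense_b
    probs = _sigmoid(logits)
    if keep_cache:
        return probs, (cache, h, mask, h_drop)
    return probs


def forward(
    p: GruParameters,
    x: np.ndarray,
    timesteps: int = 1,
    dropout: float = 0.0,
    dropout_active: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Probability for one flat feature vector.

    The vector is split into ``timesteps`` equal chunks, rolled through the
    recurrence from h_0 = 0, and the final hidden state is mapped through
    the dense sigmoid head.  At inference (``dropout_active=False``) this is
    a pure function of (parameters, input).
    """
    x = np.asarray(x, dtype=np.float64).reshape(1, -1)
    return float(
        _forward_batch(p, x, timesteps, dropout, dropout_active, rng)[0]
    )


def bce_loss(p: float | np.ndarray, t: float | np.ndarray) -> float | np.ndarray:
    """Binary cross-entropy with probabilities clipped to [eps, 1-eps]."""
    p = np.clip(np.asarray(p, dtype=np.float64), _BCE_EPS, 1.0 - _BCE_EPS)
    t = np.asarray(t, dtype=np.float64)
    out = -((1.0 - t) * np.log(1.0 - p) + t * np.log(p))
    return float(out) if out.ndim == 0 else out


class _Adam:
    def __init__(self, shapes: dict[str, tuple], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _backward_batch(p: GruParameters, cache, mask, h_drop, probs, targets):
    """Gradients of the mean BCE over the batch w.r.t. every parameter."""
    caches, h_T, _, _ = cache
    b = probs.shape[0]
    grads = {n: np.zeros_like(np.asarray(getattr(p, n), dtype=np.float64))
             for n in _PARAM_NAMES[:-1]}
    grads["dense_b"] = np.zeros(())

    dlogit = (probs - targets) / b          # sigmoid+BCE shortcut
    grads["dense_w"] += h_drop.T @ dlogit
    grads["dense_b"] = grads["dense_b"] + dlogit.sum()
    dh = np.outer(dlogit, p.dense_w) * mask

    for x_t, h_prev, z, r, c in reversed(caches):
        dz = dh * (c - h_prev)
        dc = dh * z
        dh_prev = dh * (1.0 - z)

        da_c = dc * (1.0 - c * c)
        grads["W_h"] += da_c.T @ x_t
        grads["U_h"] += da_c.T @ (r * h_prev)
        grads["b_h"] += da_c.sum(axis=0)
        drh = da_c @ p.U_h
        dr = drh * h_prev
        dh_prev += drh * r

        da_z = dz * z * (1.0 - z)
        grads["W_z"] += da_z.T @ x_t
        grads["U_z"] += da_z.T @ h_prev
        grads["b_z"] += da_z.sum(axis=0)
        dh_prev += da_z @ p.U_z

        da_r = dr * r * (1.0 - r)
        grads["W_r"] += da_r.T @ x_t
        grads["U_r"] += da_r.T @ h_prev
        grads["b_r"] += da_r.sum(axis=0)
        dh_prev += da_r @ p.U_r

        dh = dh_prev
    return grads


def train(
    table: PairFeatureTable, cfg: TrainConfig
) -> tuple[GruParameters, list[float]]:
    """Fit the classifier on a labelled pair-feature table.

    Returns the trained parameters and the per-epoch mean training loss.
    Deterministic given ``cfg.seed``; raises if only one label class is
    present.  ``epochs=0`` returns the initialisation with empty history.
    """
    if table.labels is None:
        raise ValueError("training requires labels")
    y = np.asarray(table.labels, dtype=np.float64)
    if np.unique(y).size < 2:
        raise ValueError("training requires both label classes")
    X = table.features
    if X.shape[1] % cfg.timesteps != 0:
        raise ValueError(
            f"feature width {X.shape[1]} is not divisible by timesteps {cfg.timesteps}"
        )
    input_dim = X.shape[1] // cfg.timesteps
    params = GruParameters.init(input_dim, cfg.hidden, cfg.seed)
    pdict = {n: np.asarray(getattr(params, n), dtype=np.float64) for n in _PARAM_NAMES[:-1]}
    pdict["dense_b"] = np.zeros(())
    pdict["dense_b"] = pdict["dense_b"] + params.dense_b
    opt = _Adam({k: v.shape for k, v in pdict.items()}, cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)

    def current() -> GruParameters:
        return GruParameters(
            **{n: pdict[n] for n in _PARAM_NAMES[:-1]}, dense_b=float(pdict["dense_b"])
        )

    history: list[float] = []
    n = X.shape[0]
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            cp = current()
            probs, cache = _forward_batch(
                cp, xb, cfg.timesteps, cfg.dropout, dropout_active=True,
                rng=rng, keep_cache=True,
            )
            epoch_loss += float(bce_loss(probs, yb).sum())
            grads = _backward_batch(cp, cache, cache[2], cache[3], probs, yb)
            opt.step(pdict, grads)
        history.append(epoch_loss / n)
    return current(), history


def predict(p: GruParameters, table: PairFeatureTable, cfg: TrainConfig) -> np.ndarray:
    """Score every row of the table; dropout disabled, scores in (0, 1)."""
    X = table.features
    if X.shape[1] % cfg.timesteps != 0 or X.shape[1] // cfg.timesteps != p.input_dim:
        raise ValueError(
            f"feature width {X.shape[1]} incompatible with parameters "
            f"(input_dim {p.input_dim} x timesteps {cfg.timesteps})"
        )
    out = np.empty(X.shape[0])
    bs = 1024
    for start in range(0, X.shape[0], bs):
        out[start:start + bs] = _forward_batch(p, X[start:start + bs], cfg.timesteps)
    return out


def save_parameters(p: GruParameters, cfg: TrainConfig, path: str | Path) -> None:
    """Serialise parameters plus the training config to a single .npz file."""
    arrays = {n: np.asarray(getattr(p, n)) for n in _PARAM_NAMES}
    cfg_arr = np.array(
        [cfg.hidden, cfg.dropout, cfg.epochs, cfg.batch_size,
         cfg.learning_rate, cfg.timesteps, cfg.seed], dtype=np.float64
    )
    np.savez(path, __config__=cfg_arr, **arrays)


def load_parameters(path: str | Path) -> tuple[GruParameters, TrainConfig]:
    with np.load(path) as data:
        kwargs = {n: data[n] for n in _PARAM_NAMES[:-1]}
        params = GruParameters(**kwargs, dense_b=float(data["dense_b"]))
        c = data["__config__"]
    cfg = TrainConfig(
        hidden=int(c[0]), dropout=float(c[1]), epochs=int(c[2]),
        batch_size=int(c[3]), learning_rate=float(c[4]),
        timesteps=int(c[5]), seed=int(c[6]),
    )
    return params, cfg
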