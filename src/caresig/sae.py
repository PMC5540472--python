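"""Sparse autoencoder with KL-divergence sparsity, and greedy stacking.

An autoencoder here is the classic three-layer network: a visible layer
``n`` (features in [0, 1]), a sigmoid hidden layer ``z = f(W_e n + b_e)``
and a sigmoid reconstruction ``y = f(W_d z + b_d)``.  Training minimizes

    c = (1 / 2q) Σ_i ||n_i − y_i||²  +  α Σ_j KL(ρ || ρ̂_j)

over a batch of q inputs, where ρ̂_j is neuron j's mean activation over
the batch, ρ is the sparsity target and α weighs the penalty.  The KL
term (natural log) pulls every hidden neuron's average activity toward
ρ, producing sparse codes.  Gradients are exact, including the penalty's
dependence on ρ̂ through z, and are exercised against central finite
differences in the test suite.

A stack is pretrained greedily: layer i+1 is trained as an autoencoder
on layer i's hidden activations of the batch.

Optimization is deterministic full-batch gradient descent with a
halve-on-increase step-size backoff (a step that raises the cost is
rejected and retried at half the rate), so the cost trace is
non-increasing by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError, TrainingError

_EPS = 1e-6  # clamp for mean activations inside the KL term


def sigmoid(a):
    """Logistic function 1 / (1 + e^(−a)); saturates instead of overflowing."""
    a = np.asarray(a, dtype=float)
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out if out.ndim else float(out)


@dataclass
class SparsityConfig:
    """Sparsity penalty: weight ``alpha`` (α ≥ 0) and target ``rho`` (ρ).

    The default α is deliberately small: because ρ̂ is a mean over the
    batch, a heavy penalty makes "every activation pinned at ρ" a
    near-stationary collapse point that gradient descent cannot leave,
    and the code then carries no information.  α = 0.1 keeps codes
    sparse without collapsing them.
    """

    alpha: float = 0.1
    rho: float = 0.05

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise InputError("alpha must be nonnegative")
        if not 0 < self.rho < 1:
            raise InputError("rho must lie in (0, 1)")


@dataclass
class TrainConfig:
    """Full-batch gradient-descent settings.

    ``learning_rate`` is the initial step size; on a cost increase the
    step is rejected and the rate halved, on success it grows by 5%.
    ``max_iters=0`` returns the seeded initialization unchanged.
    """

    learning_rate: float = 0.5
    max_iters: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise InputError("learning_rate must be positive")
        if self.max_iters < 0:
            raise InputError("max_iters must be nonnegative")


@dataclass
class AutoencoderLayer:
    """One autoencoder's parameters.

    ``W_e`` is (hidden × visible), ``W_d`` (visible × hidden); ``b_e``
    and ``b_d`` are the hidden and visible offsets.
    """

    W_e: np.ndarray
    W_d: np.ndarray
    b_e: np.ndarray
    b_d: np.ndarray
    cost_trace: list = field(default_factory=list, repr=False, compare=False)

    @property
    def n_visible(self) -> int:
        return self.W_e.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W_e.shape[0]

    def encode(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return sigmoid(X @ self.W_e.T + self.b_e)

    def decode(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return sigmoid(Z @ self.W_d.T + self.b_d)

    def copy(self) -> "AutoencoderLayer":
        return AutoencoderLayer(
            self.W_e.copy(), self.W_d.copy(), self.b_e.copy(), self.b_d.copy()
        )


def init_layer(n_visible: int, n_hidden: int, seed: int = 0) -> AutoencoderLayer:
    """Seeded uniform initialization in ±sqrt(6 / (fan_in + fan_out))."""
    rng = np.random.default_rng(seed)
    lim = np.sqrt(6.0 / (n_visible + n_hidden))
    return AutoencoderLayer(
        W_e=rng.uniform(-lim, lim, size=(n_hidden, n_visible)),
        W_d=rng.uniform(-lim, lim, size=(n_visible, n_hidden)),
        b_e=np.zeros(n_hidden),
        b_d=np.zeros(n_visible),
    )


def forward(layer: AutoencoderLayer, n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hidden code and reconstruction for one input vector or a batch."""
    n = np.asarray(n, dtype=float)
    single = n.ndim == 1
    if n.shape[-1] != layer.n_visible:
        raise InputError(
            f"input dimension {n.shape[-1]} != layer visible size {layer.n_visible}"
        )
    Z = layer.encode(n)
    Y = layer.decode(Z)
    if single:
        return Z[0], Y[0]
    return Z, Y


def kl_penalty(rho: float, rho_hat):
    """KL(ρ || ρ̂) for Bernoulli means, natural log, elementwise.

    ρ̂ is clamped to [1e−6, 1−1e−6]; the result is ≥ 0 with equality iff
    ρ̂ = ρ.
    """
    rho_hat = np.clip(np.asarray(rho_hat, dtype=float), _EPS, 1 - _EPS)
    val = rho * np.log(rho / rho_hat) + (1 - rho) * np.log((1 - rho) / (1 - rho_hat))
    return val if val.ndim else float(val)


def _check_batch(layer: AutoencoderLayer, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise InputError("empty batch")
    if X.shape[1] != layer.n_visible:
        raise InputError("batch dimension does not match the layer")
    if np.isnan(X).any():
        raise InputError("batch contains NaN")
    return X


def ae_cost(
    layer: AutoencoderLayer, X: np.ndarray, sparsity: SparsityConfig
) -> tuple[float, float, float]:
    """Total cost plus its reconstruction and sparsity terms."""
    X = _check_batch(layer, X)
    q = X.shape[0]
    Z, Y = forward(layer, X)
    recon = float(np.sum((X - Y) ** 2) / (2 * q))
    rho_hat = Z.mean(axis=0)
    sparse = float(sparsity.alpha * np.sum(kl_penalty(sparsity.rho, rho_hat)))
    return recon + sparse, recon, sparse


def ae_gradients(
    layer: AutoencoderLayer, X: np.ndarray, sparsity: SparsityConfig
) -> dict[str, np.ndarray]:
    """Exact analytic gradients of the sparse-autoencoder cost.

    The sparsity term's dependence on ρ̂ through the hidden activations
    is included; where ρ̂ sits at its clamp the penalty is locally flat
    and contributes zero gradient, matching the cost exactly.
    """
    X = _check_batch(layer, X)
    q = X.shape[0]
    Z = layer.encode(X)
    Y = layer.decode(Z)

    delta_out = ((Y - X) / q) * Y * (1 - Y)  # (q, n_visible)
    grad_W_d = delta_out.T @ Z
    grad_b_d = delta_out.sum(axis=0)

    rho_hat = Z.mean(axis=0)
    inside = (rho_hat > _EPS) & (rho_hat < 1 - _EPS)
    rho_hat_c = np.clip(rho_hat, _EPS, 1 - _EPS)
    kl_grad = np.where(
        inside,
        -sparsity.rho / rho_hat_c + (1 - sparsity.rho) / (1 - rho_hat_c),
        0.0,
    )
    dZ = delta_out @ layer.W_d + (sparsity.alpha / q) * kl_grad
    delta_hid = dZ * Z * (1 - Z)
    grad_W_e = delta_hid.T @ X
    grad_b_e = delta_hid.sum(axis=0)
    return {"W_e": grad_W_e, "W_d": grad_W_d, "b_e": grad_b_e, "b_d": grad_b_d}


_PARAM_NAMES = ("W_e", "W_d", "b_e", "b_d")


def train_autoencoder(
    X: np.ndarray,
    n_hidden: int,
    sparsity: SparsityConfig | None = None,
    cfg: TrainConfig | None = None,
) -> AutoencoderLayer:
    """Train one sparse autoencoder by deterministic full-batch descent.

    Returns the layer with its accepted-cost trace on ``cost_trace``
    (non-increasing by construction); the final cost never exceeds the
    initial one.  Raises :class:`TrainingError` if the cost turns NaN.
    """
    sparsity = sparsity or SparsityConfig()
    cfg = cfg or TrainConfig()
    if n_hidden < 1:
        raise InputError("n_hidden must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    layer = init_layer(X.shape[1], n_hidden, cfg.seed)
    if cfg.max_iters == 0:
        return layer

    cost, _, _ = ae_cost(layer, X, sparsity)
    if np.isnan(cost):
        raise TrainingError("cost is NaN at initialization")
    trace = [cost]
    lr = cfg.learning_rate
    for it in range(cfg.max_iters):
        grads = ae_gradients(layer, X, sparsity)
        stepped = False
        while lr > 1e-12:
            trial = AutoencoderLayer(
                *(getattr(layer, p) - lr * grads[p] for p in _PARAM_NAMES)
            )
            new_cost, _, _ = ae_cost(trial, X, sparsity)
            if np.isnan(new_cost):
                raise TrainingError(f"cost diverged to NaN at iteration {it}")
            if new_cost <= cost:
                layer, cost = trial, new_cost
                lr *= 1.05
                stepped = True
                break
            lr *= 0.5
        if not stepped:
            break  # step size underflowed: at a numerical stationary point
        trace.append(cost)
    layer.cost_trace = trace
    return layer


def pretrain_stack(
    X: np.ndarray,
    layer_sizes: list[int],
    sparsity: SparsityConfig | None = None,
    cfg: TrainConfig | None = None,
) -> list[AutoencoderLayer]:
    """Greedy layer-wise pretraining of a stack of sparse autoencoders.

    Layer 1 trains on the batch; each subsequent layer trains on the
    previous layer's hidden activations.  Layer seeds derive from
    ``cfg.seed`` so the whole stack is reproducible.
    """
    if not layer_sizes:
        raise InputError("layer_sizes must be nonempty")
    sparsity = sparsity or SparsityConfig()
    cfg = cfg or TrainConfig()
    layers: list[AutoencoderLayer] = []
    data = np.atleast_2d(np.asarray(X, dtype=float))
    for i, h in enumerate(layer_sizes):
        layer_cfg = TrainConfig(cfg.learning_rate, cfg.max_iters, cfg.seed + i)
        layer = train_autoencoder(data, h, sparsity, layer_cfg)
        layers.append(layer)
        data = layer.encode(data)
    return layers


def encode_stack(X: np.ndarray, layers: list[AutoencoderLayer]) -> np.ndarray:
    """Activations of the last hidden layer for a batch."""
    data = np.atleast_2d(np.asarray(X, dtype=float))
    for layer in layers:
        data = layer.encode(data)
    return data


# --------------------------------------------------------------------------
# serialization: JSON metadata + an .npz array container


def save_stack(path, layers: list[AutoencoderLayer], meta: dict | None = None) -> None:
    """Save a stack to ``<path>`` as an .npz with a JSON metadata entry."""
    arrays = {}
    for i, layer in enumerate(layers):
        for p in _PARAM_NAMES:
            arrays[f"layer{i}_{p}"] = getattr(layer, p)
    meta = dict(meta or {})
    meta["n_layers"] = len(layers)
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_stack(path) -> tuple[list[AutoencoderLayer], dict]:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta_json"]).decode("utf-8"))
        layers = [
            AutoencoderLayer(*(npz[f"layer{i}_{p}"] for p in _PARAM_NAMES))
            for i in range(meta["n_layers"])
        ]
    return layers, meta
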