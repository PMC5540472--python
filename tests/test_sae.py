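"""Sparse-autoencoder tests: closed forms, loop/finite-difference oracles,
training behavior, greedy stacking."""

import numpy as np
import pytest

from caresig import sae
from caresig.exceptions import InputError
from caresig.sae import (
    AutoencoderLayer,
    SparsityConfig,
    TrainConfig,
    ae_cost,
    ae_gradients,
    encode_stack,
    forward,
    init_layer,
    kl_penalty,
    load_stack,
    pretrain_stack,
    save_stack,
    sigmoid,
    train_autoencoder,
)


def test_sigmoid_closed_forms(rng):
    assert sigmoid(0.0) == 0.5
    assert sigmoid(2.0) == pytest.approx(0.8807970779778823, abs=1e-12)
    a = rng.normal(0, 5, size=50)
    np.testing.assert_allclose(sigmoid(a) + sigmoid(-a), 1.0, atol=1e-12)
    assert sigmoid(1000.0) == 1.0 and sigmoid(-1000.0) == 0.0  # saturation, no NaN


def test_forward_zero_layer_outputs_half(rng):
    layer = AutoencoderLayer(np.zeros((3, 4)), np.zeros((4, 3)), np.zeros(3), np.zeros(4))
    z, y = forward(layer, rng.uniform(size=4))
    np.testing.assert_array_equal(z, 0.5)
    np.testing.assert_array_equal(y, 0.5)


def test_forward_matches_hand_computation():
    W_e = np.array([[1.0, -1.0], [0.5, 2.0]])
    W_d = np.array([[2.0, 0.0], [-1.0, 1.0]])
    b_e = np.array([0.1, -0.2])
    b_d = np.array([0.3, 0.0])
    n = np.array([0.8, 0.4])
    layer = AutoencoderLayer(W_e, W_d, b_e, b_d)
    z, y = forward(layer, n)
    z_hand = 1 / (1 + np.exp(-(W_e @ n + b_e)))
    y_hand = 1 / (1 + np.exp(-(W_d @ z_hand + b_d)))
    np.testing.assert_allclose(z, z_hand, atol=1e-15)
    np.testing.assert_allclose(y, y_hand, atol=1e-15)


def test_forward_dimension_mismatch():
    layer = init_layer(4, 2, 0)
    with pytest.raises(InputError):
        forward(layer, np.zeros(5))


class TestKLPenalty:
    def test_zero_at_equality(self):
        assert kl_penalty(0.05, 0.05) == pytest.approx(0.0, abs=1e-12)

    def test_reference_value(self):
        # 0.5·ln(0.5/0.25) + 0.5·ln(0.5/0.75) = 0.5·ln(4/3)
        assert kl_penalty(0.5, 0.25) == pytest.approx(0.14384103622589045, abs=1e-10)

    def test_unique_minimum_on_grid(self):
        rho = 0.3
        grid = np.linspace(0.01, 0.99, 199)
        vals = kl_penalty(rho, grid)
        assert np.all(vals >= 0)
        assert grid[np.argmin(vals)] == pytest.approx(rho, abs=0.005)

    def test_convex_on_grid(self):
        grid = np.linspace(0.02, 0.98, 97)
        vals = kl_penalty(0.05, grid)
        second = np.diff(vals, 2)
        assert np.all(second >= -1e-12)


def _loop_cost(layer, X, sparsity):
    """Independent scalar-loop re-implementation of the cost."""
    q, n_vis = X.shape
    h = layer.n_hidden
    Z = np.zeros((q, h))
    recon = 0.0
    for i in range(q):
        for j in range(h):
            a = layer.b_e[j]
            for v in range(n_vis):
                a += layer.W_e[j, v] * X[i, v]
            Z[i, j] = 1 / (1 + np.exp(-a))
        for v in range(n_vis):
            a = layer.b_d[v]
            for j in range(h):
                a += layer.W_d[v, j] * Z[i, j]
            y = 1 / (1 + np.exp(-a))
            recon += (X[i, v] - y) ** 2
    recon /= 2 * q
    sparse = 0.0
    for j in range(h):
        rho_hat = Z[:, j].mean()
        sparse += sparsity.alpha * (
            sparsity.rho * np.log(sparsity.rho / rho_hat)
            + (1 - sparsity.rho) * np.log((1 - sparsity.rho) / (1 - rho_hat))
        )
    return recon + sparse, recon, sparse


def test_cost_zero_for_perfect_reconstruction_without_penalty():
    layer = AutoencoderLayer(np.zeros((2, 3)), np.zeros((3, 2)), np.zeros(2), np.zeros(3))
    X = np.full((4, 3), 0.5)  # zero decoder reproduces 0.5 exactly
    total, recon, sparse = ae_cost(layer, X, SparsityConfig(alpha=0.0))
    assert total == 0.0 and recon == 0.0 and sparse == 0.0


def test_cost_matches_scalar_loop_oracle(rng):
    sparsity = SparsityConfig(alpha=0.7, rho=0.1)
    for _ in range(5):
        layer = init_layer(4, 3, int(rng.integers(1e6)))
        X = rng.uniform(0.05, 0.95, size=(5, 4))
        total, recon, sparse = ae_cost(layer, X, sparsity)
        t2, r2, s2 = _loop_cost(layer, X, sparsity)
        assert total == pytest.approx(t2, abs=1e-12)
        assert recon == pytest.approx(r2, abs=1e-12)
        assert sparse == pytest.approx(s2, abs=1e-12)


def test_empty_batch_rejected():
    with pytest.raises(InputError):
        ae_cost(init_layer(3, 2, 0), np.zeros((0, 3)), SparsityConfig())


def _fd_gradients(layer, X, sparsity, step=1e-5):
    grads = {}
    for p in ("W_e", "W_d", "b_e", "b_d"):
        arr = getattr(layer, p)
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            ix = it.multi_index
            orig = arr[ix]
            arr[ix] = orig + step
            up = ae_cost(layer, X, sparsity)[0]
            arr[ix] = orig - step
            dn = ae_cost(layer, X, sparsity)[0]
            arr[ix] = orig
            g[ix] = (up - dn) / (2 * step)
        grads[p] = g
    return grads


def _relative_error(a, b):
    denom = max(np.abs(a).max(), np.abs(b).max(), 1e-8)
    return np.abs(a - b).max() / denom


def test_gradients_match_finite_differences(rng):
    sparsity = SparsityConfig(alpha=1.3, rho=0.07)
    for _ in range(3):
        layer = init_layer(5, 3, int(rng.integers(1e6)))
        X = rng.uniform(0.1, 0.9, size=(4, 5))
        analytic = ae_gradients(layer, X, sparsity)
        numeric = _fd_gradients(layer, X, sparsity)
        for p in analytic:
            assert _relative_error(analytic[p], numeric[p]) < 1e-6


def test_zero_alpha_equals_plain_autoencoder_gradients(rng):
    layer = init_layer(4, 2, 3)
    X = rng.uniform(0.2, 0.8, size=(3, 4))
    with_term = ae_gradients(layer, X, SparsityConfig(alpha=0.0))
    numeric = _fd_gradients(layer, X, SparsityConfig(alpha=0.0))
    for p in with_term:
        assert _relative_error(with_term[p], numeric[p]) < 1e-6


def test_train_zero_iters_returns_seeded_init(rng):
    X = rng.uniform(size=(6, 4))
    out = train_autoencoder(X, 2, cfg=TrainConfig(max_iters=0, seed=42))
    ref = init_layer(4, 2, 42)
    for p in ("W_e", "W_d", "b_e", "b_d"):
        np.testing.assert_array_equal(getattr(out, p), getattr(ref, p))


def test_train_reduces_cost_on_low_rank_manifold(rng):
    """4-d inputs on a 2-d linear manifold: a 2-unit plain autoencoder
    should cut the reconstruction cost to below a quarter of the start."""
    latent = rng.uniform(size=(60, 2))
    A = rng.uniform(-0.5, 0.5, size=(2, 4))
    X = np.clip(0.5 + (latent - 0.5) @ A, 0, 1)
    cfg = TrainConfig(learning_rate=0.5, max_iters=300, seed=0)
    layer = train_autoencoder(X, 2, SparsityConfig(alpha=0.0), cfg)
    trace = layer.cost_trace
    assert trace[-1] < 0.25 * trace[0]


def test_cost_trace_is_non_increasing(rng):
    X = rng.uniform(size=(20, 5))
    layer = train_autoencoder(X, 3, SparsityConfig(), TrainConfig(max_iters=60, seed=1))
    assert np.all(np.diff(layer.cost_trace) <= 1e-12)


def test_training_is_deterministic(rng):
    X = rng.uniform(size=(15, 6))
    a = train_autoencoder(X, 3, cfg=TrainConfig(max_iters=40, seed=5))
    b = train_autoencoder(X, 3, cfg=TrainConfig(max_iters=40, seed=5))
    for p in ("W_e", "W_d", "b_e", "b_d"):
        np.testing.assert_array_equal(getattr(a, p), getattr(b, p))


def test_single_layer_stack_equals_direct_training(rng):
    X = rng.uniform(size=(12, 5))
    cfg = TrainConfig(max_iters=30, seed=9)
    stack = pretrain_stack(X, [3], cfg=cfg)
    direct = train_autoencoder(X, 3, SparsityConfig(), TrainConfig(max_iters=30, seed=9))
    np.testing.assert_array_equal(stack[0].W_e, direct.W_e)


def test_stack_shapes_match_layer_plan(rng):
    X = rng.uniform(size=(10, 280))
    stack = pretrain_stack(X, [80, 80, 80], cfg=TrainConfig(max_iters=1, seed=0))
    assert [l.W_e.shape for l in stack] == [(80, 280), (80, 80), (80, 80)]


def test_greedy_stacking_feeds_hidden_activations_forward(rng):
    """Layer 2's training input equals layer 1's encoding of the batch,
    re-verified by an independent forward pass."""
    X = rng.uniform(size=(10, 6))
    cfg = TrainConfig(max_iters=20, seed=2)
    stack = pretrain_stack(X, [4, 3], cfg=cfg)
    H1 = sae.sigmoid(X @ stack[0].W_e.T + stack[0].b_e)
    retrained = train_autoencoder(
        H1, 3, SparsityConfig(), TrainConfig(max_iters=20, seed=3)
    )
    np.testing.assert_allclose(stack[1].W_e, retrained.W_e, atol=1e-12)
    top = sae.sigmoid(H1 @ stack[1].W_e.T + stack[1].b_e)
    np.testing.assert_allclose(encode_stack(X, stack), top, atol=1e-12)


def test_strong_sparsity_pins_mean_activation(rng):
    X = rng.uniform(size=(40, 8))
    layer = train_autoencoder(
        X, 5, SparsityConfig(alpha=10.0, rho=0.05), TrainConfig(max_iters=200, seed=0)
    )
    rho_hat = layer.encode(X).mean()
    assert 0.01 <= rho_hat <= 0.15


def test_stack_serialization_round_trip(tmp_path, rng):
    X = rng.uniform(size=(8, 5))
    stack = pretrain_stack(X, [3, 2], cfg=TrainConfig(max_iters=5, seed=1))
    path = tmp_path / "stack.npz"
    save_stack(path, stack, {"note": "unit"})
    back, meta = load_stack(path)
    assert meta["note"] == "unit" and meta["n_layers"] == 2
    for a, b in zip(stack, back):
        np.testing.assert_array_equal(a.W_e, b.W_e)
        np.testing.assert_array_equal(a.b_d, b.b_d)
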