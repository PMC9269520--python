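"""Layer-level contracts of the numpy network engine."""

import numpy as np
import pytest

import gaitgcn.nn as nn


@pytest.fixture
def x_small(rng):
    return rng.normal(size=(2, 8, 5, 4)).astype(nn.DTYPE)


def numeric_gradients(layer, x, seed=0, eps=1e-6):
    """Central-difference gradients of sum(forward(x) * R) in float64."""
    rng = np.random.default_rng(seed)
    R = rng.normal(size=layer.forward(x).shape)

    def loss():
        return float((layer.forward(x) * R).sum())

    layer.zero_grad()
    layer.forward(x)
    gx = layer.backward(R.copy())
    num_gx = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = loss()
        x[i] = old - eps
        fm = loss()
        x[i] = old
        num_gx[i] = (fp - fm) / (2 * eps)
    param_errs = []
    for p in layer.parameters():
        num = np.zeros_like(p.data)
        it = np.nditer(p.data, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            old = p.data[i]
            p.data[i] = old + eps
            fp = loss()
            p.data[i] = old - eps
            fm = loss()
            p.data[i] = old
            num[i] = (fp - fm) / (2 * eps)
        param_errs.append(np.abs(p.grad - num).max())
    return np.abs(gx - num_gx).max(), max(param_errs, default=0.0)


@pytest.fixture
def float64_layers(monkeypatch):
    """Run layer math in double precision for tight gradient checks."""
    monkeypatch.setattr(nn, "DTYPE", np.float64)
    nn._ONES_CACHE.clear()
    yield
    nn._ONES_CACHE.clear()


@pytest.mark.parametrize(
    "make_layer",
    [
        pytest.param(
            lambda A: nn.SpatialGraphConv(
                4, 6, A, np.random.default_rng(1)
            ),
            id="spatial-graph-conv",
        ),
        pytest.param(
            lambda A: nn.SpatialGraphConv(
                4, 6, A, np.random.default_rng(1), edge_importance=True
            ),
            id="spatial-graph-conv-masked",
        ),
        pytest.param(
            lambda A: nn.TemporalConv(
                4, 5, 9, 1, False, np.random.default_rng(2)
            ),
            id="temporal-standard",
        ),
        pytest.param(
            lambda A: nn.TemporalConv(
                4, 5, 9, 2, True, np.random.default_rng(2)
            ),
            id="temporal-separable-stride2",
        ),
        pytest.param(
            lambda A: nn.TemporalConv(
                4, 5, 1, 2, False, np.random.default_rng(2)
            ),
            id="temporal-1x1-stride2",
        ),
        pytest.param(lambda A: nn.BatchNorm(4), id="batchnorm"),
        pytest.param(
            lambda A: nn.InputBatchNorm(5, 4), id="input-batchnorm"
        ),
        pytest.param(
            lambda A: nn.STJointAttention(4, 2, np.random.default_rng(3)),
            id="st-joint-attention",
        ),
    ],
)
def test_backward_matches_numeric_gradient(float64_layers, make_layer):
    rng = np.random.default_rng(7)
    A = np.abs(rng.normal(size=(3, 5, 5)))
    x = rng.normal(size=(2, 8, 5, 4))
    layer = make_layer(A)
    gx_err, p_err = numeric_gradients(layer, x)
    assert gx_err <= 1e-7
    assert p_err <= 1e-7


class TestSpatialGraphConv:
    def test_identity_configuration_passthrough(self, x_small):
        # A = I, W = I, b = 0: the layer is the identity map
        layer = nn.SpatialGraphConv(
            4, 4, np.eye(5), np.random.default_rng(0)
        )
        layer.W.data[...] = np.eye(4)[None]
        layer.b.data[...] = 0.0
        assert np.allclose(layer.forward(x_small), x_small, atol=1e-6)

    def test_single_joint_reduces_to_linear_map(self, rng):
        x = rng.normal(size=(3, 6, 1, 4)).astype(nn.DTYPE)
        layer = nn.SpatialGraphConv(
            4, 2, np.ones((1, 1, 1)), np.random.default_rng(0)
        )
        out = layer.forward(x)
        expected = x.reshape(-1, 4) @ layer.W.data[0] + layer.b.data
        assert np.allclose(out.reshape(-1, 2), expected, atol=1e-5)

    def test_matches_neighbor_sum_oracle(self, rng):
        # random 6-joint graph, K = 1: out_i = sum_j A[i,j] x_j W + b
        V, C, Co = 6, 4, 3
        A = np.triu((rng.random((V, V)) < 0.5).astype(float), 1)
        A = A + A.T
        layer = nn.SpatialGraphConv(C, Co, A, np.random.default_rng(0))
        x = rng.normal(size=(2, 5, V, C)).astype(nn.DTYPE)
        out = layer.forward(x)
        W, b = layer.W.data[0], layer.b.data
        for n in range(2):
            for t in range(5):
                for i in range(V):
                    acc = b.astype(np.float64).copy()
                    for j in range(V):
                        if A[i, j]:
                            acc += A[i, j] * (x[n, t, j] @ W)
                    assert np.abs(out[n, t, i] - acc).max() <= 1e-5


class TestTemporalConv:
    def test_identity_kernel_passthrough(self, x_small):
        layer = nn.TemporalConv(4, 4, 1, 1, False,
                                np.random.default_rng(0))
        layer.W.data[...] = np.eye(4)[None]
        layer.b.data[...] = 0.0
        assert np.allclose(layer.forward(x_small), x_small, atol=1e-6)

    def test_stride_two_halves_frames(self, rng):
        x = rng.normal(size=(1, 64, 5, 4)).astype(nn.DTYPE)
        layer = nn.TemporalConv(4, 4, 9, 2, True,
                                np.random.default_rng(0))
        assert layer.forward(x).shape == (1, 32, 5, 4)

    def test_separable_factorized_identity(self, x_small):
        # depth-wise = centered delta, point-wise = identity → passthrough
        layer = nn.TemporalConv(4, 4, 9, 1, True,
                                np.random.default_rng(0))
        layer.Wd.data[...] = 0.0
        layer.Wd.data[4, :] = 1.0
        layer.Wp.data[...] = np.eye(4)
        layer.b.data[...] = 0.0
        assert np.allclose(layer.forward(x_small), x_small, atol=1e-6)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            nn.TemporalConv(4, 4, 8, 1, True, np.random.default_rng(0))


class TestBatchNorm:
    def test_normalizes_batch_statistics(self, rng):
        x = (rng.normal(size=(8, 16, 5, 4)) * 3.0 + 7.0).astype(nn.DTYPE)
        layer = nn.BatchNorm(4)
        y = layer.forward(x).reshape(-1, 4)
        assert np.abs(y.mean(axis=0)).max() < 1e-4
        assert np.abs(y.std(axis=0) - 1.0).max() < 1e-3

    def test_eval_mode_uses_running_statistics(self, rng):
        x = rng.normal(size=(8, 4, 5, 4)).astype(nn.DTYPE)
        layer = nn.BatchNorm(4, momentum=1.0)
        layer.forward(x)  # running stats ← batch stats
        layer.set_training(False)
        y_eval = layer.forward(x)
        layer.set_training(True)
        y_train = layer.forward(x)
        assert np.allclose(y_eval, y_train, atol=1e-4)


class TestSTJointAttention:
    def test_scores_strictly_inside_unit_interval(self, rng):
        layer = nn.STJointAttention(4, 2, np.random.default_rng(0))
        x = (rng.normal(size=(3, 8, 5, 4)) * 10).astype(nn.DTYPE)
        layer.forward(x)
        fs, js = layer.last_scores
        for s in (fs, js):
            assert s.min() > 0.0 and s.max() < 1.0

    def test_identity_mode_is_exact_passthrough(self, x_small):
        layer = nn.STJointAttention(4, 2, np.random.default_rng(0))
        layer.identity_mode = True
        out = layer.forward(x_small)
        assert out is x_small  # bit-identical, not just close

    def test_constant_input_gives_constant_scores(self):
        layer = nn.STJointAttention(4, 2, np.random.default_rng(0))
        x = np.full((2, 8, 5, 4), 1.5, dtype=nn.DTYPE)
        layer.forward(x)
        fs, js = layer.last_scores
        assert np.abs(fs - fs[:, :1]).max() <= 1e-6
        assert np.abs(js - js[:, :1]).max() <= 1e-6

    def test_output_ratio_recovers_score_product(self, rng):
        layer = nn.STJointAttention(4, 2, np.random.default_rng(0))
        x = rng.normal(size=(2, 8, 5, 4)).astype(nn.DTYPE)
        x[np.abs(x) < 0.1] = 0.5  # keep denominators away from zero
        out = layer.forward(x)
        fs, js = layer.last_scores
        mask = fs[:, :, None, :] * js[:, None, :, :]
        assert np.abs(out / x - mask).max() <= 1e-6

    def test_indivisible_reduction_rejected(self):
        with pytest.raises(ValueError, match="reduction"):
            nn.STJointAttention(6, 4, np.random.default_rng(0))


def test_cross_entropy_gradient_matches_numeric():
    rng = np.random.default_rng(0)
    logits = rng.normal(size=(4, 3))
    labels = np.array([0, 2, 1, 2])
    _, g = nn.cross_entropy(logits, labels)
    eps = 1e-6
    for n in range(4):
        for c in range(3):
            lp = logits.copy()
            lp[n, c] += eps
            lm = logits.copy()
            lm[n, c] -= eps
            num = (
                nn.cross_entropy(lp, labels)[0]
                - nn.cross_entropy(lm, labels)[0]
            ) / (2 * eps)
            assert abs(g[n, c] - num) <= 1e-6


def test_softmax_rows_sum_to_one(rng):
    p = nn.softmax(rng.normal(size=(5, 7)) * 10)
    assert np.allclose(p.sum(axis=1), 1.0)
    assert p.min() >= 0.0
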