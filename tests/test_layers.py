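"""Unit checks of the hand-rolled layer stack, against brute-force oracles
and finite differences."""

import numpy as np
import pytest

from orbitseg.net import pool_with_indices, unpool
from orbitseg.nn.layers import (BatchNorm2d, Conv2d, MaxPool2d, MaxUnpool2d,
                                ReLU)


def brute_force_pool(x: np.ndarray, pool: int = 2):
    """Window-scan reference for max pooling with absolute argmax indices."""
    h, w = x.shape
    hp, wp = h // pool, w // pool
    pooled = np.empty((hp, wp), dtype=x.dtype)
    idx = np.empty((hp, wp), dtype=np.int64)
    for i in range(hp):
        for j in range(wp):
            best = None
            for di in range(pool):
                for dj in range(pool):
                    r, c = i * pool + di, j * pool + dj
                    if best is None or x[r, c] > best[0]:
                        best = (x[r, c], r * w + c)
            pooled[i, j], idx[i, j] = best
    return pooled, idx


class TestPoolWithIndices:
    def test_direct_maximum(self):
        pooled, idx = pool_with_indices(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert pooled.tolist() == [[4.0]]
        assert idx.tolist() == [[3]]  # bottom-right, row-major flat index

    def test_constant_input_tie_breaks_first_in_scan_order(self):
        pooled, idx = pool_with_indices(np.full((4, 4), 7.0))
        assert np.all(pooled == 7.0)
        # top-left of each window
        assert idx.tolist() == [[0, 2], [8, 10]]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_scan(self, seed):
        x = np.random.default_rng(seed).random((8, 8))
        pooled, idx = pool_with_indices(x)
        ref_pooled, ref_idx = brute_force_pool(x)
        assert np.array_equal(pooled, ref_pooled)
        assert np.array_equal(idx, ref_idx)

    def test_indices_lie_inside_their_windows(self):
        x = np.random.default_rng(10).random((16, 16))
        _, idx = pool_with_indices(x)
        for i in range(8):
            for j in range(8):
                r, c = divmod(int(idx[i, j]), 16)
                assert 2 * i <= r < 2 * i + 2 and 2 * j <= c < 2 * j + 2

    def test_rejects_odd_size(self):
        with pytest.raises(ValueError):
            pool_with_indices(np.zeros((5, 4)))


class TestUnpool:
    def test_places_value_at_recorded_location(self):
        out = unpool(np.array([[5.0]]), np.array([[1]]), (2, 2))
        assert out.tolist() == [[0.0, 5.0], [0.0, 0.0]]

    def test_zero_input_gives_zero_output(self):
        out = unpool(np.zeros((2, 2)), np.array([[0, 3], [8, 11]]), (4, 4))
        assert not out.any()

    def test_sum_preserved_and_zero_off_index(self):
        x = np.random.default_rng(2).random((8, 8))
        pooled, idx = pool_with_indices(x)
        up = unpool(pooled, idx, (8, 8))
        assert np.isclose(up.sum(), pooled.sum())
        nz = np.flatnonzero(up)
        assert set(nz) == set(idx.ravel())
        assert np.allclose(up.ravel()[nz], x.ravel()[nz])

    def test_pool_unpool_pool_fixpoint(self):
        for seed in range(5):
            x = np.random.default_rng(seed).random((16, 16))
            pooled, idx = pool_with_indices(x)
            again, _ = pool_with_indices(unpool(pooled, idx, (16, 16)))
            assert np.array_equal(again, pooled)

    def test_rejects_out_of_range_index(self):
        with pytest.raises(ValueError):
            unpool(np.ones((1, 1)), np.array([[4]]), (2, 2))


class TestLayerGradients:
    """Finite-difference checks; float32 noise bounds the tolerance."""

    def _loss_and_grads(self, layer, x, direction):
        out = layer.forward(x, training=True)
        loss = float(np.sum(out * direction))
        dx = layer.backward(direction)
        return loss, dx

    def _fd_input(self, layer, x, direction, idx, eps=1e-3):
        x1, x2 = x.copy(), x.copy()
        x1[idx] += eps
        x2[idx] -= eps
        l1 = float(np.sum(layer.forward(x1, training=True) * direction))
        l2 = float(np.sum(layer.forward(x2, training=True) * direction))
        return (l1 - l2) / (2 * eps)

    @pytest.mark.parametrize("layer_factory", [
        lambda rng: Conv2d("c", 3, 4, 3, rng),
        lambda rng: BatchNorm2d("b", 3),
        lambda rng: ReLU(),
    ], ids=["conv", "batchnorm", "relu"])
    def test_input_gradient(self, layer_factory):
        rng = np.random.default_rng(0)
        layer = layer_factory(rng)
        x = rng.normal(size=(2, 6, 6, 3)).astype(np.float32) + 0.1
        out = layer.forward(x, training=True)
        direction = np.random.default_rng(1).normal(size=out.shape).astype(np.float32)
        _, dx = self._loss_and_grads(layer, x, direction)
        for idx in [(0, 0, 0, 0), (1, 3, 2, 1), (0, 5, 5, 2)]:
            num = self._fd_input(layer, x, direction, idx)
            assert dx[idx] == pytest.approx(num, rel=2e-2, abs=2e-3)

    def test_conv_weight_gradient(self):
        rng = np.random.default_rng(4)
        layer = Conv2d("c", 2, 3, 3, rng)
        x = rng.normal(size=(2, 6, 6, 2)).astype(np.float32)
        out = layer.forward(x, training=True)
        direction = np.random.default_rng(5).normal(size=out.shape).astype(np.float32)
        layer.backward(direction)
        eps = 1e-3
        for idx in [(0, 0, 0, 0), (1, 2, 1, 2), (2, 1, 0, 1)]:
            old = layer.weight.value[idx]
            layer.weight.value[idx] = old + eps
            l1 = float(np.sum(layer.forward(x, training=True) * direction))
            layer.weight.value[idx] = old - eps
            l2 = float(np.sum(layer.forward(x, training=True) * direction))
            layer.weight.value[idx] = old
            assert layer.weight.grad[idx] == pytest.approx(
                (l1 - l2) / (2 * eps), rel=2e-2, abs=2e-3)

    def test_pool_backward_routes_to_argmax(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(1, 4, 4, 2)).astype(np.float32)
        pool = MaxPool2d(2)
        out = pool.forward(x, training=True)
        d = pool.backward(np.ones_like(out))
        # each window receives exactly one unit of gradient, at the max
        assert d.sum() == out.size
        assert set(np.unique(d)) <= {0.0, 1.0}
        recovered = d * x
        win_max = pool.forward(x, training=True)
        assert np.allclose(recovered.sum(axis=(1, 2)), win_max.sum(axis=(1, 2)))

    def test_unpool_backward_gathers(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(1, 4, 4, 1)).astype(np.float32)
        pool = MaxPool2d(2)
        pooled = pool.forward(x, training=True)
        up = MaxUnpool2d(2)
        out = up.forward(pooled, pool.indices, training=True)
        dout = rng.normal(size=out.shape).astype(np.float32)
        d = up.backward(dout)
        assert d.shape == pooled.shape
        # gathered gradient equals dout at the scatter locations
        re_scattered = MaxUnpool2d(2).forward(d, pool.indices)
        mask = out != 0
        assert np.allclose(re_scattered[mask], dout[mask])

    def test_batchnorm_eval_uses_running_stats(self):
        rng = np.random.default_rng(8)
        bn = BatchNorm2d("b", 2, momentum=0.5)
        x = rng.normal(loc=3.0, size=(4, 8, 8, 2)).astype(np.float32)
        for _ in range(20):
            bn.forward(x, training=True)
        y = bn.forward(x, training=False)
        assert abs(float(y.mean())) < 0.2  # running stats converged to batch
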