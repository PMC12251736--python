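"""Contracts of the SPD, SimAM, SSPDConv and ESPPFCSPC blocks."""

import numpy as np
import pytest

from leafdet.nn import (
    ESPPFCSPC,
    ESPPFCSPCConfig,
    SSPDConv,
    SimAMConfig,
    Tensor,
    functional as F,
    simam_attention,
    spd_inverse,
    spd_transform,
)


class TestSPD:
    def test_enumerated_4x4(self):
        """Index-arithmetic oracle on a 4x4 map with values 0..15."""
        x = Tensor(np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4))
        y = spd_transform(x).data[0]
        assert y.shape == (4, 2, 2)
        # offset order (0,0), (1,0), (0,1), (1,1) over (row, col)
        np.testing.assert_array_equal(y[0], [[0, 2], [8, 10]])
        np.testing.assert_array_equal(y[1], [[1, 3], [9, 11]])
        np.testing.assert_array_equal(y[2], [[4, 6], [12, 14]])
        np.testing.assert_array_equal(y[3], [[5, 7], [13, 15]])

    def test_channel_expansion_and_halving(self, rng):
        x = Tensor(rng.random((2, 3, 640, 640), np.float32))
        y = spd_transform(x)
        assert y.shape == (2, 12, 320, 320)

    def test_roundtrip_identity(self, rng):
        x = rng.random((2, 5, 8, 12)).astype(np.float32)
        np.testing.assert_array_equal(spd_inverse(spd_transform(Tensor(x))), x)

    def test_element_count_conserved(self, rng):
        x = Tensor(rng.random((1, 7, 6, 6), np.float32))
        assert spd_transform(x).size == x.size

    def test_odd_dims_rejected(self, rng):
        with pytest.raises(ValueError):
            spd_transform(Tensor(np.zeros((1, 1, 5, 4), np.float32)))

    def test_differentiable(self, rng):
        x = Tensor(rng.random((1, 2, 4, 4), np.float32), requires_grad=True)
        spd_transform(x).sum().backward()
        np.testing.assert_array_equal(x.grad, np.ones_like(x.data))


class TestSimAM:
    def test_constant_channel_uniform_weight(self):
        """Zero variance -> energy 2 everywhere -> weight sigmoid(0.5)."""
        x = Tensor(np.full((1, 3, 6, 6), 4.0, np.float32))
        y = simam_attention(x, SimAMConfig(1e-4))
        w = 1.0 / (1.0 + np.exp(-0.5))
        np.testing.assert_allclose(y.data, w * x.data, rtol=1e-4)

    def test_shape_preserved(self, rng):
        x = Tensor(rng.random((2, 4, 5, 7), np.float32))
        assert simam_attention(x).shape == x.shape

    def test_weights_in_unit_interval(self, rng):
        x = Tensor(rng.normal(0, 3, (1, 2, 8, 8)).astype(np.float32))
        y = simam_attention(x)
        w = y.data / np.where(np.abs(x.data) < 1e-9, 1, x.data)
        assert (w[np.abs(x.data) > 1e-6] > 0).all()
        assert (w[np.abs(x.data) > 1e-6] < 1).all()

    def test_outlier_neuron_gets_larger_weight(self):
        x = np.zeros((1, 1, 4, 4), np.float32)
        x[0, 0, 2, 2] = 10.0
        y = simam_attention(Tensor(x)).data
        weights = np.zeros_like(x)
        # weight = output / input where input != 0; compare vs a near-mean one
        w_outlier = y[0, 0, 2, 2] / 10.0
        x2 = x.copy()
        x2[0, 0, 1, 1] = 0.05  # near the channel mean
        y2 = simam_attention(Tensor(x2)).data
        w_near = y2[0, 0, 1, 1] / 0.05
        assert w_outlier > w_near

    def test_no_learnable_parameters(self):
        from leafdet.nn import SimAM

        assert SimAM().num_params() == 0

    def test_batch_consistency(self, rng):
        """Per-sample statistics: results independent of batch composition."""
        a = rng.random((1, 3, 8, 8)).astype(np.float32)
        b = rng.random((1, 3, 8, 8)).astype(np.float32)
        solo = simam_attention(Tensor(a)).data
        pair = simam_attention(Tensor(np.concatenate([a, b]))).data[:1]
        np.testing.assert_allclose(solo, pair, rtol=1e-5)


class TestSSPDConv:
    def test_output_shape(self, rng):
        block = SSPDConv(8, 16, rng=rng)
        y = block(Tensor(rng.random((2, 8, 20, 20), np.float32)))
        assert y.shape == (2, 16, 10, 10)

    def test_constant_input_closed_form(self):
        """Identity-style 1x1 kernel on a constant map composes the SPD sum
        with the uniform SimAM weight sigmoid(0.5)."""
        block = SSPDConv(1, 1, k=1)
        block.conv.conv.weight.data[:] = 1.0  # sum the 4 SPD channels
        block.conv.bn.running_mean[:] = 0
        block.conv.bn.running_var[:] = 1
        block.conv.bn.eps = 0.0
        block.eval()
        x = Tensor(np.full((1, 1, 4, 4), 2.0, np.float32))
        y = block(x).data
        pre = 8.0  # 4 SPD channels x 2.0 through the all-ones kernel
        silu = pre / (1 + np.exp(-pre))
        expect = silu * (1 / (1 + np.exp(-0.5)))
        np.testing.assert_allclose(y, expect, rtol=1e-4)

    def test_odd_spatial_rejected(self, rng):
        with pytest.raises(ValueError):
            SSPDConv(2, 4)(Tensor(np.zeros((1, 2, 5, 6), np.float32)))

    def test_gradient_reaches_kernel(self, rng):
        block = SSPDConv(2, 4, rng=rng)
        y = block(Tensor(rng.random((1, 2, 8, 8), np.float32)))
        (y * y).sum().backward()
        assert block.conv.conv.weight.grad is not None
        assert np.abs(block.conv.conv.weight.grad).sum() > 0

    def test_simam_adds_no_parameters(self, rng):
        with_att = SSPDConv(4, 8, use_simam=True)
        without = SSPDConv(4, 8, use_simam=False)
        assert with_att.num_params() == without.num_params()


class TestESPPFCSPC:
    def test_shape_preserved(self, rng):
        cfg = ESPPFCSPCConfig(in_channels=32, out_channels=32, hidden_channels=16)
        block = ESPPFCSPC(cfg, rng=rng)
        y = block(Tensor(rng.random((1, 32, 20, 20), np.float32)))
        assert y.shape == (1, 32, 20, 20)

    @pytest.mark.parametrize("size", [13, 16, 20])
    def test_spatial_invariance_across_sizes(self, rng, size):
        cfg = ESPPFCSPCConfig(in_channels=8, out_channels=12, hidden_channels=4)
        block = ESPPFCSPC(cfg, rng=rng)
        y = block(Tensor(rng.random((1, 8, size, size), np.float32)))
        assert y.shape[2:] == (size, size)

    def test_serial_pools_equal_parallel_pools(self, rng):
        """Three serial k=5 stride-1 max-pools == parallel 5/9/13 pools."""
        x = Tensor(rng.normal(0, 1, (2, 3, 16, 16)).astype(np.float32))
        y1 = F.max_pool2d(x, 5, stride=1, padding=2)
        y2 = F.max_pool2d(y1, 5, stride=1, padding=2)
        y3 = F.max_pool2d(y2, 5, stride=1, padding=2)
        for serial, k in ((y1, 5), (y2, 9), (y3, 13)):
            parallel = F.max_pool2d(x, k, stride=1, padding=k // 2)
            np.testing.assert_array_equal(serial.data, parallel.data)

    def test_channel_mismatch_rejected(self, rng):
        block = ESPPFCSPC(ESPPFCSPCConfig(in_channels=16, out_channels=16))
        with pytest.raises(ValueError):
            block(Tensor(np.zeros((1, 8, 10, 10), np.float32)))

    def test_dilation_one_matches_plain_sppfcspc_contract(self, rng):
        """dilation_rate=1 keeps the same parameter count and output shape."""
        c1 = ESPPFCSPCConfig(in_channels=16, out_channels=16, hidden_channels=8,
                             dilation_rate=1)
        c2 = ESPPFCSPCConfig(in_channels=16, out_channels=16, hidden_channels=8,
                             dilation_rate=2)
        b1, b2 = ESPPFCSPC(c1), ESPPFCSPC(c2)
        assert b1.num_params() == b2.num_params()
        x = Tensor(np.random.default_rng(0).random((1, 16, 12, 12), np.float32))
        assert b1(x).shape == b2(x).shape == (1, 16, 12, 12)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ESPPFCSPCConfig(pool_kernel=4)
        with pytest.raises(ValueError):
            ESPPFCSPCConfig(dilation_rate=0)
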