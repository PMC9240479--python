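import numpy as np
import pytest

from weedseg.attention import (
    ResNet34Encoder,
    SEBasicBlock,
    SEModule,
    ShapeError,
    excitation,
    rescale,
    squeeze,
)
from weedseg.nn import Tensor, no_grad
from .oracles import excitation_loop, rescale_loop, squeeze_loop


class TestSqueeze:
    def test_constant_channel_gives_its_value(self):
        u = np.full((3, 5, 7), 0.0)
        u[1] = 3.0
        assert squeeze(u)[1] == pytest.approx(3.0)

    def test_small_map_mean(self):
        u = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        assert squeeze(u)[0] == pytest.approx(2.5)

    def test_single_pixel_identity(self):
        u = np.array([[[42.0]]])
        assert squeeze(u)[0] == pytest.approx(42.0)

    def test_matches_scalar_loop(self, rng):
        u = rng.standard_normal((3, 4, 5))
        np.testing.assert_allclose(squeeze(u), squeeze_loop(u), atol=1e-6)


class TestExcitation:
    def test_zero_descriptor_gives_half(self, rng):
        w1 = rng.standard_normal((2, 4))
        w2 = rng.standard_normal((4, 2))
        np.testing.assert_allclose(excitation(np.zeros(4), w1, w2), 0.5)

    def test_zero_second_layer_gives_half(self, rng):
        z = rng.standard_normal(2)
        np.testing.assert_allclose(
            excitation(z, np.eye(2), np.zeros((2, 2))), [0.5, 0.5])

    def test_weights_strictly_in_unit_interval(self, rng):
        for _ in range(20):
            z = rng.standard_normal(8)
            w1 = rng.standard_normal((2, 8)) * 0.5
            w2 = rng.standard_normal((8, 2)) * 0.5
            s = excitation(z, w1, w2)
            assert np.all(s > 0) and np.all(s < 1)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ShapeError):
            excitation(np.zeros(3), np.zeros((2, 4)), np.zeros((4, 2)))

    def test_matches_scalar_loop(self, rng):
        z = rng.standard_normal(6)
        w1 = rng.standard_normal((3, 6))
        w2 = rng.standard_normal((6, 3))
        np.testing.assert_allclose(excitation(z, w1, w2),
                                   excitation_loop(z, w1, w2), atol=1e-6)

    def test_reduction_must_divide_channels(self):
        SEModule(2, reduction=1)  # 2/1 ok
        with pytest.raises(ShapeError):
            SEModule(3, reduction=2)


class TestRescale:
    def test_unit_weights_identity(self, rng):
        u = rng.standard_normal((3, 4, 4))
        np.testing.assert_allclose(rescale(u, np.ones(3)), u)

    def test_zero_weights_zero_map(self, rng):
        u = rng.standard_normal((3, 4, 4))
        assert (rescale(u, np.zeros(3)) == 0).all()

    def test_contraction_for_unit_interval_weights(self, rng):
        u = rng.standard_normal((4, 3, 3))
        s = rng.uniform(0.01, 0.99, size=4)
        assert (np.abs(rescale(u, s)) <= np.abs(u) + 1e-12).all()

    def test_matches_scalar_loop(self, rng):
        u = rng.standard_normal((3, 4, 5))
        s = rng.uniform(0, 1, size=3)
        np.testing.assert_allclose(rescale(u, s), rescale_loop(u, s), atol=1e-6)


class TestSEBasicBlock:
    def test_zero_weights_zero_input_gives_zero(self):
        blk = SEBasicBlock(4, 4, use_se=True, reduction=2,
                           rng=np.random.default_rng(0))
        for p in (blk.conv1.weight, blk.conv2.weight):
            p.data[...] = 0.0
        x = Tensor(np.zeros((1, 4, 6, 6), dtype=np.float32))
        with no_grad():
            out = blk.eval()(x)
        assert (out.data == 0).all()

    def test_stride1_preserves_shape(self):
        blk = SEBasicBlock(8, 8, reduction=2, rng=np.random.default_rng(0))
        with no_grad():
            out = blk.eval()(Tensor(np.random.rand(2, 8, 10, 10).astype(np.float32)))
        assert out.shape == (2, 8, 10, 10)

    def test_stride2_halves_even_sizes(self):
        blk = SEBasicBlock(8, 16, stride=2, reduction=2,
                           rng=np.random.default_rng(0))
        with no_grad():
            out = blk.eval()(Tensor(np.random.rand(1, 8, 12, 12).astype(np.float32)))
        assert out.shape == (1, 16, 6, 6)

    def test_channel_mismatch_rejected(self):
        blk = SEBasicBlock(8, 8, reduction=2, rng=np.random.default_rng(0))
        with pytest.raises(ShapeError):
            blk(Tensor(np.zeros((1, 4, 6, 6), dtype=np.float32)))

    def test_pinned_unit_weights_recover_plain_block(self):
        """With the excitation sigmoid saturated at 1, the SE block must
        equal the identical plain residual block."""
        blk = SEBasicBlock(4, 4, use_se=True, reduction=2,
                           rng=np.random.default_rng(3))
        x = Tensor(np.random.default_rng(1).random((2, 4, 8, 8)).astype(np.float32))
        blk.eval()
        blk.se.fc2.bias.data[...] = 50.0   # sigmoid -> 1 for every channel
        blk.se.fc2.weight.data[...] = 0.0
        with no_grad():
            with_se = blk(x).data
            blk.use_se = False
            plain = blk(x).data
        np.testing.assert_allclose(with_se, plain, atol=1e-5)


class TestEncoder:
    @pytest.mark.parametrize("use_se", [True, False])
    def test_tap_shapes_64(self, use_se):
        enc = ResNet34Encoder(use_se=use_se, rng=np.random.default_rng(0)).eval()
        x = Tensor(np.random.rand(1, 3, 64, 64).astype(np.float32))
        with no_grad():
            taps = enc(x)
        shapes = [t.shape for t in taps]
        assert shapes == [(1, 64, 32, 32), (1, 64, 16, 16), (1, 128, 8, 8),
                          (1, 256, 4, 4), (1, 512, 2, 2)]

    def test_indivisible_size_rejected(self):
        enc = ResNet34Encoder(rng=np.random.default_rng(0)).eval()
        with pytest.raises(ShapeError):
            enc(Tensor(np.zeros((1, 3, 60, 60), dtype=np.float32)))

    def test_deterministic_given_weights(self):
        enc = ResNet34Encoder(rng=np.random.default_rng(0)).eval()
        x = Tensor(np.random.default_rng(5).random((1, 3, 64, 64)).astype(np.float32))
        with no_grad():
            a = enc(x)[-1].data.copy()
            b = enc(x)[-1].data.copy()
        np.testing.assert_array_equal(a, b)
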