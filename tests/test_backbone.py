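import numpy as np
import pytest

from tspnet import _autograd as ag
from tspnet._autograd import Tensor
from tspnet.backbone import (SDFE, TDFE, ParallelResidualBlock, Stem,
                             TSPNetConfig, decimation_stride, desk_config,
                             temporal_decimate)
from tspnet.core import ConfigurationError
from tspnet.model import TSPNet


def brute_force_parallel_block(x, block):
    """Direct loop evaluation of Σ_branches ReLU(BN(conv) + skip).

    Independent of the vectorised path: plain Python loops over output
    positions, "same" zero padding, evaluation-mode batch norm.
    """
    n, c, h, w = x.shape
    out = None
    for bi in range(block.n_branches):
        br = getattr(block, f"branch{bi}")
        conv, bn = br.body.conv, br.body.bn
        o, ci, k = conv.weight.shape
        stride, axis = conv.stride, conv.axis
        pad = k // 2
        length = w if axis == 3 else h
        l_out = (length + 2 * pad - k) // stride + 1
        y = np.zeros((n, o) + ((h, l_out) if axis == 3 else (l_out, w)))
        for ni in range(n):
            for oi in range(o):
                for a in range(h if axis == 3 else w):
                    for t in range(l_out):
                        acc = conv.bias.data[oi]
                        for cc in range(ci):
                            for j in range(k):
                                src = t * stride + j - pad
                                if 0 <= src < length:
                                    v = (x[ni, cc, a, src] if axis == 3
                                         else x[ni, cc, src, a])
                                    acc += conv.weight.data[oi, cc, j] * v
                        if axis == 3:
                            y[ni, oi, a, t] = acc
                        else:
                            y[ni, oi, t, a] = acc
        # evaluation-mode batch norm
        ybn = (bn.gamma.data[None, :, None, None]
               * (y - bn.running_mean[None, :, None, None])
               / np.sqrt(bn.running_var[None, :, None, None] + bn.eps)
               + bn.beta.data[None, :, None, None])
        if br.residual:
            if br.proj is not None:
                skip = np.zeros_like(ybn)
                for ni in range(n):
                    for oi in range(o):
                        for cc in range(ci):
                            if axis == 3:
                                skip[ni, oi] += (br.proj.weight.data[oi, cc, 0]
                                                 * x[ni, cc])
                            else:
                                skip[ni, oi] += (br.proj.weight.data[oi, cc, 0]
                                                 * x[ni, cc, ::stride, :][:skip.shape[2]])
                ybn = ybn + skip
            else:
                ybn = ybn + x
        branch_out = np.maximum(ybn, 0)
        out = branch_out if out is None else out + branch_out
    return out


class TestStem:
    def test_output_shape_and_width(self, tiny_config, rng):
        stem = Stem(tiny_config, np.random.default_rng(0))
        x = Tensor(rng.normal(size=(2, 1, 4, 16)))
        y = stem(x)
        assert y.shape == (2, tiny_config.tdfe_widths[0], 4, 16)

    def test_zero_input_zero_bias_gives_zero(self, tiny_config):
        stem = Stem(tiny_config, np.random.default_rng(0))
        stem.conv.bias.data[:] = 0
        stem.eval()
        y = stem(Tensor(np.zeros((1, 1, 4, 16))))
        assert np.abs(y.data).max() < 1e-12

    def test_impulse_support_is_kernel_width(self, tiny_config):
        """Pre-BN convolution of an impulse spans ≤ stem_kernel samples."""
        stem = Stem(tiny_config, np.random.default_rng(0))
        stem.conv.bias.data[:] = 0
        x = np.zeros((1, 1, 4, 16))
        x[0, 0, 2, 8] = 1.0
        y = stem.conv(Tensor(x)).data
        nz = np.nonzero(np.abs(y).sum(axis=(0, 1, 2)))[0]
        assert nz.min() >= 8 - 3 and nz.max() <= 8 + 3
        assert np.abs(y[0, :, [0, 1, 3], :]).max() == 0   # temporal conv only


class TestParallelResidualBlock:
    def test_zeroed_branches_with_identity_skip(self, rng):
        block = ParallelResidualBlock(4, 4, (1, 3), axis=3,
                                      rng=np.random.default_rng(1), dtype=np.float64)
        for i in range(2):
            br = getattr(block, f"branch{i}")
            br.body.conv.weight.data[:] = 0
            br.body.conv.bias.data[:] = 0
        block.eval()
        x = rng.normal(size=(2, 4, 3, 8))
        y = block(Tensor(x))
        np.testing.assert_allclose(y.data, 2 * np.maximum(x, 0), atol=1e-12)

    def test_zeroed_branches_non_residual_gives_zero(self, rng):
        block = ParallelResidualBlock(4, 4, (1, 3), axis=3, residual=False,
                                      rng=np.random.default_rng(1), dtype=np.float64)
        for i in range(2):
            br = getattr(block, f"branch{i}")
            br.body.conv.weight.data[:] = 0
            br.body.conv.bias.data[:] = 0
        block.eval()
        y = block(Tensor(rng.normal(size=(2, 4, 3, 8))))
        assert np.abs(y.data).max() == 0

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            ParallelResidualBlock(2, 2, (2,), axis=3)

    @pytest.mark.parametrize("axis,shape", [(3, (2, 4, 3, 6)), (2, (2, 4, 6, 3))])
    @pytest.mark.parametrize("trial", range(4))
    def test_matches_brute_force(self, axis, shape, trial):
        rng = np.random.default_rng(100 + trial)
        block = ParallelResidualBlock(4, 4, (1, 3), axis=axis,
                                      rng=rng, dtype=np.float64)
        # randomize BN stats so the oracle exercises them
        for i in range(block.n_branches):
            bn = getattr(block, f"branch{i}").body.bn
            bn.running_mean[:] = rng.normal(size=4)
            bn.running_var[:] = rng.uniform(0.5, 2.0, size=4)
            bn.gamma.data[:] = rng.uniform(0.5, 1.5, size=4)
            bn.beta.data[:] = rng.normal(size=4)
        block.eval()
        x = rng.normal(size=shape)
        fast = block(Tensor(x)).data
        slow = brute_force_parallel_block(x, block)
        np.testing.assert_allclose(fast, slow, atol=1e-5)


class TestTDFE:
    def test_channel_progression(self):
        cfg = desk_config(8, 32, tdfe_widths=(4, 6, 8), sdfe_width=10, w_max=8)
        tdfe = TDFE(cfg, np.random.default_rng(0))
        tdfe.eval()
        with ag.no_grad():
            y = tdfe(Tensor(np.random.default_rng(1).normal(size=(2, 4, 8, 32))))
        assert y.shape == (2, 8, 8, 32)

    def test_spatial_permutation_equivariance(self, rng):
        """Temporal-only convolutions commute with electrode reordering."""
        cfg = desk_config(6, 16, tdfe_widths=(4, 6, 8), sdfe_width=10, w_max=8,
                          dtype="float64")
        tdfe = TDFE(cfg, np.random.default_rng(2))
        tdfe.eval()
        x = rng.normal(size=(2, 4, 6, 16))
        perm = rng.permutation(6)
        with ag.no_grad():
            y = tdfe(Tensor(x)).data
            yp = tdfe(Tensor(x[:, :, perm, :])).data
        np.testing.assert_allclose(yp, y[:, :, perm, :], atol=1e-10)


class TestSDFE:
    def test_maxpool_halves_spatial(self):
        cfg = desk_config(16, 32, tdfe_widths=(4, 6, 8), sdfe_width=12, w_max=8)
        sdfe = SDFE(cfg, 8, np.random.default_rng(0))
        sdfe.eval()
        with ag.no_grad():
            y = sdfe(Tensor(np.random.default_rng(1)
                            .normal(size=(2, 8, 16, 32)).astype(np.float32)))
        assert y.shape == (2, 12, 8, 32)

    def test_stride2_variant_shape(self):
        cfg = desk_config(16, 32, tdfe_widths=(4, 6, 8), sdfe_width=12, w_max=8,
                          sdfe_pooling_mode="stride2")
        sdfe = SDFE(cfg, 8, np.random.default_rng(0))
        sdfe.eval()
        with ag.no_grad():
            y = sdfe(Tensor(np.random.default_rng(1)
                            .normal(size=(2, 8, 16, 32)).astype(np.float32)))
        assert y.shape == (2, 12, 8, 32)

    def test_temporal_permutation_equivariance(self, rng):
        """Spatial-only convolutions commute with time reordering (pre-pool)."""
        cfg = desk_config(8, 12, tdfe_widths=(2, 3, 4), sdfe_width=6, w_max=8,
                          dtype="float64")
        sdfe = SDFE(cfg, 4, np.random.default_rng(3))
        sdfe.eval()
        x = rng.normal(size=(2, 4, 8, 12))
        perm = rng.permutation(12)
        with ag.no_grad():
            y = sdfe.block(Tensor(x)).data
            yp = sdfe.block(Tensor(x[:, :, :, perm])).data
        np.testing.assert_allclose(yp, y[:, :, :, perm], atol=1e-10)


class TestTemporalDecimate:
    def test_study_scale_arithmetic(self):
        assert decimation_stride(1500, 64) == 24
        x = np.random.default_rng(0).normal(size=(1, 2, 4, 1500))
        assert temporal_decimate(x, 64).shape[-1] == 62

    def test_identity_when_short(self):
        x = np.random.default_rng(0).normal(size=(1, 2, 4, 64))
        np.testing.assert_array_equal(temporal_decimate(x, 64), x)

    def test_mean_preserving_on_constant(self):
        x = np.full((1, 1, 1, 100), 3.5)
        np.testing.assert_allclose(temporal_decimate(x, 10), 3.5)


class TestShapeContract:
    @pytest.mark.parametrize("n_ch,n_s,widths,sw,wmax", [
        (16, 128, (4, 6, 8), 10, 32),
        (8, 100, (2, 3, 4), 6, 16),
        (61, 64, (2, 3, 4), 6, 8),
    ])
    def test_backbone_composition(self, n_ch, n_s, widths, sw, wmax):
        cfg = desk_config(n_ch, n_s, tdfe_widths=widths, sdfe_width=sw, w_max=wmax)
        model = TSPNet(cfg)
        x = np.random.default_rng(0).normal(size=(2, n_ch, n_s))
        fm = model.feature_maps(x, tap="pre-tspfe")
        assert fm.values.shape[1] == sw
        assert fm.values.shape[2] == n_ch // 2
        assert fm.values.shape[3] <= wmax
        out = model.feature_maps(x, tap="tspfe")
        assert out.values.shape[1] == 2 * sw

    def test_config_variant_arithmetic(self):
        cfg = desk_config(16, 128)
        assert cfg.head_in_channels() == 2 * cfg.sdfe_width
        import dataclasses
        no_tspfe = dataclasses.replace(cfg, use_tspfe=False)
        assert no_tspfe.head_in_channels() == cfg.sdfe_width

    def test_strictly_increasing_widths_enforced(self):
        with pytest.raises(ConfigurationError):
            TSPNetConfig(tdfe_widths=(64, 64, 128))
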