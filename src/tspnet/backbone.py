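"""Temporal and spatial convolutional feature extractors.

The backbone is three stages applied to an epoch laid out as a
``1 × n_channels × n_samples`` map (feature channels × space × time):

* a stem: one 1×7 temporal convolution (+BN, ReLU) that widens to the first
  feature width;
* the temporal extractor (TDFE): three parallel-residual blocks with 1×1 and
  1×3 temporal kernels, widths 64 → 128 → 256 (desk-scale configs shrink
  these), convolving along time only;
* the spatial extractor (SDFE): three parallel residual branches with 1×1,
  3×1 and 5×1 spatial kernels at width 512, summed elementwise, followed by
  a 2:1 spatial reduction (max-pooling, or stride-2 convolution in the "NP"
  variant).

Ablation switches reproduce the named variants: ``tdfe_residual=False``
(TDFE-NR) drops the skip connections, ``use_tdfe``/``use_sdfe`` remove whole
stages, and ``sdfe_pooling_mode`` selects the spatial-reduction mechanism.

A final average-pooling step (``temporal_decimate``) bounds the temporal
extent before the time-spatial parallel head, whose similarity matrices are
W × W per feature channel and would be unmanageable at W = 1500.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from . import _autograd as ag
from .core import ConfigurationError
from .nn import BatchNorm, Conv1dAxis, Module

TEMPORAL_AXIS = 3
SPATIAL_AXIS = 2


@dataclass(frozen=True)
class TSPNetConfig:
    """Architecture hyperparameters and ablation-variant switches."""

    n_input_channels: int = 16
    n_samples: int = 1500
    n_classes: int = 6
    stem_kernel: int = 7
    tdfe_widths: tuple[int, ...] = (64, 128, 256)
    tdfe_kernels: tuple[int, ...] = (1, 3)
    sdfe_width: int = 512
    sdfe_kernels: tuple[int, ...] = (1, 3, 5)
    w_max: int = 64           # temporal extent cap ahead of the parallel head
    use_tdfe: bool = True
    tdfe_residual: bool = True
    use_sdfe: bool = True
    sdfe_pooling_mode: str = "maxpool"   # or "stride2" (the NP variant)
    use_tspfe: bool = True
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if list(self.tdfe_widths) != sorted(set(self.tdfe_widths)):
            raise ConfigurationError("tdfe_widths must be strictly increasing")
        for k in (self.stem_kernel, *self.tdfe_kernels, *self.sdfe_kernels):
            if k % 2 == 0:
                raise ConfigurationError(f"kernel sizes must be odd, got {k}")
        if self.w_max < 4:
            raise ConfigurationError("w_max must be at least 4")
        if self.sdfe_pooling_mode not in ("maxpool", "stride2"):
            raise ConfigurationError(
                f"unknown sdfe_pooling_mode {self.sdfe_pooling_mode!r}")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)

    # -- shape arithmetic --------------------------------------------------
    def backbone_out_channels(self) -> int:
        if self.use_sdfe:
            return self.sdfe_width
        return self.tdfe_widths[-1] if self.use_tdfe else self.tdfe_widths[0]

    def spatial_out(self) -> int:
        if not self.use_sdfe:
            return self.n_input_channels
        if self.sdfe_pooling_mode == "maxpool":
            return self.n_input_channels // 2
        return math.ceil(self.n_input_channels / 2)

    def temporal_out(self) -> int:
        return self.n_samples // decimation_stride(self.n_samples, self.w_max)

    def head_in_channels(self) -> int:
        c = self.backbone_out_channels()
        return 2 * c if self.use_tspfe else c

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "TSPNetConfig":
        d = json.loads(s)
        for k in ("tdfe_widths", "tdfe_kernels", "sdfe_kernels"):
            d[k] = tuple(d[k])
        return cls(**d)


def desk_config(n_input_channels: int = 16, n_samples: int = 256,
                **overrides) -> TSPNetConfig:
    """Reduced-width configuration for CPU-scale runs and tests.

    Keeps the full wiring (stem, three TDFE blocks, three SDFE branches,
    parallel head) at a fraction of the study widths.
    """
    defaults = dict(tdfe_widths=(12, 16, 24), sdfe_width=32, w_max=32)
    defaults.update(overrides)
    return TSPNetConfig(n_input_channels=n_input_channels,
                        n_samples=n_samples, **defaults)


@dataclass
class FeatureMap:
    """Intermediate activation: [feature channels × space × time] per trial."""

    values: np.ndarray  # [N, C, H, W]
    stage: str = ""     # post-stem / post-tdfe / post-sdfe / post-tspfe

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 4:
            raise ConfigurationError("feature maps are [N, C, H, W]")


# -- layers ----------------------------------------------------------------


class ConvBN(Module):
    """conv → BN, the Γ(·) mapping before any skip connection."""

    def __init__(self, cin, cout, k, axis, stride, rng, dtype):
        super().__init__()
        self.conv = Conv1dAxis(cin, cout, k, axis, stride, rng=rng, dtype=dtype)
        self.bn = BatchNorm(cout, dtype=dtype)

    def forward(self, x):
        return self.bn(self.conv(x))


class ResidualBranch(Module):
    """One branch: σ[Γ(x, w)] = ReLU(BN(conv(x)) + skip(x)).

    The skip is the identity when shapes allow, otherwise a 1×1 projection
    convolution; with ``residual=False`` (the NR wiring) it is omitted.
    """

    def __init__(self, cin, cout, k, axis, stride=1, residual=True,
                 rng=None, dtype=np.float32):
        super().__init__()
        self.body = ConvBN(cin, cout, k, axis, stride, rng, dtype)
        self.residual = residual
        self.proj = None
        if residual and (cin != cout or stride != 1):
            self.proj = Conv1dAxis(cin, cout, 1, axis, stride, bias=False,
                                   rng=rng, dtype=dtype)

    def forward(self, x):
        y = self.body(x)
        if self.residual:
            y = y + (self.proj(x) if self.proj is not None else x)
        return ag.relu(y)


class ParallelResidualBlock(Module):
    """Elementwise sum of residual branches with different kernel sizes."""

    def __init__(self, cin, cout, kernels, axis, stride=1, residual=True,
                 rng=None, dtype=np.float32):
        super().__init__()
        for i, k in enumerate(kernels):
            setattr(self, f"branch{i}", ResidualBranch(
                cin, cout, k, axis, stride, residual, rng, dtype))
        self.n_branches = len(kernels)

    def forward(self, x):
        out = None
        for i in range(self.n_branches):
            y = getattr(self, f"branch{i}")(x)
            out = y if out is None else out + y
        return out


class Stem(Module):
    """1×7 temporal convolution → BN → ReLU, one input feature channel."""

    def __init__(self, config: TSPNetConfig, rng):
        super().__init__()
        dtype = config.np_dtype
        self.conv = Conv1dAxis(1, config.tdfe_widths[0], config.stem_kernel,
                               TEMPORAL_AXIS, rng=rng, dtype=dtype)
        self.bn = BatchNorm(config.tdfe_widths[0], dtype=dtype)

    def forward(self, x):
        return ag.relu(self.bn(self.conv(x)))


class TDFE(Module):
    """Three successive parallel-residual blocks over the temporal axis."""

    def __init__(self, config: TSPNetConfig, rng):
        super().__init__()
        widths = config.tdfe_widths
        cin = widths[0]
        for i, cout in enumerate(widths):
            setattr(self, f"block{i}", ParallelResidualBlock(
                cin, cout, config.tdfe_kernels, TEMPORAL_AXIS,
                residual=config.tdfe_residual, rng=rng, dtype=config.np_dtype))
            cin = cout
        self.n_blocks = len(widths)

    def forward(self, x):
        for i in range(self.n_blocks):
            x = getattr(self, f"block{i}")(x)
        return x


class SDFE(Module):
    """Spatial-kernel residual branches summed, then 2:1 spatial reduction."""

    def __init__(self, config: TSPNetConfig, cin, rng):
        super().__init__()
        self.mode = config.sdfe_pooling_mode
        stride = 2 if self.mode == "stride2" else 1
        self.block = ParallelResidualBlock(
            cin, config.sdfe_width, config.sdfe_kernels, SPATIAL_AXIS,
            stride=stride, residual=True, rng=rng, dtype=config.np_dtype)

    def forward(self, x):
        if self.mode == "maxpool" and x.shape[SPATIAL_AXIS] < 2:
            raise ConfigurationError("spatial extent < 2 cannot be max-pooled")
        y = self.block(x)
        if self.mode == "maxpool":
            y = ag.maxpool_spatial(y, 2, 2)
        return y


# -- functional surface ----------------------------------------------------


def decimation_stride(w: int, w_max: int) -> int:
    """Smallest integer average-pooling stride making w // stride ≤ w_max."""
    return max(1, math.ceil(w / w_max))


def temporal_decimate(x: np.ndarray | FeatureMap, w_max: int) -> np.ndarray:
    """Average-pool the temporal axis down to at most ``w_max`` columns."""
    values = x.values if isinstance(x, FeatureMap) else np.asarray(x)
    w = values.shape[-1]
    s = decimation_stride(w, w_max)
    if s == 1:
        return values
    wo = w // s
    shape = values.shape[:-1] + (wo, s)
    return values[..., :wo * s].reshape(shape).mean(-1)
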