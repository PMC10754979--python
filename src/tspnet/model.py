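"""The full network: stem → TDFE → SDFE → temporal decimation → TSPFE → head.

``TSPNet`` wires the backbone stages and the time-spatial parallel head
according to a :class:`~tspnet.backbone.TSPNetConfig`, honouring every
ablation switch.  Checkpoints serialise all weights, running batch-norm
statistics and the config into a single ``.npz`` file.
"""

from __future__ import annotations

import json

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .backbone import (SDFE, TDFE, FeatureMap, Stem, TSPNetConfig,
                       decimation_stride)
from .core import ConfigurationError
from .nn import Module
from .tspfe import TSPFE, ClassifierHead

TAP_POINTS = ("post-stem", "post-tdfe", "post-sdfe", "pre-tspfe", "tspfe")


class TSPNet(Module):
    def __init__(self, config: TSPNetConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        dtype = config.np_dtype
        self.stem = Stem(config, rng)
        if config.use_tdfe:
            self.tdfe = TDFE(config, rng)
        if config.use_sdfe:
            cin = config.tdfe_widths[-1] if config.use_tdfe else config.tdfe_widths[0]
            self.sdfe = SDFE(config, cin, rng)
        if config.use_tspfe:
            self.tspfe = TSPFE(config.backbone_out_channels(),
                               config.spatial_out(), rng=rng, dtype=dtype)
        self.head = ClassifierHead(config.head_in_channels(),
                                   config.n_classes, rng=rng, dtype=dtype)

    # -- forward passes ----------------------------------------------------
    def _as_input(self, epochs_data: np.ndarray) -> Tensor:
        x = np.asarray(epochs_data, dtype=self.config.np_dtype)
        if x.ndim != 3:
            raise ConfigurationError("expected [n_trials, n_channels, n_samples]")
        return Tensor(x[:, None])  # one input feature channel

    def features(self, epochs_data: np.ndarray, tap: str = "tspfe") -> Tensor:
        if tap not in TAP_POINTS:
            raise ConfigurationError(f"unknown tap point {tap!r}; use {TAP_POINTS}")
        x = self.stem(self._as_input(epochs_data))
        if tap == "post-stem":
            return x
        if self.config.use_tdfe:
            x = self.tdfe(x)
        if tap == "post-tdfe":
            return x
        if self.config.use_sdfe:
            x = self.sdfe(x)
        if tap == "post-sdfe":
            return x
        s = decimation_stride(x.shape[3], self.config.w_max)
        x = ag.avgpool_temporal(x, s)
        if tap == "pre-tspfe":
            return x
        if self.config.use_tspfe:
            x = self.tspfe(x)
        return x

    def forward(self, epochs_data: np.ndarray) -> Tensor:
        """Logits [n_trials, n_classes]."""
        return self.head(self.features(epochs_data))

    def predict_proba(self, epochs_data: np.ndarray,
                      batch_size: int = 64) -> np.ndarray:
        """Class probabilities in evaluation mode (deterministic)."""
        was_training = self.training
        self.eval()
        out = []
        with ag.no_grad():
            for i in range(0, len(epochs_data), batch_size):
                logits = self.forward(epochs_data[i:i + batch_size])
                out.append(ag.softmax(logits, axis=1).data)
        self.train(was_training)
        return np.concatenate(out, axis=0)

    def predict(self, epochs_data: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Argmax class per trial; ties resolve to the lowest class index."""
        return np.argmax(self.predict_proba(epochs_data, batch_size), axis=1)

    def feature_maps(self, epochs_data: np.ndarray, tap: str = "tspfe",
                     batch_size: int = 64) -> FeatureMap:
        """Per-trial activations at a tap point, in evaluation mode."""
        was_training = self.training
        self.eval()
        out = []
        with ag.no_grad():
            for i in range(0, len(epochs_data), batch_size):
                out.append(self.features(epochs_data[i:i + batch_size], tap).data)
        self.train(was_training)
        return FeatureMap(np.concatenate(out, axis=0), stage=tap)

    # -- serialisation -----------------------------------------------------
    def save(self, path) -> None:
        state = self.state_dict()
        state["__config__"] = np.frombuffer(
            self.config.to_json().encode(), dtype=np.uint8)
        np.savez(path, **state)

    @classmethod
    def load(cls, path) -> "TSPNet":
        with np.load(path) as f:
            cfg = TSPNetConfig.from_json(bytes(f["__config__"]).decode())
            model = cls(cfg)
            model.load_state_dict({k: f[k] for k in f.files if k != "__config__"})
        return model

    def summary(self) -> str:
        cfg = self.config
        lines = [f"TSPNet({cfg.n_input_channels} ch × {cfg.n_samples} samples)"]
        shapes = [("stem", cfg.tdfe_widths[0], cfg.n_input_channels, cfg.n_samples)]
        if cfg.use_tdfe:
            for w in cfg.tdfe_widths:
                shapes.append(("tdfe", w, cfg.n_input_channels, cfg.n_samples))
        if cfg.use_sdfe:
            shapes.append(("sdfe", cfg.sdfe_width, cfg.spatial_out(), cfg.n_samples))
        shapes.append(("decimate", shapes[-1][1], shapes[-1][2], cfg.temporal_out()))
        if cfg.use_tspfe:
            shapes.append(("tspfe", cfg.head_in_channels(), shapes[-1][2],
                           cfg.temporal_out()))
        for name, c, h, w in shapes:
            lines.append(f"  {name:9s} [{c} × {h} × {w}]")
        n_params = sum(p.data.size for p in self.parameters())
        lines.append(f"  head      [{cfg.n_classes}]   ({n_params:,} parameters)")
        return "\n".join(lines)
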