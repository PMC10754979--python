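"""Shared domain types: labeled epoch sets, electrode montages, class names.

The package works on epoched motor-imagery EEG: ``trials × channels × time``
arrays with one of six upper-limb class labels per trial (hand open/close,
forearm supination/pronation, elbow flexion/extension).  Two built-in
recording profiles are supported: a 16-channel 10-20 layout (OpenBCI
Cyton+Daisy ordering) and a 61-channel extended 10-10 layout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np

#: Fixed package-wide bijection between class index and movement name.
CLASS_NAMES: tuple[str, ...] = (
    "hand open",
    "hand close",
    "forearm supination",
    "forearm pronation",
    "elbow flexion",
    "elbow extension",
)

N_CLASSES = len(CLASS_NAMES)

PROFILE_16 = "dataset_I_16ch"
PROFILE_61 = "dataset_II_61ch"

# OpenBCI Cyton+Daisy default 16-electrode 10-20 assignment, board order.
_CHANNELS_16 = (
    "Fp1", "Fp2", "C3", "C4", "P7", "P8", "O1", "O2",
    "F7", "F8", "F3", "F4", "T7", "T8", "P3", "P4",
)

# 61-channel extended 10-10 grid (frontal through occipital rows).
_CHANNELS_61 = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)


class ConfigurationError(ValueError):
    """Raised for unknown profiles, bands, variants, or invalid settings."""


class ValidationError(ValueError):
    """Raised when an epoch set violates its invariants."""


@dataclass(frozen=True)
class ClassLabel:
    index: int
    name: str = ""

    def __post_init__(self):
        if not 0 <= self.index < N_CLASSES:
            raise ConfigurationError(f"class index {self.index} out of range")
        expected = CLASS_NAMES[self.index]
        if self.name and self.name != expected:
            raise ConfigurationError(
                f"class {self.index} is named {expected!r}, not {self.name!r}")
        if not self.name:
            object.__setattr__(self, "name", expected)


# -- montage ---------------------------------------------------------------

_ROW_AP = {"FP": 4.0, "AF": 3.0, "F": 2.0, "FC": 1.0, "C": 0.0,
           "CP": -1.0, "P": -2.0, "PO": -3.0, "O": -4.0}
# Temporal-line labels alias onto the adjacent row at full lateral extent.
_T_ALIASES = {"T": "C", "FT": "FC", "TP": "CP"}


def _electrode_grid(name: str) -> tuple[float, float]:
    """Map a 10-10 electrode label to (anterior-posterior, lateral) grid units.

    One unit is one 10%-of-arc step from the vertex; left is negative.
    """
    m = re.fullmatch(r"([A-Za-z]+?)([zZ]|\d+)", name)
    if m is None:
        raise ConfigurationError(f"unrecognised electrode label {name!r}")
    row, num = m.group(1).upper(), m.group(2)
    if row in _T_ALIASES:
        base, lat = _T_ALIASES[row], 4.0
    else:
        base = row
        if num in ("z", "Z", ""):
            lat = 0.0
        else:
            lat = (int(num) + 1) // 2
    if base not in _ROW_AP:
        raise ConfigurationError(f"unrecognised electrode label {name!r}")
    if num not in ("z", "Z", "") and int(num) % 2 == 1:
        lat = -abs(lat)
    return _ROW_AP[base], float(lat)


@dataclass(frozen=True)
class Montage:
    """Named electrodes with schematic 2-D positions on the unit disc.

    Positions come from an azimuthal projection of the idealized 10-20/10-10
    grid: x = lateral arc fraction, y = anterior-posterior arc fraction, so
    the vertex (Cz) sits at the origin and the outer 10% ring at radius 0.8.
    """

    channel_names: tuple[str, ...]
    positions: np.ndarray  # [n, 2]

    def __post_init__(self):
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ConfigurationError("duplicate electrode names in montage")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.channel_names), 2):
            raise ConfigurationError("positions must be [n_channels, 2]")
        if (np.linalg.norm(pos, axis=1) > 1.0 + 1e-9).any():
            raise ConfigurationError("electrode positions must lie in the unit disc")
        object.__setattr__(self, "positions", pos)

    @classmethod
    def from_names(cls, names) -> "Montage":
        pos = np.array([_electrode_grid(n)[::-1] for n in names]) / 5.0
        return cls(tuple(names), pos)

    def index(self, name: str) -> int:
        return self.channel_names.index(name)

    def to_tsv(self) -> str:
        lines = [f"{n}\t{x:.4f}\t{y:.4f}"
                 for n, (x, y) in zip(self.channel_names, self.positions)]
        return "\n".join(lines) + "\n"

    def __len__(self):
        return len(self.channel_names)


def default_montage(profile: str) -> Montage:
    """Built-in montage for a recording profile (16- or 61-channel)."""
    if profile == PROFILE_16:
        return Montage.from_names(_CHANNELS_16)
    if profile == PROFILE_61:
        return Montage.from_names(_CHANNELS_61)
    raise ConfigurationError(f"unknown profile {profile!r}")


# -- epoch sets ------------------------------------------------------------


@dataclass
class EpochSet:
    """Labeled epoched EEG: ``data[trial, channel, sample]`` plus metadata."""

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = ()
    subject_id: str | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValidationError("data must be trials × channels × samples")
        if self.labels.shape != (self.data.shape[0],):
            raise ValidationError("one label per trial required")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= N_CLASSES):
            bad = int(np.argmax((self.labels < 0) | (self.labels >= N_CLASSES)))
            raise ValidationError(
                f"label {self.labels[bad]} at trial {bad} outside 0..{N_CLASSES - 1}")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.channel_names and len(self.channel_names) != self.data.shape[1]:
            raise ValidationError("channel_names length must match n_channels")
        self.channel_names = tuple(self.channel_names)
        if not np.isfinite(self.data).all():
            t, c, _ = np.unravel_index(
                int(np.argmin(np.isfinite(self.data))), self.data.shape)
            raise ValidationError(f"non-finite value at trial {t}, channel {c}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def select(self, idx) -> "EpochSet":
        return replace(self, data=self.data[idx], labels=self.labels[idx])

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=N_CLASSES)


def normalize_epochs(epochs: EpochSet) -> EpochSet:
    """Z-score every trial/channel trace along time (mean 0, SD 1).

    Channels with zero variance map to all-zeros.  Idempotent within
    numerical tolerance; labels are untouched.
    """
    mu = epochs.data.mean(axis=2, keepdims=True)
    sd = epochs.data.std(axis=2, keepdims=True)
    centered = epochs.data - mu
    out = np.divide(centered, sd, out=np.zeros_like(centered), where=sd > 0)
    return replace(epochs, data=out)
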