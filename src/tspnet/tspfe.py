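"""Time-spatial parallel feature extractor and the classification head.

The parallel head decorrelates temporal and spatial structure: each feature
channel's H × W slice X is mapped through a shared orthogonal projection P
and diagonal scaling D into a W × W similarity matrix

    Q = (P X)ᵀ D (P X),

whose column- and row-softmax normalisations act as two attention maps.
The two projected branches F_c = X·softmax(Q) and F_r = X·softmax(Qᵀ) are
each reweighted by a ReLU gate (a 1×1 convolution across feature channels)
and concatenated, doubling the channel count.  Global average pooling, a
fully connected layer and a softmax produce six class probabilities; the
training criterion is weighted cross-entropy.

P is kept exactly orthogonal by construction: it is the matrix exponential
of the skew-symmetric part of an unconstrained square generator, so
orthogonality survives any number of gradient steps.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .core import ConfigurationError
from .nn import Linear, Module, Parameter

# -- functional operations (NumPy in, NumPy out) ---------------------------


def orthogonalize(a: np.ndarray) -> np.ndarray:
    """P = exp(A − Aᵀ); orthogonal for any square A (exp of skew is in SO(n))."""
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"generator must be square, got {a.shape}")
    from scipy.linalg import expm
    return expm(a - a.T)


def similarity_matrix(x: np.ndarray, p: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Q = (PX)ᵀ D (PX) for one or many feature channels.

    ``x`` may be [H, W] or [..., H, W]; P is [H, H], d the diagonal of D.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-2] != p.shape[0]:
        raise ValueError(f"H mismatch: X has {x.shape[-2]} rows, P is {p.shape}")
    px = np.einsum("ij,...jw->...iw", p, x)
    return np.einsum("...hw,h,...hv->...wv", px, np.asarray(d, dtype=float), px)


def normalize_similarity(q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-softmax of Q and of Qᵀ: every column of each output sums to 1."""
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != q.shape[-2]:
        raise ValueError("Q must be square")

    def _colsoftmax(m):
        z = m - m.max(axis=-2, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-2, keepdims=True)

    return _colsoftmax(q), _colsoftmax(np.swapaxes(q, -1, -2))


def parallel_project(x: np.ndarray, qc: np.ndarray, qr: np.ndarray):
    """F_c = X·Q_c and F_r = X·Q_r, per feature channel."""
    x, qc, qr = (np.asarray(a, dtype=float) for a in (x, qc, qr))
    if x.shape[-1] != qc.shape[-2] or qc.shape != qr.shape:
        raise ValueError("shapes not conformable for X·Q")
    return np.matmul(x, qc), np.matmul(x, qr)


def gated_features(f: np.ndarray, w_f: np.ndarray, b_f: float) -> np.ndarray:
    """F ⊙ ReLU(w_f·F + b_f): the gate is one 1×1 conv across channels.

    ``f`` is [..., C, H, W] (or a bare scalar/array for the degenerate case
    where w_f is scalar); the single gate channel broadcasts across C.
    """
    f = np.asarray(f, dtype=float)
    w_f = np.asarray(w_f, dtype=float)
    if w_f.ndim == 0:
        gate = np.maximum(w_f * f + b_f, 0.0)
    else:
        lin = np.einsum("...chw,c->...hw", f, w_f) + b_f
        gate = np.maximum(lin, 0.0)[..., None, :, :]
    return f * gate


def cross_entropy_loss(probabilities: np.ndarray, labels: np.ndarray,
                       class_weights: np.ndarray | None = None,
                       eps: float = 1e-12) -> float:
    """Weighted multiclass cross-entropy, mean over trials.

    loss = −(1/N) Σ_n w_{y_n} ln p_{n, y_n}; a zero probability at the true
    class is clamped at ``eps`` with a warning.
    """
    p = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels)
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-5):
        raise ValueError("probability rows must sum to 1")
    w = np.ones(p.shape[1]) if class_weights is None else np.asarray(class_weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("class weights must be positive")
    true_p = p[np.arange(len(labels)), labels]
    if (true_p < eps).any():
        warnings.warn("zero probability at the true class clamped to eps")
        true_p = np.maximum(true_p, eps)
    return float(-(w[labels] * np.log(true_p)).mean())


# -- differentiable modules ------------------------------------------------


class TSPFE(Module):
    """The parallel head as a differentiable layer over [N, C, H, W] maps.

    One (P, D) pair is shared across all feature channels; the two branch
    gates carry separate parameters.
    """

    def __init__(self, n_channels: int, h: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.generator = Parameter(np.zeros((h, h), dtype=np.float64))
        self.diag = Parameter(np.ones(h, dtype=np.float64))
        # depthwise ReLU gate, identity at init (w=0, b=1).  A gate shared
        # across all feature channels has a catastrophic absorbing state:
        # once ReLU(w·F+b) closes over the whole (all-positive) map its
        # gradient vanishes and the entire head emits zeros forever.  One
        # scalar gate weight/bias per channel confines any such closure to
        # single channels.
        self.gate_c_w = Parameter(np.zeros(n_channels, dtype=dtype))
        self.gate_c_b = Parameter(np.ones(n_channels, dtype=dtype))
        self.gate_r_w = Parameter(np.zeros(n_channels, dtype=dtype))
        self.gate_r_b = Parameter(np.ones(n_channels, dtype=dtype))

    def orthogonal(self) -> np.ndarray:
        """Current P (evaluated outside the tape)."""
        with ag.no_grad():
            return ag.expm_skew(self.generator).data

    def forward(self, x: Tensor) -> Tensor:
        h = x.shape[2]
        if h != self.generator.shape[0]:
            raise ConfigurationError(
                f"head built for H={self.generator.shape[0]}, got H={h}")
        # P and D live in float64 for the matrix exponential; they enter the
        # graph in the feature dtype so activations stay single precision
        p = ag.cast(ag.expm_skew(self.generator), x.data.dtype)
        d = ag.cast(ag.reshape(self.diag, (-1, 1)), x.data.dtype)
        px = ag.matmul(p, x)                       # [N,C,H,W], P broadcasts
        dpx = ag.mul(px, d)
        q = ag.matmul(ag.transpose_last2(px), dpx)  # [N,C,W,W]
        qc = ag.softmax(q, axis=-2)
        qr = ag.softmax(ag.transpose_last2(q), axis=-2)
        fc = ag.matmul(x, qc)
        fr = ag.matmul(x, qr)
        fc = ag.mul(fc, self._gate(fc, self.gate_c_w, self.gate_c_b))
        fr = ag.mul(fr, self._gate(fr, self.gate_r_w, self.gate_r_b))
        return ag.concat([fc, fr], axis=1)

    @staticmethod
    def _gate(f: Tensor, w: Parameter, b: Parameter) -> Tensor:
        wc = ag.reshape(w, (-1, 1, 1))
        bc = ag.reshape(b, (-1, 1, 1))
        return ag.relu(ag.add(ag.mul(f, wc), bc))


class ClassifierHead(Module):
    """Global average pooling → fully connected → (log-)softmax."""

    def __init__(self, in_channels: int, n_classes: int = 6,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        self.fc = Linear(in_channels, n_classes, rng=rng, dtype=dtype)
        # zero-init the classifier: training starts at the uniform prediction
        # (loss ln 6) so early gradients discriminate between classes instead
        # of merely shrinking large random logits — with a ReLU gate upstream
        # the shrink direction can slam the gate shut irrecoverably
        self.fc.weight.data[:] = 0
        self.fc.bias.data[:] = 0

    def forward(self, x: Tensor) -> Tensor:
        """Returns logits [N, n_classes]; apply softmax for probabilities."""
        pooled = ag.mean(x, axis=(2, 3))           # GAP over space and time
        return self.fc(pooled)


def cross_entropy_from_logits(logits: Tensor, labels: np.ndarray,
                              class_weights: np.ndarray | None = None) -> Tensor:
    """Differentiable Eq-style loss computed stably via log-softmax."""
    n, k = logits.shape
    w = np.ones(k) if class_weights is None else np.asarray(class_weights, dtype=float)
    onehot = np.zeros((n, k), dtype=logits.data.dtype)
    onehot[np.arange(n), labels] = w[labels] / n
    lp = ag.log_softmax(logits, axis=1)
    return -ag.sum_(ag.mul(lp, Tensor(onehot)))
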