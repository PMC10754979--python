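"""Training and evaluation protocol.

Per subject: stratified 70/30 train/test splits, re-drawn for each of 10
repetitions; ADAM with gradient-norm clipping and a step-decay learning
rate; accuracy as the criterion; pooled-variance two-sample t-tests between
methods; and the six-variant ablation matrix (full network, no-TDFE,
TDFE-NR, no-SDFE, SDFE-NP, no-TSPFE) on shared partition seeds for paired
comparison.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from ._kernels import _adam_update
from .backbone import TSPNetConfig
from .core import ConfigurationError, EpochSet, normalize_epochs
from .model import TSPNet
from .tspfe import cross_entropy_from_logits

ABLATION_VARIANTS: dict[str, dict] = {
    "TSPNet-w/o-TDFE": {"use_tdfe": False},
    "TSPNet-TDFE-NR": {"tdfe_residual": False},
    "TSPNet-w/o-SDFE": {"use_sdfe": False},
    "TSPNet-SDFE-NP": {"sdfe_pooling_mode": "stride2"},
    "TSPNet-w/o-TSPFE": {"use_tspfe": False},
    "TSPNet": {},
}


@dataclass(frozen=True)
class OptimizerProfile:
    """ADAM settings; the defaults are the study-scale training profile."""

    initial_learn_rate: float = 0.001
    gradient_threshold: float = 1.0
    max_epochs: int = 1000
    mini_batch_size: int = 64
    learn_rate_drop_factor: float = 0.1
    learn_rate_drop_period: int = 500
    squared_gradient_decay: float = 0.999
    gradient_decay: float = 0.9

    def __post_init__(self):
        vals = dataclasses.astuple(self)
        if any(v <= 0 for v in vals):
            raise ConfigurationError("all optimizer settings must be positive")
        if not 0 < self.learn_rate_drop_factor <= 1:
            raise ConfigurationError("drop factor must be in (0, 1]")

    def learning_rate(self, epoch: int) -> float:
        """Step-decay schedule: ×drop_factor every drop_period epochs."""
        return self.initial_learn_rate * (
            self.learn_rate_drop_factor ** (epoch // self.learn_rate_drop_period))


def paper_profile() -> OptimizerProfile:
    return OptimizerProfile()


def desk_profile(max_epochs: int = 40, mini_batch_size: int = 16,
                 initial_learn_rate: float = 0.005,
                 learn_rate_drop_period: int = 30) -> OptimizerProfile:
    """CPU-scale training settings used by the bundled experiments.

    Smaller batches and a higher initial rate than the study profile: the
    desk problem has two orders of magnitude fewer gradient steps available,
    and the late ×0.1 drop settles the final epochs.
    """
    return OptimizerProfile(initial_learn_rate=initial_learn_rate,
                            max_epochs=max_epochs,
                            mini_batch_size=mini_batch_size,
                            learn_rate_drop_period=learn_rate_drop_period)


@dataclass
class EvalReport:
    accuracies: list[float]
    seeds: list[int]
    config_fingerprint: str

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        """Sample standard deviation over partitions (0 for a single one)."""
        if len(self.accuracies) < 2:
            return 0.0
        return float(np.std(self.accuracies, ddof=1))

    def as_dict(self) -> dict:
        return {"accuracies": list(map(float, self.accuracies)),
                "mean": self.mean, "sd": self.sd,
                "seeds": list(map(int, self.seeds)),
                "config_fingerprint": self.config_fingerprint}


def _fingerprint(config: TSPNetConfig, profile: OptimizerProfile) -> str:
    blob = config.to_json() + repr(dataclasses.astuple(profile))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def stratified_split(epochs: EpochSet, train_fraction: float = 0.7,
                     seed: int = 0) -> tuple[EpochSet, EpochSet]:
    """Per-class 70/30 split: both partitions balanced, disjoint, exhaustive."""
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(epochs.labels):
        idx = np.flatnonzero(epochs.labels == cls)
        if idx.size < 2:
            raise ConfigurationError(f"class {cls} has fewer than 2 trials")
        rng.shuffle(idx)
        n_train = int(np.floor(train_fraction * idx.size))
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    train_idx = np.sort(np.concatenate(train_idx))
    test_idx = np.sort(np.concatenate(test_idx))
    return epochs.select(train_idx), epochs.select(test_idx)


def train_model(train: EpochSet, config: TSPNetConfig,
                profile: OptimizerProfile, seed: int = 0,
                model: TSPNet | None = None) -> tuple[TSPNet, list[float]]:
    """ADAM training with gradient clipping and step-decay learning rate.

    Returns the trained model and the per-epoch mean loss trajectory.  The
    run is fully seeded: weight init comes from ``config.seed`` and batch
    shuffling from ``seed``.
    """
    if model is None:
        model = TSPNet(replace(config, seed=seed))
    data = normalize_epochs(train).data
    labels = train.labels
    params = model.parameters()
    m = [np.zeros_like(p.data) for p in params]
    v = [np.zeros_like(p.data) for p in params]
    rng = np.random.default_rng(seed)
    step = 0
    trajectory: list[float] = []
    model.train()
    for epoch in range(profile.max_epochs):
        lr = profile.learning_rate(epoch)
        order = rng.permutation(len(data))
        epoch_losses = []
        for start in range(0, len(order), profile.mini_batch_size):
            batch = order[start:start + profile.mini_batch_size]
            model.zero_grad()
            logits = model.forward(data[batch])
            loss = cross_entropy_from_logits(logits, labels[batch])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch starting {start}")
            loss.backward()
            grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                     for p in params]
            step += 1
            b1, b2 = profile.gradient_decay, profile.squared_gradient_decay
            bc1, bc2 = 1 - b1 ** step, 1 - b2 ** step
            for p, g, mi, vi in zip(params, grads, m, v):
                # fused per-learnable L2 clip + ADAM moment/parameter update
                _adam_update(p.data, np.ascontiguousarray(g), mi, vi, lr,
                             b1, b2, bc1, bc2, profile.gradient_threshold,
                             1e-8)
            epoch_losses.append(float(loss.data))
        trajectory.append(float(np.mean(epoch_losses)))
    model.eval()
    return model, trajectory


def evaluate(model: TSPNet, test: EpochSet) -> float:
    """Fraction of test trials whose argmax class matches the label."""
    if test.n_trials == 0:
        raise ConfigurationError("test set is empty")
    pred = model.predict(normalize_epochs(test).data)
    return float(np.mean(pred == test.labels))


def repeated_evaluation(epochs: EpochSet, config: TSPNetConfig,
                        profile: OptimizerProfile, n_partitions: int = 10,
                        base_seed: int = 0) -> EvalReport:
    """Split → train → evaluate over ``n_partitions`` re-drawn shuffles."""
    accuracies, seeds = [], []
    for i in range(n_partitions):
        seed = base_seed + i
        train, test = stratified_split(epochs, seed=seed)
        model, _ = train_model(train, config, profile, seed=seed)
        accuracies.append(evaluate(model, test))
        seeds.append(seed)
    return EvalReport(accuracies, seeds, _fingerprint(config, profile))


def two_sample_t_test(a, b) -> tuple[float, float]:
    """Pooled-variance two-sided t-test (equal unknown variances).

    Degenerate zero-variance inputs resolve analytically: equal means give
    (0, 1); unequal means give (±inf, 0) with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("each sample needs at least 2 observations")
    na, nb = a.size, b.size
    pooled = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
              / (na + nb - 2))
    diff = a.mean() - b.mean()
    if pooled == 0:
        if diff == 0:
            return 0.0, 1.0
        warnings.warn("zero pooled variance with unequal means")
        return float(np.sign(diff) * np.inf), 0.0
    t = diff / np.sqrt(pooled * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), df=na + nb - 2)
    return float(t), float(p)


def ablation_matrix(epochs: EpochSet, base_config: TSPNetConfig,
                    profile: OptimizerProfile, n_partitions: int = 10,
                    base_seed: int = 0) -> dict[str, dict]:
    """Evaluate the six named variants on identical partition seeds.

    Every variant reuses the same split seeds, so comparisons against the
    full network are paired; each row carries the pooled t-test vs TSPNet.
    """
    reports = {name: repeated_evaluation(
        epochs, replace(base_config, **flags), profile,
        n_partitions=n_partitions, base_seed=base_seed)
        for name, flags in ABLATION_VARIANTS.items()}
    full = reports["TSPNet"]
    table = {}
    for name, rep in reports.items():
        row = rep.as_dict()
        if name != "TSPNet" and len(rep.accuracies) >= 2:
            t, p = two_sample_t_test(rep.accuracies, full.accuracies)
            row["t_vs_tspnet"], row["p_vs_tspnet"] = t, p
        table[name] = row
    return table
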