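"""Network building blocks: shared feature extractor, gradient-reversed
per-source domain discriminators, per-source category classifiers.

The feature extractor is a compact three-convolution EEG backbone:

====================  =================  ==================
layer                 kernel             output
====================  =================  ==================
temporal conv, F1     (1, fs/2 + 1)      (F1, ch, T)
batch norm            --                 (F1, ch, T)
spatial conv, F2      (ch, 1)            (F2, 1, T)
batch norm + ReLU     --                 (F2, 1, T)
avg pool              (1, 2)             (F2, 1, T/2)
temporal conv, F2     (1, fs/5 + 1)      (F2, 1, T/2)
batch norm + ReLU     --                 (F2, 1, T/2)
avg pool              (1, 5)             (F2, 1, T/10)
dropout (maps)        --                 (F2, 1, T/10)
flatten               --                 F2 x T/10
====================  =================  ==================

Both temporal convolutions use length-preserving (same) zero padding; the
odd kernel lengths fs/2+1 and fs/5+1 make this exact.  The first learns
band-pass-like temporal filters at ~2 Hz resolution, the second collapses
the channel dimension into learned spatial filters, the third summarises
~200 ms of the downsampled time course.  Each discriminator and classifier
is a single affine layer on the flattened F2*T/10 feature followed by
softmax over 2 classes (index 1 = "target domain" / "deviant").
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .errors import ConfigurationError
from .nn import (Adam, AvgPool1xK, BatchNorm2d, Conv2d, Dropout2d, Flatten,
                 GradReverse, Linear, ReLU, Sequential, softmax)

__all__ = ["ModelConfig", "build_feature_extractor", "Head",
           "feature_forward", "head_forward", "P3MSDANet",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    Defaults are the published operating point: F1=4 temporal filters,
    F2=8 spatial filters, dropout 0.2, 61 channels, 100 samples at 100 Hz
    (one-second epochs), which yields an 80-dimensional feature.
    """

    F1: int = 4
    F2: int = 8
    p_dropout: float = 0.2
    ch: int = 61
    T: int = 100
    fs: float = 100.0

    def __post_init__(self) -> None:
        if self.T % 10:
            raise ConfigurationError("T must be divisible by 10")
        for frac in (2, 5):
            k = self.fs / frac + 1
            if k != int(k) or int(k) % 2 == 0:
                raise ConfigurationError(
                    f"fs/{frac}+1 = {k} must be an odd integer kernel length")
            if int(k) > self.T:
                raise ConfigurationError(
                    f"kernel length fs/{frac}+1 = {int(k)} exceeds T={self.T}")
        if not 0.0 <= self.p_dropout < 1.0:
            raise ConfigurationError("p_dropout must be in [0, 1)")

    @property
    def k_temporal(self) -> int:
        return int(self.fs // 2 + 1)

    @property
    def k_summary(self) -> int:
        return int(self.fs // 5 + 1)

    @property
    def feature_dim(self) -> int:
        """Flattened feature length F2 * T / 10 — also the input width of
        every discriminator and classifier."""
        return self.F2 * (self.T // 10)


def build_feature_extractor(cfg: ModelConfig,
                            rng: np.random.Generator) -> Sequential:
    """Instantiate the three-convolution backbone with seeded init."""
    k1, k2 = cfg.k_temporal, cfg.k_summary
    return Sequential([
        Conv2d(1, cfg.F1, 1, k1, pad_w=k1 // 2, rng=rng),
        BatchNorm2d(cfg.F1),
        Conv2d(cfg.F1, cfg.F2, cfg.ch, 1, rng=rng),
        BatchNorm2d(cfg.F2),
        ReLU(),
        AvgPool1xK(2),
        Conv2d(cfg.F2, cfg.F2, 1, k2, pad_w=k2 // 2, rng=rng),
        BatchNorm2d(cfg.F2),
        ReLU(),
        AvgPool1xK(5),
        Dropout2d(cfg.p_dropout),
        Flatten(),
    ])


class Head:
    """A softmax head: one affine layer to 2 logits.

    Used for both domain discriminators (class 1 = target domain) and
    category classifiers (class 1 = deviant).
    """

    def __init__(self, n_in: int, rng: np.random.Generator):
        self.linear = Linear(n_in, 2, rng=rng)

    def params(self):
        return self.linear.params()

    def forward(self, f: np.ndarray):
        """Probabilities (and logits cache) for a (batch, n_in) feature."""
        if f.shape[-1] != self.linear.weight.value.shape[0]:
            raise ConfigurationError(
                f"feature length {f.shape[-1]} != head input "
                f"{self.linear.weight.value.shape[0]}")
        logits, cache = self.linear.forward(f)
        return softmax(logits), cache

    def backward_from_probs_grad_logits(self, glogits: np.ndarray, cache):
        """Backprop a gradient already expressed at the logits (the
        softmax+cross-entropy shortcut: glogits = probs - onehot)."""
        return self.linear.backward(glogits, cache)


def feature_forward(extractor: Sequential, x: np.ndarray,
                    train: bool = False) -> np.ndarray:
    """Flattened feature(s) for one trial (ch, T) or a batch (n, ch, T)."""
    single = x.ndim == 2
    if single:
        x = x[None]
    if x.ndim != 3:
        raise ConfigurationError(f"expected (n, ch, T) input, got {x.shape}")
    f, _ = extractor.forward(x[:, None, :, :], train=train)
    return f[0] if single else f


def head_forward(head: Head, f: np.ndarray) -> np.ndarray:
    """Softmax probabilities for a single feature vector or a batch."""
    single = f.ndim == 1
    probs, _ = head.forward(np.atleast_2d(f))
    return probs[0] if single else probs


class P3MSDANet:
    """The full parameter bundle: shared extractor ``F``, per-source
    gradient-reversed discriminators ``D_j`` and classifiers ``C_j``."""

    def __init__(self, cfg: ModelConfig, n_sources: int, seed: int = 0):
        if n_sources < 1:
            raise ConfigurationError("need at least one source domain")
        self.cfg = cfg
        self.n_sources = n_sources
        rng = np.random.default_rng(seed)
        self.extractor = build_feature_extractor(cfg, rng)
        self.grl = GradReverse()
        self.discriminators = [Head(cfg.feature_dim, rng)
                               for _ in range(n_sources)]
        self.classifiers = [Head(cfg.feature_dim, rng)
                            for _ in range(n_sources)]

    # -- parameter plumbing -------------------------------------------
    def params(self):
        out = list(self.extractor.params())
        for h in self.discriminators + self.classifiers:
            out.extend(h.params())
        return out

    def set_dropout_rng(self, rng: np.random.Generator | None) -> None:
        for layer in self.extractor.layers:
            if isinstance(layer, Dropout2d):
                layer.rng = rng

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self.params(), lr=lr)

    # -- inference -----------------------------------------------------
    def features(self, trials: np.ndarray, train: bool = False):
        return feature_forward(self.extractor, trials, train=train)

    def classify(self, trials: np.ndarray) -> np.ndarray:
        """Eval-mode per-classifier deviant probabilities, shape
        (n_sources, n_trials)."""
        f = self.features(trials, train=False)
        return np.stack([head_forward(c, f)[:, 1] for c in self.classifiers])

    def discriminate(self, trials: np.ndarray) -> np.ndarray:
        """Eval-mode per-discriminator target-domain probabilities, shape
        (n_sources, n_trials)."""
        f = self.features(trials, train=False)
        return np.stack([head_forward(d, f)[:, 1]
                         for d in self.discriminators])

    def evaluate_trials(self, trials: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
        """One eval-mode feature pass feeding every head: returns
        (disc_target_probs, classifier_deviant_probs), each
        (n_sources, n_trials)."""
        f = self.features(trials, train=False)
        disc = np.stack([head_forward(d, f)[:, 1]
                         for d in self.discriminators])
        cls = np.stack([head_forward(c, f)[:, 1] for c in self.classifiers])
        return disc, cls

    # -- state ----------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        arrs = {f"param{i}": p.value for i, p in enumerate(self.params())}
        j = 0
        for layer in self.extractor.layers:
            if isinstance(layer, BatchNorm2d):
                arrs[f"bn{j}_mean"] = layer.running_mean
                arrs[f"bn{j}_var"] = layer.running_var
                j += 1
        return arrs

    def load_state_arrays(self, arrs: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value = np.array(arrs[f"param{i}"])
            p.grad = np.zeros_like(p.value)
        j = 0
        for layer in self.extractor.layers:
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = np.array(arrs[f"bn{j}_mean"])
                layer.running_var = np.array(arrs[f"bn{j}_var"])
                j += 1


def save_checkpoint(net: P3MSDANet, path) -> None:
    """Single-file .npz archive with the architecture config embedded."""
    meta = json.dumps({"cfg": asdict(net.cfg), "n_sources": net.n_sources})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **net.state_arrays())


def load_checkpoint(path) -> P3MSDANet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        net = P3MSDANet(ModelConfig(**meta["cfg"]), meta["n_sources"])
        net.load_state_arrays({k: data[k] for k in data.files
                               if k != "__meta__"})
    return net
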