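"""Model-object surface: build a :class:`P3MSDA` from epoched data, call
``fit()`` and get a :class:`P3MSDAResults` with predictions, ensemble
weights, loss trajectories and a ``summary()`` table.

This is a thin, stateful facade over :mod:`p3msda.trainer`; the functional
API there remains the canonical definition of every computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import EpochSet
from .errors import ConfigurationError
from .network import ModelConfig, P3MSDANet, save_checkpoint
from .trainer import (PerplexityWeights, PredictionState, TrainConfig,
                      TrainOutput, predict, train_p3msda)

__all__ = ["P3MSDA", "P3MSDAResults"]


class P3MSDA:
    """Unsupervised multi-source domain-adaptation model for single-trial
    oddball EEG target detection.

    Parameters
    ----------
    sources : list of EpochSet
        Labeled source subjects; each becomes one source domain with its
        own gradient-reversed domain discriminator and category
        classifier.
    target : EpochSet
        The unlabeled subject to decode (any labels present are ignored).
    model_config, train_config : optional
        Architecture and optimisation hyper-parameters; defaults are the
        published operating point.
    """

    def __init__(self, sources: list[EpochSet], target: EpochSet,
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None):
        if not sources:
            raise ConfigurationError("need at least one source subject")
        ch = {s.n_channels for s in sources} | {target.n_channels}
        ts = {s.n_samples for s in sources} | {target.n_samples}
        if len(ch) != 1 or len(ts) != 1:
            raise ConfigurationError(
                f"inhomogeneous shapes: channels {ch}, samples {ts}")
        self.sources = list(sources)
        self.target = target
        self.model_config = model_config or ModelConfig(
            ch=target.n_channels, T=target.n_samples, fs=target.fs)
        self.train_config = train_config or TrainConfig()
        if (self.model_config.ch != target.n_channels
                or self.model_config.T != target.n_samples):
            raise ConfigurationError("model_config does not match the data")

    @classmethod
    def from_files(cls, source_paths, target_path, **kwargs) -> "P3MSDA":
        from .containers import load_epochs
        return cls([load_epochs(p) for p in source_paths],
                   load_epochs(target_path), **kwargs)

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    def fit(self, seed: int | None = None) -> "P3MSDAResults":
        """Run the adversarial training loop; ``seed`` overrides the
        train_config master seed."""
        tcfg = self.train_config
        if seed is not None:
            tcfg = TrainConfig(**{**tcfg.__dict__, "seed": seed})
        out = train_p3msda(self.sources, self.target, self.model_config,
                           tcfg)
        return P3MSDAResults(self, out, tcfg)


class P3MSDAResults:
    """Fitted-model results: trained parameters, final perplexity
    weights, per-epoch loss history and target predictions."""

    def __init__(self, model: P3MSDA, out: TrainOutput, tcfg: TrainConfig):
        self.model = model
        self.net: P3MSDANet = out.net
        self.state: PredictionState = out.state
        self.weights: PerplexityWeights = out.weights
        self.history = out.history
        self.train_config = tcfg

    # -- predictions ----------------------------------------------------
    @property
    def target_probabilities(self) -> np.ndarray:
        """Weighted ensemble deviant probability per target trial."""
        return self.state.weighted

    @property
    def target_labels(self) -> np.ndarray:
        return self.state.pseudo_labels

    def predict(self, epochs: EpochSet | None = None):
        """Ensemble-predict labels for new epochs (default: the training
        target set)."""
        epochs = epochs if epochs is not None else self.model.target
        return predict(self.net, self.weights, epochs)

    # -- diagnostics ----------------------------------------------------
    def loss_frame(self) -> pd.DataFrame:
        """Per-epoch losses and ensemble weights as a tidy DataFrame."""
        rows = []
        for log in self.history:
            row = {"epoch": log.epoch, "loss_total": log.loss_total,
                   "pool_size": log.pool_size,
                   "n_pseudo_deviant": log.n_pseudo_deviant}
            for j in range(self.model.n_sources):
                row[f"loss_adv_{j}"] = log.loss_adv[j]
                row[f"loss_cls_src_{j}"] = log.loss_cls_src[j]
                row[f"loss_cls_tgt_{j}"] = log.loss_cls_tgt[j]
                row[f"w_{j}"] = log.weights[j]
            rows.append(row)
        return pd.DataFrame(rows)

    def prediction_frame(self) -> pd.DataFrame:
        """Final per-trial predictions (sample_index, probability, label)."""
        return pd.DataFrame({
            "sample_index": np.arange(len(self.state.weighted)),
            "probability": self.state.weighted,
            "label": self.state.pseudo_labels,
        })

    def save(self, path) -> None:
        save_checkpoint(self.net, path)

    def summary(self) -> str:
        m, t = self.model.model_config, self.train_config
        lines = [
            "P3-MSDA fit summary",
            "===================",
            f"source domains        : {self.model.n_sources}",
            f"target trials         : {self.model.target.n_trials}",
            f"architecture          : F1={m.F1} F2={m.F2} ch={m.ch} "
            f"T={m.T} fs={m.fs:g} (feature dim {m.feature_dim})",
            f"loss trade-offs       : alpha={t.alpha} gamma={t.gamma} "
            f"lambda={t.lam}",
            f"batch size / pool Q   : K={t.K}, Q={t.Q:.0%}",
            f"epochs / lr / seed    : {t.epochs} / {t.lr:g} / {t.seed}",
            "",
            "final ensemble weights:",
        ]
        for j, (w, p, l) in enumerate(zip(self.weights.w, self.weights.p_s,
                                          self.weights.l_s)):
            sid = self.model.sources[j].subject_id or f"source{j}"
            lines.append(f"  {sid:<12s} w={w:.4f}  perplexity={p:.4f}  "
                         f"l_s={l:.4f}")
        if self.history:
            lines += [
                "",
                f"final total loss      : {self.history[-1].loss_total:.4f}",
                f"pseudo-deviant trials : {self.history[-1].n_pseudo_deviant}"
                f" / {self.model.target.n_trials}",
            ]
        return "\n".join(lines)
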