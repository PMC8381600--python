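"""Detection metrics and the scheme-comparison harness.

Three training schemes are compared, mirroring the usual
no-adaptation / single-source / multi-source ladder:

``eegnet``
    The same compact feature extractor plus one softmax classifier,
    trained supervised on the pooled labeled sources only — no
    discriminators, no target data during training.
``sda``
    Single-source adversarial adaptation: all selected subjects pooled
    into one source domain (N=1).
``msda``
    Multi-source adversarial adaptation: the selected subjects split
    evenly into N source domains, each with its own discriminator and
    classifier, ensembled by perplexity weights.

The headline metric is the F1 score on the deviant (rare target) class,
appropriate for the heavy class imbalance of oddball detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EpochSet
from .errors import ConfigurationError
from .network import ModelConfig
from .trainer import (TrainConfig, predict, train_p3msda,
                      train_supervised_baseline)

__all__ = ["Metrics", "SchemeSpec", "compute_metrics", "pool_epochs",
           "split_into_domains", "run_scheme", "run_experiment_grid"]

SCHEMES = ("eegnet", "sda", "msda")


@dataclass
class Metrics:
    """Confusion-matrix detection metrics; the deviant class is positive."""

    f1: float
    accuracy: float
    hit_rate: float
    false_alarm_rate: float
    confusion: tuple[int, int, int, int]   # (TP, FP, FN, TN)


@dataclass
class SchemeSpec:
    """One scheme configuration for the comparison harness."""

    scheme: str                       # eegnet | sda | msda
    source_groups: tuple[str, ...] = ("strong",)
    n_source_subjects: int = 5        # drawn per run from the groups
    n_source_domains: int = 1         # msda only

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ConfigurationError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "msda":
            if self.n_source_domains < 1:
                raise ConfigurationError("n_source_domains must be >= 1")
            if self.n_source_subjects % self.n_source_domains:
                raise ConfigurationError(
                    f"{self.n_source_subjects} subjects do not divide "
                    f"evenly into {self.n_source_domains} domains")


def compute_metrics(y_true, y_pred) -> Metrics:
    """F1 (deviant class), accuracy, hit rate and false alarm rate from
    binary label vectors."""
    y_true = np.asarray(y_true).astype(int).ravel()
    y_pred = np.asarray(y_pred).astype(int).ravel()
    if y_true.shape != y_pred.shape:
        raise ConfigurationError("label vectors differ in length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    n = tp + fp + fn + tn
    acc = (tp + tn) / n if n else np.nan
    if tp + fn == 0:
        warnings.warn("no positives in y_true; hit rate and F1 undefined",
                      stacklevel=2)
        hit = np.nan
        f1 = np.nan
    else:
        hit = tp / (tp + fn)
        f1 = 2 * tp / (2 * tp + fp + fn)
    far = fp / (fp + tn) if (fp + tn) else np.nan
    return Metrics(f1=f1, accuracy=acc, hit_rate=hit, false_alarm_rate=far,
                   confusion=(tp, fp, fn, tn))


def pool_epochs(epochs: list[EpochSet], subject_id: str = "pooled") -> EpochSet:
    """Concatenate several subjects' trials into one EpochSet."""
    if not epochs:
        raise ConfigurationError("nothing to pool")
    if len(epochs) == 1:
        return epochs[0]
    return EpochSet(
        trials=np.concatenate([e.trials for e in epochs]),
        labels=np.concatenate([e.labels for e in epochs]),
        fs=epochs[0].fs, channel_names=epochs[0].channel_names,
        subject_id=subject_id)


def split_into_domains(epochs: list[EpochSet], n_domains: int
                       ) -> list[EpochSet]:
    """Evenly split a subject list into pooled source domains (subject
    order preserved)."""
    if len(epochs) % n_domains:
        raise ConfigurationError(
            f"{len(epochs)} subjects do not divide into {n_domains} domains")
    per = len(epochs) // n_domains
    return [pool_epochs(epochs[i * per:(i + 1) * per], f"domain{i}")
            for i in range(n_domains)]


def run_scheme(spec: SchemeSpec, sources: list[EpochSet], target: EpochSet,
               mcfg: ModelConfig, tcfg: TrainConfig) -> Metrics:
    """Train one scheme on the given labeled sources and score it on the
    labeled target subject.

    The target subject must not appear among the sources; adversarial
    schemes see an unlabeled view of the target during training, the
    supervised baseline never sees it at all.
    """
    if any(s.subject_id == target.subject_id for s in sources):
        raise ConfigurationError(
            f"target {target.subject_id!r} leaked into the sources")
    if spec.scheme == "eegnet":
        out = train_supervised_baseline(sources, mcfg, tcfg)
    elif spec.scheme == "sda":
        out = train_p3msda([pool_epochs(sources)], target, mcfg, tcfg)
    else:
        domains = split_into_domains(sources, spec.n_source_domains)
        out = train_p3msda(domains, target, mcfg, tcfg)
    y_pred, _ = predict(out.net, out.weights, target)
    return compute_metrics(target.labels, y_pred)


def run_experiment_grid(schemes: list[SchemeSpec], cohort: list[EpochSet],
                        groups: dict[str, str], repeats: int, seed: int,
                        mcfg: ModelConfig, tcfg: TrainConfig,
                        target_group: str | None = None) -> pd.DataFrame:
    """Repeatedly draw a target subject and sources, run every scheme and
    tabulate the metrics.

    Per repeat one target subject is drawn (from ``target_group`` if
    given, else from the whole cohort) and shared by all schemes, so the
    schemes are compared on identical targets. Sources are drawn without
    replacement from each scheme's groups, excluding the target.
    """
    if repeats < 1:
        raise ConfigurationError("repeats must be >= 1")
    by_id = {e.subject_id: e for e in cohort}
    unknown = set(groups) - set(by_id)
    if unknown:
        raise ConfigurationError(f"groups refer to unknown subjects {unknown}")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(repeats):
        candidates = [sid for sid in by_id
                      if target_group is None or groups[sid] == target_group]
        target_id = candidates[rng.integers(len(candidates))]
        target = by_id[target_id]
        rep_seed = int(rng.integers(2 ** 31))
        for spec in schemes:
            pool = [sid for sid in by_id
                    if groups[sid] in spec.source_groups
                    and sid != target_id]
            if len(pool) < spec.n_source_subjects:
                raise ConfigurationError(
                    f"only {len(pool)} candidates for "
                    f"{spec.n_source_subjects} source subjects "
                    f"({spec.scheme}, groups {spec.source_groups})")
            pick = rng.choice(len(pool), size=spec.n_source_subjects,
                              replace=False)
            sources = [by_id[pool[i]] for i in sorted(pick)]
            run_tcfg = TrainConfig(**{**tcfg.__dict__, "seed": rep_seed})
            metrics = run_scheme(spec, sources, target, mcfg, run_tcfg)
            rows.append({
                "scheme": spec.scheme, "repeat": rep,
                "target_subject": target_id,
                "target_group": groups[target_id],
                "f1": metrics.f1, "accuracy": metrics.accuracy,
                "hit_rate": metrics.hit_rate,
                "far": metrics.false_alarm_rate, "seed": rep_seed,
            })
    return pd.DataFrame(rows)
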