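"""Losses, perplexity-weighted ensembling, samplers and the adversarial
multi-source training loop.

The optimisation objective is, over N source domains,

    min_{F, D, C}  alpha * sum_j L_adv^j + gamma * sum_j L_cls-src^j
                   + lambda * sum_j L_cls-tgt^j

where ``L_adv^j`` is the domain-discrimination cross-entropy between the
j-th source batch and the target batch (reaching the shared extractor F
through a gradient-reversal layer, so F learns to confuse the
discriminators), ``L_cls-src^j`` is the supervised category cross-entropy
of classifier C_j on its source batch, and ``L_cls-tgt^j`` is the
cross-entropy of C_j on the target batch against pseudo labels binarized
from the weighted classifier ensemble.  All cross-entropies are natural-log
sums over the batch.

Each classifier's ensemble weight is the normalised target-source
perplexity score

    p_s^j = mean_k[ -log(1 - D_j(F(x_k^t))) ] + l_s^j ,
    w_j   = p_s^j / sum_j p_s^j ,

where D_j(.) is the probability the j-th discriminator assigns the target
sample to the target domain and ``l_s^j`` is the running per-sample mean of
that discriminator's source-side loss over the current epoch: a source the
discriminator cannot tell from the target (high confusion) gets a high
weight.

Class imbalance is handled on both sides: every source epoch re-samples
all deviants plus an equal number of random standards, and the target pool
for the next epoch is the top-Q fraction of target samples ranked by
ensemble deviant probability (initially the whole target set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import EpochSet
from .errors import ConfigurationError, TrainingDivergedError
from .network import ModelConfig, P3MSDANet

__all__ = [
    "TrainConfig", "PerplexityWeights", "PredictionState", "LossBundle",
    "domain_adv_loss", "source_class_loss", "target_pseudo_loss",
    "perplexity_scores", "classifier_weights", "ensemble_predict",
    "balanced_source_sample", "select_target_pool", "total_loss",
    "adversarial_step", "train_p3msda", "predict",
    "train_supervised_baseline",
]

EPS = 1e-12

# domain one-hot convention: index 1 = target domain
V_SOURCE = np.array([1.0, 0.0])
V_TARGET = np.array([0.0, 1.0])


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    Defaults are the published operating point: loss trade-offs
    (alpha, gamma, lam) = (0.2, 0.8, 0.2), batch size K=20, retained
    target fraction Q=80%, Adam at lr 3e-4 for 300 epochs.
    """

    alpha: float = 0.2
    gamma: float = 0.8
    lam: float = 0.2
    K: int = 20
    Q: float = 0.8
    lr: float = 3e-4
    epochs: int = 300
    seed: int = 0
    use_true_entropy: bool = False   # replace pseudo-label CE by prediction entropy

    def __post_init__(self) -> None:
        if min(self.alpha, self.gamma, self.lam) < 0:
            raise ConfigurationError("loss trade-offs must be >= 0")
        if not 0.0 < self.Q <= 1.0:
            raise ConfigurationError("Q must be in (0, 1]")
        if self.K < 2 or self.K % 2:
            raise ConfigurationError("K must be even and >= 2 (class balance)")
        if self.epochs < 1 or self.lr <= 0:
            raise ConfigurationError("epochs >= 1 and lr > 0 required")


@dataclass
class PerplexityWeights:
    """Per-source perplexity scores, mean discriminator losses and the
    normalised classifier weights (a point on the simplex)."""

    p_s: np.ndarray
    l_s: np.ndarray
    w: np.ndarray


@dataclass
class PredictionState:
    """Ensemble predictions over a target sample set.

    ``p_hat`` is the literal (1/N)-scaled ensemble probability;
    ``weighted`` is the simplex-weighted mean sum_j w_j p_j on the [0, 1]
    scale, which is what gets thresholded at 0.5 for pseudo labels and
    ranked (the two orderings coincide — they differ by the constant 1/N).
    """

    p_hat: np.ndarray
    weighted: np.ndarray
    pseudo_labels: np.ndarray
    ranking: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.p_hat)
        if sorted(self.ranking.tolist()) != list(range(n)):
            raise ConfigurationError("ranking must be a permutation")


@dataclass
class LossBundle:
    """Per-source loss terms for one batch iteration plus the weighted
    total objective."""

    adv: np.ndarray
    cls_src: np.ndarray
    cls_tgt: np.ndarray
    total: float = 0.0


# ---------------------------------------------------------------------
# loss terms (values on probability batches; sums over the batch, ln)
# ---------------------------------------------------------------------

def _clamped_log(p: np.ndarray) -> np.ndarray:
    return np.log(np.clip(p, EPS, None))


def domain_adv_loss(p_src: np.ndarray, p_tgt: np.ndarray) -> float:
    """Domain-discrimination cross-entropy of one discriminator on one
    source batch and one target batch (probabilities, shape (K, 2))."""
    p_src = np.atleast_2d(p_src)
    p_tgt = np.atleast_2d(p_tgt)
    loss = -(np.sum(V_SOURCE * _clamped_log(p_src))
             + np.sum(V_TARGET * _clamped_log(p_tgt)))
    return float(loss)


def _class_cross_entropy(p: np.ndarray, y: np.ndarray) -> float:
    p = np.atleast_2d(p)
    y = np.asarray(y, dtype=int)
    if p.shape[0] != y.shape[0]:
        raise ConfigurationError("probability/label batch size mismatch")
    return float(-np.sum(_clamped_log(p[np.arange(len(y)), y])))


def source_class_loss(p: np.ndarray, y: np.ndarray) -> float:
    """Supervised category cross-entropy on a labeled source batch."""
    return _class_cross_entropy(p, y)


def target_pseudo_loss(p: np.ndarray, pseudo: np.ndarray) -> float:
    """Category cross-entropy on a target batch against binarized pseudo
    labels from the ensemble."""
    return _class_cross_entropy(p, pseudo)


def prediction_entropy(p: np.ndarray) -> float:
    """Sum over the batch of the Shannon entropy of each prediction (the
    optional strict-entropy reading of the unsupervised target loss)."""
    p = np.atleast_2d(p)
    return float(-np.sum(p * _clamped_log(p)))


# ---------------------------------------------------------------------
# perplexity weighting and ensembling
# ---------------------------------------------------------------------

def perplexity_scores(disc_target_probs: np.ndarray,
                      l_s: np.ndarray) -> PerplexityWeights:
    """Per-source perplexity scores and normalised classifier weights.

    Parameters
    ----------
    disc_target_probs : ndarray (N, K)
        For each source's discriminator, the probability it assigns each
        target-batch sample to the *target* domain.
    l_s : ndarray (N,)
        Per-source mean discriminator losses.
    """
    d = np.atleast_2d(np.asarray(disc_target_probs, dtype=float))
    l_s = np.asarray(l_s, dtype=float)
    if d.shape[0] != l_s.shape[0]:
        raise ConfigurationError("need one l_s per source")
    p_s = np.mean(-np.log(np.clip(1.0 - d, EPS, None)), axis=1) + l_s
    return PerplexityWeights(p_s=p_s, l_s=l_s, w=classifier_weights(p_s))


def classifier_weights(p_s: np.ndarray) -> np.ndarray:
    """Normalise perplexity scores onto the simplex; an all-zero score
    vector falls back to uniform weights."""
    p_s = np.asarray(p_s, dtype=float)
    if (p_s < 0).any():
        raise ConfigurationError("perplexity scores must be >= 0")
    s = p_s.sum()
    if s <= 0:
        warnings.warn("all perplexity scores zero; uniform classifier "
                      "weights", stacklevel=2)
        return np.full(len(p_s), 1.0 / len(p_s))
    return p_s / s


def ensemble_predict(w: np.ndarray,
                     per_classifier_probs: np.ndarray) -> PredictionState:
    """Weighted ensemble of the N classifiers' deviant probabilities.

    ``per_classifier_probs`` has shape (N, n). The stored ``p_hat`` keeps
    the literal (1/N) sum_j w_j p_j value; ranking and the 0.5 pseudo-label
    threshold use the scale-correct weighted mean sum_j w_j p_j. Ranking is
    descending with ties broken toward the lower original index.
    """
    w = np.asarray(w, dtype=float)
    probs = np.atleast_2d(np.asarray(per_classifier_probs, dtype=float))
    if probs.shape[0] != len(w):
        raise ConfigurationError("need one weight per classifier")
    weighted = w @ probs
    p_hat = weighted / len(w)
    ranking = np.argsort(-weighted, kind="stable")
    return PredictionState(p_hat=p_hat, weighted=weighted,
                           pseudo_labels=(weighted > 0.5).astype(np.int8),
                           ranking=ranking)


# ---------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------

def balanced_source_sample(epochs: EpochSet,
                           rng: np.random.Generator) -> EpochSet:
    """All deviants plus an equal-count uniform random subset of
    standards; with fewer standards than deviants, all standards (logged)."""
    dev = np.flatnonzero(epochs.deviant_mask)
    std = np.flatnonzero(~epochs.deviant_mask)
    if len(dev) == 0 or len(std) == 0:
        raise ConfigurationError("both classes required for balancing")
    if len(std) < len(dev):
        warnings.warn(f"{epochs.subject_id}: fewer standards ({len(std)}) "
                      f"than deviants ({len(dev)}); taking all standards",
                      stacklevel=2)
        pick = std
    else:
        pick = rng.choice(std, size=len(dev), replace=False)
    return epochs.subset(np.concatenate([dev, np.sort(pick)]))


def select_target_pool(state: PredictionState, Q: float) -> np.ndarray:
    """Indices of the top ceil(Q*n) target samples by ensemble deviant
    probability (the next epoch's target pool)."""
    if not 0.0 < Q <= 1.0:
        raise ConfigurationError("Q must be in (0, 1]")
    n = len(state.ranking)
    return state.ranking[: int(np.ceil(Q * n))].copy()


def total_loss(bundle: LossBundle, cfg: TrainConfig) -> float:
    """alpha * sum_j adv_j + gamma * sum_j cls_src_j + lam * sum_j cls_tgt_j."""
    return float(cfg.alpha * np.sum(bundle.adv)
                 + cfg.gamma * np.sum(bundle.cls_src)
                 + cfg.lam * np.sum(bundle.cls_tgt))


# ---------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------

def _onehot(y: np.ndarray) -> np.ndarray:
    out = np.zeros((len(y), 2))
    out[np.arange(len(y)), np.asarray(y, dtype=int)] = 1.0
    return out


def _stratified_batches(labels: np.ndarray, n_batches: int, half: int,
                        rng: np.random.Generator) -> list[np.ndarray]:
    """Class-balanced batches (half per class) without replacement."""
    dev = rng.permutation(np.flatnonzero(labels == 1))
    std = rng.permutation(np.flatnonzero(labels == 0))
    out = []
    for b in range(n_batches):
        idx = np.concatenate([dev[b * half:(b + 1) * half],
                              std[b * half:(b + 1) * half]])
        out.append(rng.permutation(idx))
    return out


@dataclass
class EpochLog:
    """Per-epoch diagnostics written by the training loop."""

    epoch: int
    loss_total: float
    loss_adv: np.ndarray
    loss_cls_src: np.ndarray
    loss_cls_tgt: np.ndarray
    weights: np.ndarray
    pool_size: int
    n_pseudo_deviant: int


@dataclass
class TrainOutput:
    net: P3MSDANet
    state: PredictionState
    weights: PerplexityWeights
    history: list[EpochLog] = field(default_factory=list)


def adversarial_step(net: P3MSDANet, opt, src_data, xt: np.ndarray,
                     tcfg: TrainConfig, l_sum: np.ndarray, n_seen: int,
                     update: bool = True):
    """One batch iteration of the adversarial objective.

    Runs the shared extractor on the target batch and each source batch,
    computes the domain, source-category and target-pseudo losses, the
    perplexity weights and the batch pseudo labels, and (when ``update``)
    backpropagates the weighted total and takes one optimiser step.
    ``l_sum`` is updated in place with the source-side discriminator loss
    of this batch.

    Returns ``(LossBundle, PerplexityWeights, PredictionState)`` for the
    batch. Exposed separately from the epoch loop so single-step
    objective-descent properties can be tested on a frozen batch.
    """
    n_sources = net.n_sources
    K = len(xt)
    if update:
        opt.zero_grad()
    ft, cache_t = net.extractor.forward(xt[:, None], train=True)

    per_src = []
    disc_t = np.empty((n_sources, K))
    cls_t = np.empty((n_sources, K))
    adv = np.empty(n_sources)
    cls_src = np.empty(n_sources)
    for j in range(n_sources):
        xs, ys = src_data[j]
        fs_, cache_s = net.extractor.forward(xs[:, None], train=True)
        p_ds, cds = net.discriminators[j].forward(fs_)
        p_dt, cdt = net.discriminators[j].forward(ft)
        p_cs, ccs = net.classifiers[j].forward(fs_)
        p_ct, cct = net.classifiers[j].forward(ft)
        adv[j] = domain_adv_loss(p_ds, p_dt)
        cls_src[j] = source_class_loss(p_cs, ys)
        disc_t[j] = p_dt[:, 1]
        cls_t[j] = p_ct[:, 1]
        # per-sample source-side discriminator loss feeds l_s
        l_sum[j] += float(-np.sum(_clamped_log(p_ds[:, 0])))
        per_src.append((ys, cache_s, p_ds, cds, p_dt, cdt,
                        p_cs, ccs, p_ct, cct))
    weights = perplexity_scores(disc_t, l_sum / (n_seen + K))

    batch_state = ensemble_predict(weights.w, cls_t)
    pseudo = batch_state.pseudo_labels
    cls_tgt = np.empty(n_sources)
    for j in range(n_sources):
        p_ct = per_src[j][8]
        if tcfg.use_true_entropy:
            cls_tgt[j] = prediction_entropy(p_ct)
        else:
            cls_tgt[j] = target_pseudo_loss(p_ct, pseudo)

    bundle = LossBundle(adv=adv, cls_src=cls_src, cls_tgt=cls_tgt)
    bundle.total = total_loss(bundle, tcfg)
    if not np.isfinite(bundle.total):
        raise TrainingDivergedError(
            f"non-finite loss: adv={adv}, cls_src={cls_src}, "
            f"cls_tgt={cls_tgt}")
    if not update:
        return bundle, weights, batch_state

    # ---- backward (softmax+CE shortcut: glogits = p - onehot) ----
    g_ft = np.zeros_like(ft)
    onehot_t = np.tile(V_TARGET, (K, 1))
    onehot_s_dom = np.tile(V_SOURCE, (K, 1))
    for j in range(n_sources):
        (ys, cache_s, p_ds, cds, p_dt, cdt,
         p_cs, ccs, p_ct, cct) = per_src[j]
        g_fs = np.zeros_like(ft)
        if tcfg.alpha > 0:
            gd_s = net.discriminators[j].backward_from_probs_grad_logits(
                tcfg.alpha * (p_ds - onehot_s_dom), cds)
            gd_t = net.discriminators[j].backward_from_probs_grad_logits(
                tcfg.alpha * (p_dt - onehot_t), cdt)
            # gradient reversal between extractor and discriminator
            g_fs += net.grl.backward(gd_s, None)
            g_ft += net.grl.backward(gd_t, None)
        if tcfg.gamma > 0:
            g_fs += net.classifiers[j].backward_from_probs_grad_logits(
                tcfg.gamma * (p_cs - _onehot(ys)), ccs)
        if tcfg.lam > 0:
            if tcfg.use_true_entropy:
                logp = _clamped_log(p_ct)
                ent = -np.sum(p_ct * logp, axis=1, keepdims=True)
                gl = tcfg.lam * (-p_ct * (logp + ent))
            else:
                gl = tcfg.lam * (p_ct - _onehot(pseudo))
            g_ft += net.classifiers[j].backward_from_probs_grad_logits(
                gl, cct)
        net.extractor.backward(g_fs, cache_s)
    net.extractor.backward(g_ft, cache_t)
    opt.step()
    return bundle, weights, batch_state


def train_p3msda(sources: list[EpochSet], target: EpochSet,
                 mcfg: ModelConfig, tcfg: TrainConfig) -> TrainOutput:
    """Train the adversarial multi-source model and return the trained
    network plus the final target prediction state.

    The target's labels are never read: training sees an unlabeled view.
    """
    if len(sources) < 1:
        raise ConfigurationError("need at least one source domain")
    target = target.unlabeled()
    n_sources = len(sources)
    n_t = target.n_trials
    if n_t < tcfg.K:
        raise ConfigurationError(
            f"target has {n_t} trials < batch size K={tcfg.K}")

    seeds = np.random.SeedSequence(tcfg.seed).spawn(3)
    init_seed = int(seeds[0].generate_state(1)[0] % (2 ** 31))
    sample_rng = np.random.default_rng(seeds[1])
    dropout_rng = np.random.default_rng(seeds[2])

    net = P3MSDANet(mcfg, n_sources, seed=init_seed)
    net.set_dropout_rng(dropout_rng)
    opt = net.make_optimizer(tcfg.lr)
    half = tcfg.K // 2

    # initial pool/ranking: the whole target set in original order
    state = PredictionState(p_hat=np.zeros(n_t), weighted=np.zeros(n_t),
                            pseudo_labels=np.zeros(n_t, dtype=np.int8),
                            ranking=np.arange(n_t))
    weights = PerplexityWeights(p_s=np.ones(n_sources),
                                l_s=np.zeros(n_sources),
                                w=np.full(n_sources, 1.0 / n_sources))
    history: list[EpochLog] = []

    for epoch in range(tcfg.epochs):
        balanced = [balanced_source_sample(s, sample_rng) for s in sources]
        pool = select_target_pool(state, tcfg.Q)
        per_src_m = [min(int(b.deviant_mask.sum()),
                         int((~b.deviant_mask).sum())) // half
                     for b in balanced]
        m = min(min(per_src_m), len(pool) // tcfg.K)
        if m < 1:
            raise ConfigurationError(
                "not enough samples for one batch of K per domain; "
                f"balanced source sizes {[b.n_trials for b in balanced]}, "
                f"pool size {len(pool)}, K={tcfg.K}")

        src_batches = [_stratified_batches(b.labels, m, half, sample_rng)
                       for b in balanced]
        pool_perm = sample_rng.permutation(pool)

        l_sum = np.zeros(n_sources)   # running source-side disc loss
        n_seen = 0
        last = None
        for b in range(m):
            src_data = [(balanced[j].trials[src_batches[j][b]],
                         balanced[j].labels[src_batches[j][b]])
                        for j in range(n_sources)]
            t_idx = pool_perm[b * tcfg.K:(b + 1) * tcfg.K]
            try:
                last, weights, _ = adversarial_step(
                    net, opt, src_data, target.trials[t_idx], tcfg,
                    l_sum, n_seen)
            except TrainingDivergedError as err:
                err.epoch, err.batch = epoch, b
                raise
            n_seen += tcfg.K

        # ---- epoch end: re-rank the full target set (eval mode) ----
        disc_full, cls_full = net.evaluate_trials(target.trials)
        weights = perplexity_scores(disc_full, l_sum / max(n_seen, 1))
        state = ensemble_predict(weights.w, cls_full)
        history.append(EpochLog(
            epoch=epoch, loss_total=last.total, loss_adv=last.adv,
            loss_cls_src=last.cls_src, loss_cls_tgt=last.cls_tgt,
            weights=weights.w.copy(), pool_size=len(pool),
            n_pseudo_deviant=int(state.pseudo_labels.sum())))

    net.set_dropout_rng(None)
    return TrainOutput(net=net, state=state, weights=weights,
                       history=history)


def predict(net: P3MSDANet, weights: PerplexityWeights,
            target: EpochSet) -> tuple[np.ndarray, PredictionState]:
    """Eval-mode ensemble prediction on a target sample set; returns the
    binary labels and the full prediction state."""
    state = ensemble_predict(weights.w, net.classify(target.trials))
    return state.pseudo_labels.copy(), state


def train_supervised_baseline(sources: list[EpochSet], mcfg: ModelConfig,
                              tcfg: TrainConfig) -> TrainOutput:
    """No-adaptation baseline: the same feature extractor plus a single
    softmax classifier, trained by supervised cross-entropy on the pooled
    labeled sources only.

    No discriminators are updated and no target data is consumed, so the
    comparison against the adversarial runs isolates the effect of domain
    adaptation. Returned as a ``TrainOutput`` with uniform (single-source)
    weights so the same ``predict`` path applies.
    """
    if len(sources) < 1:
        raise ConfigurationError("need at least one source subject")
    pooled = sources[0]
    if len(sources) > 1:
        pooled = EpochSet(
            trials=np.concatenate([s.trials for s in sources]),
            labels=np.concatenate([s.labels for s in sources]),
            fs=sources[0].fs, channel_names=sources[0].channel_names,
            subject_id="pooled")

    seeds = np.random.SeedSequence(tcfg.seed).spawn(3)
    init_seed = int(seeds[0].generate_state(1)[0] % (2 ** 31))
    sample_rng = np.random.default_rng(seeds[1])
    dropout_rng = np.random.default_rng(seeds[2])

    net = P3MSDANet(mcfg, 1, seed=init_seed)
    net.set_dropout_rng(dropout_rng)
    opt = net.make_optimizer(tcfg.lr)
    half = tcfg.K // 2
    history: list[EpochLog] = []

    for epoch in range(tcfg.epochs):
        bal = balanced_source_sample(pooled, sample_rng)
        m = min(int(bal.deviant_mask.sum()),
                int((~bal.deviant_mask).sum())) // half
        if m < 1:
            raise ConfigurationError("not enough samples for one batch")
        batches = _stratified_batches(bal.labels, m, half, sample_rng)
        last_loss = np.nan
        for idx in batches:
            opt.zero_grad()
            xs, ys = bal.trials[idx], bal.labels[idx]
            f, cache = net.extractor.forward(xs[:, None], train=True)
            p, cc = net.classifiers[0].forward(f)
            loss = source_class_loss(p, ys)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite baseline loss at epoch {epoch}",
                    epoch=epoch)
            gf = net.classifiers[0].backward_from_probs_grad_logits(
                p - _onehot(ys), cc)
            net.extractor.backward(gf, cache)
            opt.step()
            last_loss = loss
        history.append(EpochLog(
            epoch=epoch, loss_total=last_loss,
            loss_adv=np.zeros(1), loss_cls_src=np.array([last_loss]),
            loss_cls_tgt=np.zeros(1), weights=np.ones(1),
            pool_size=0, n_pseudo_deviant=0))

    net.set_dropout_rng(None)
    weights = PerplexityWeights(p_s=np.ones(1), l_s=np.zeros(1),
                                w=np.ones(1))
    n = pooled.n_trials
    state = PredictionState(p_hat=np.zeros(n), weighted=np.zeros(n),
                            pseudo_labels=np.zeros(n, dtype=np.int8),
                            ranking=np.arange(n))
    return TrainOutput(net=net, state=state, weights=weights,
                       history=history)
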