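# Methods

This note documents the models, the generative assumptions of the
synthetic cohorts, the numerical choices, and what the tests do and do
not establish.

## 1. The detection model

### Feature extractor

A compact three-convolution backbone maps a single trial (ch × T
microvolts) to a flat feature of length F2·T/10:

1. temporal convolution, F1 kernels of length fs/2+1 (≈2 Hz frequency
   resolution), length-preserving zero padding, batch norm;
2. spatial convolution, F2 kernels of size ch×1 collapsing the channel
   axis into learned spatial filters, batch norm, ReLU, average pool (1,2);
3. temporal summary convolution, F2 kernels of length fs/5+1 (≈200 ms),
   batch norm, ReLU, average pool (1,5), feature-map dropout, flatten.

Both temporal kernels are odd by construction (fs/2 and fs/5 must be even
integers; the config validates this), so "same" padding preserves T
exactly and the flattened width is exactly F2·T/10 — 80 at the published
operating point (F1=4, F2=8, ch=61, T=100, fs=100, dropout 0.2).

Every discriminator and classifier head is a single affine layer to 2
logits followed by softmax. Index 1 means "target domain" for
discriminators and "deviant" for classifiers. Whether a nonlinearity
precedes the head softmax is an open design point; a plain affine map is
used.

### Adversarial multi-source objective

With N source domains, the joint objective over the shared extractor F,
discriminators D_j and classifiers C_j is

    min  alpha * sum_j L_adv^j  +  gamma * sum_j L_cls-src^j
         +  lambda * sum_j L_cls-tgt^j

All three terms are natural-log cross-entropy *sums* over the batch
(size K per domain per iteration). The adversarial term reaches F through
a gradient reversal layer — identity forward, gradient negation backward
— placed only on the discriminator branches; classifiers receive
unreversed gradients (standard adversarial-alignment placement). The
discriminators therefore descend on their own loss while F ascends on it,
which is what drives domain confusion; the joint update is *not* plain
gradient descent on the total, though in practice (and in a dedicated
single-step test on a frozen batch) the total objective still decreases
because the supervised terms dominate at the default trade-offs
(alpha, gamma, lambda) = (0.2, 0.8, 0.2).

### Perplexity-weighted ensemble

Per source j, the perplexity score is the batch mean of
−log(1 − D_j(F(x_t))) — how strongly the j-th discriminator believes
target samples are target — plus l_s^j, the running per-sample mean of
the j-th discriminator's source-side loss over the current epoch.
Weights w_j are the scores normalised onto the simplex; an all-zero score
vector (only reachable in degenerate inputs) falls back to uniform
weights with a logged warning.

The literal ensemble probability carries a 1/N factor,
p̂ = (1/N) Σ_j w_j p_j, which for N > 1 can never exceed max_j w_j and
makes a fixed 0.5 threshold unusable. The implementation therefore ranks
and thresholds the simplex-weighted mean Σ_j w_j p_j ∈ [0, 1] at 0.5
(identical ordering — the two differ by a constant factor), while the
stored `p_hat` keeps the literal value for fidelity. Ranking ties break
toward the lower original index.

The target loss is written against pseudo labels binarized from the
ensemble, and that is the default; a strict entropy-minimisation variant
(`use_true_entropy`) is exposed but off, since the pseudo-label form is
what the objective's algebra states. Pseudo labels and ensemble weights
are treated as constants in the backward pass.

### Imbalance handling

Source side: each epoch resamples all deviants plus an equal-count
random subset of standards per source; batches are additionally
stratified to K/2 per class. Target side: after every epoch the full
target set is re-ranked by ensemble deviant probability (eval mode,
running batch-norm statistics) and the next epoch draws its target
batches, without replacement, from the top ⌈Q·n⌉ pool (initially the
whole set, original order). Batches per epoch are
m = ⌊min(min_j balanced_j, pool)/K⌋, limited per source by the smaller
class so stratification never runs dry.

### Optimisation and seeding

Adam (β = 0.9/0.999, ε = 1e-8) at lr 3e-4 for 300 epochs, K = 20,
Q = 80% by default — all config-exposed. Probabilities are clamped at
1e-12 inside every logarithm. One master seed is split (SeedSequence)
into independent streams for parameter initialisation, resampling /
shuffling, and dropout, so a run is a pure function of (data, configs,
seed); this is asserted bitwise in the tests. A non-finite loss aborts
with the epoch/batch in the exception.

The network layers themselves (im2col convolutions, batch norm, pooling,
dropout, affine heads, Adam) are a small purpose-built numpy engine;
every layer's input and parameter gradients are verified against central
finite differences in the test suite.

## 2. Source-domain selection

Subjects are scored by one of four criteria — P3-peak scalp map (the
default; a vector of one microvolt value per channel), deviant-ERP
energy, deviant/standard ERP energy ratio, or SNR (deviant-ERP energy
over mean single-trial residual energy) — and k-means-clustered
(k = 3, 10 restarts, seeded) into groups relabeled strong/medium/weak by
descending mean feature magnitude. Raw topography vectors are clustered
by default; unit-normalised vectors are an option (`normalize=True`)
when spatial pattern rather than strength should drive the grouping.
The "entire-epoch" energy criteria integrate over the full post-rejection
trial window.

Preprocessing for the P3 map: amplitude rejection at ±100 μV, deviant
trials aligned to the deviant-ERP template by cross-correlation of the
centro-parietal mean trace (lag window ±max_lag, zero-padded shifts so
late components never wrap to trial start), re-averaged, and the scalp
map taken at the argmax of the centro-parietal mean inside a 250–600 ms
search window (ties to the earliest sample). The cross-correlation
aligner is a deliberate, documented substitute for more elaborate
iterative ERP alignment procedures: it recovers pure shifts exactly,
which is all the simulator's Gaussian-bump jitter requires. SNR of
identical trials saturates to an `inf` sentinel with a warning.

## 3. The synthetic cohorts

Each trial is a sum of Gaussian-bump ERP components projected onto the
scalp by Gaussian spatial falloff from a focus on a synthetic sunflower
(Fibonacci-spiral) layout, plus 70% 1/f-shaped and 30% white Gaussian
noise. Defaults (all config-exposed, per-component):

| component | latency | jitter SD | amplitude | FWHM | focus | classes |
|---|---|---|---|---|---|---|
| P1 | 100 ms | 10 ms | +2 μV | 40 ms | occipital | both |
| P2 | 200 ms | 15 ms | +3 μV | 50 ms | occipital | both |
| P3 | 400 ms | 40 ms | +8 μV × gain | 120 ms | centro-parietal | deviant only |
| LateNeg | 600 ms | 40 ms | −6 μV | 150 ms | fronto-central | deviant only |

The P3 gain carries the planted group structure (defaults 3.0/1.5/0.5
for strong/medium/weak — free parameters of the simulator, chosen to be
separable but overlapping at single-trial level). Cohort heterogeneity
(the domain shift the adaptation must bridge): lognormal gain and noise
spread (rel. SD 0.15 each around an 8 μV single-trial noise floor),
per-subject ERP latency offsets (SD 15 ms), jitter scaling in
[0.75, 1.25]. Acquisition defaults mirror the emulated setting: 61
channels, 100 Hz, 1 s epochs, 400 trials per subject (valid range
300–500), deviant:standard ≈ 1:4.3. Trial windows are 0-based,
half-open [0, T) in samples; label order is a seeded permutation; the
deviant count is round(n/(1+ratio)).

What the simulator does *not* emulate: volume-conducted forward physics
(leadfields/dipoles), ocular or muscular artifacts, non-Gaussian or
spatially correlated noise, non-stationary drift, or overlapping
responses in continuous recordings. Passing tests therefore demonstrate
that the algorithmic machinery behaves as specified under the assumed
signal structure — not that the method attains any particular accuracy
on real recordings.

## 4. Benchmark problem sizes

The end-to-end checks run on deliberately compact transfer problems
(`p3msda.benchmarks`): 8 channels, 160 trials per subject, 2 source
subjects with strong planted P3 (gain 3.0, mild idiosyncrasies), one
target subject with a systematic shift (gain 2.0, +60 ms latency offset,
×0.8 amplitude, ×1.2 jitter; the source-strength comparison uses a
+40 ms, unit-amplitude target so only donor strength varies), 50 epochs.
These sizes keep a full adversarial run in the seconds range on one CPU
while preserving imbalance, jitter and a genuine between-subject shift.
The group-recovery check runs at the full 61-channel, 400-trial scale
(15 subjects, 20 seeds). Source and target generation use split seed
streams so paired comparisons see the identical target.

## 5. Known limitations

* The ensemble weight derives from discriminator confusion; with very
  few source domains (N = 2 in the benchmarks) the weights hover near
  uniform and the multi-source ensemble can underperform the pooled
  single-source variant on individual seeds.
* Batch-norm statistics are computed per domain-batch during training;
  with K = 20 they are noisy, which is partly why eval-mode re-ranking
  uses running averages.
* The 0.5 pseudo-label threshold is not calibrated to the class prior;
  the top-Q ranking mechanism, not the threshold, is what controls
  imbalance during training.
* k = 3 strength groups is fixed by design; no model selection over k.
* HDF5 output is byte-reproducible (`track_times=False`), float32 on
  disk, float64 in memory.
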