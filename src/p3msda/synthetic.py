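"""Synthetic multi-subject oddball-EEG cohorts.

The original rare-target video-detection recordings are not public, so this
module generates epoched cohorts with the statistical structure the method
assumes and that every downstream stage can be tested against:

* stimulus-locked ERP components (P1, P2, P3 and a late negative wave),
  each a Gaussian-windowed bump with a smooth scalp topography;
* per-subject P3 strength falling into strong / medium / weak groups
  (a multiplicative ``p3_gain`` on the P3 amplitude);
* trial-to-trial latency jitter, severe for the P3, emulating the loose
  time-locking of responses to dynamic visual targets;
* per-subject domain shift (latency offset, amplitude scale, noise level);
* heavy class imbalance (one deviant per ~4.1-4.5 standards);
* 1/f-shaped plus white Gaussian noise.

Everything is driven by a single :class:`numpy.random.Generator`, so a
cohort is a pure function of its config and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import montage
from .containers import EpochSet, save_epochs
from .errors import ConfigurationError

__all__ = [
    "ERPComponentSpec", "SubjectProfile", "SynthConfig",
    "default_components", "simulate_trial", "simulate_subject",
    "simulate_cohort", "save_cohort",
]

GROUPS = ("strong", "medium", "weak")

#: default per-group P3 gains; free parameters of the simulator, chosen so
#: the three groups are separable but overlapping at single-trial level.
DEFAULT_GROUP_GAINS: dict[str, float] = {
    "strong": 3.0, "medium": 1.5, "weak": 0.5,
}

_FWHM_TO_SD = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass
class ERPComponentSpec:
    """One stimulus-locked ERP component.

    A component is a Gaussian bump in time, ``amplitude`` microvolts at its
    peak, ``width`` ms full-width-at-half-maximum, centred at
    ``latency_mean`` ms with Gaussian trial-to-trial jitter, projected onto
    the scalp by a per-channel ``topography`` weight vector in [-1, 1].
    Components flagged ``deviant_only`` (the P3 and the late negativity)
    appear only in deviant trials; exogenous early components appear in
    both classes.
    """

    name: str
    latency_mean: float          # ms
    latency_jitter_sd: float     # ms
    amplitude: float             # microvolts, signed
    width: float                 # ms, FWHM
    topography: np.ndarray       # (n_channels,), weights in [-1, 1]
    deviant_only: bool = True

    def __post_init__(self) -> None:
        self.topography = np.asarray(self.topography, dtype=float)
        if self.width <= 0:
            raise ConfigurationError(f"{self.name}: width must be > 0")
        if np.abs(self.topography).max() > 1.0 + 1e-12:
            raise ConfigurationError(f"{self.name}: topography outside [-1, 1]")


@dataclass
class SubjectProfile:
    """Generative parameters for one simulated subject.

    ``p3_gain`` multiplies the P3 amplitude (the planted group structure);
    ``latency_shift_ms`` and ``amp_scale`` implement between-subject domain
    shift; ``jitter_scale`` multiplies every component's latency jitter SD.
    """

    subject_id: str
    group: str
    p3_gain: float
    noise_sd: float              # microvolts
    jitter_scale: float = 1.0
    latency_shift_ms: float = 0.0
    amp_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.p3_gain < 0:
            raise ConfigurationError("p3_gain must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass
class SynthConfig:
    """Cohort-level generation parameters.

    Defaults mirror the acquisition this simulator emulates: 61 channels,
    100 Hz, 1 s epochs, 300-500 valid trials per subject at a deviant :
    standard ratio of ~1:4.3.
    """

    n_subjects_per_group: int = 5
    channels: int = 61
    fs: float = 100.0
    trial_len: int = 100                 # samples (T)
    imbalance_ratio: float = 4.3         # standards per deviant
    n_trials: int = 400
    seed: int = 0
    # cohort heterogeneity (domain shift across subjects)
    noise_sd: float = 8.0                # microvolts, cohort mean
    noise_rel_sd: float = 0.15           # lognormal spread of noise_sd
    gain_rel_sd: float = 0.15            # lognormal spread of p3_gain
    latency_shift_sd_ms: float = 15.0    # per-subject ERP latency offset
    jitter_scale_range: tuple[float, float] = (0.75, 1.25)
    white_noise_fraction: float = 0.3    # rest is 1/f-shaped

    def __post_init__(self) -> None:
        if self.imbalance_ratio < 1:
            raise ConfigurationError("imbalance_ratio must be >= 1")
        if not (20 <= self.n_trials <= 2000):
            raise ConfigurationError("n_trials outside the valid range [20, 2000]")
        if self.channels < 1 or self.trial_len < 2 or self.fs <= 0:
            raise ConfigurationError("invalid channels/trial_len/fs")


def default_components(n_channels: int) -> list[ERPComponentSpec]:
    """The default four-component deviant ERP.

    Amplitudes and latencies follow the usual visual-oddball morphology:
    early posterior P1/P2 (present in both classes), a centro-parietal P3
    at 400 ms whose amplitude carries the group structure, and a
    fronto-central negative wave at 600 ms.  The P3 jitter SD of 40 ms
    emulates the loose time-locking of video-evoked responses.
    """
    occ = montage.gaussian_topography(n_channels, montage.FOCI["occipital"])
    cp = montage.gaussian_topography(n_channels, montage.FOCI["centro_parietal"])
    fc = montage.gaussian_topography(n_channels, montage.FOCI["fronto_central"])
    return [
        ERPComponentSpec("P1", 100.0, 10.0, 2.0, 40.0, occ, deviant_only=False),
        ERPComponentSpec("P2", 200.0, 15.0, 3.0, 50.0, occ, deviant_only=False),
        ERPComponentSpec("P3", 400.0, 40.0, 8.0, 120.0, cp, deviant_only=True),
        ERPComponentSpec("LateNeg", 600.0, 40.0, -6.0, 150.0, fc,
                         deviant_only=True),
    ]


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                n_samples: int) -> np.ndarray:
    """Unit-SD 1/f-amplitude Gaussian noise along the last axis."""
    n_freq = n_samples // 2 + 1
    freqs = np.arange(n_freq, dtype=float)
    scale = np.zeros(n_freq)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (rng.standard_normal(shape + (n_freq,))
            + 1j * rng.standard_normal(shape + (n_freq,))) * scale
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _noise(rng: np.random.Generator, shape: tuple[int, ...], n_samples: int,
           white_fraction: float) -> np.ndarray:
    """Unit-SD mixture of 1/f-shaped and white Gaussian noise."""
    w = float(np.clip(white_fraction, 0.0, 1.0))
    out = np.zeros(shape + (n_samples,))
    if w < 1.0:
        out += np.sqrt(1.0 - w) * _pink_noise(rng, shape, n_samples)
    if w > 0.0:
        out += np.sqrt(w) * rng.standard_normal(shape + (n_samples,))
    return out


def _component_waveforms(profile: SubjectProfile,
                         components: list[ERPComponentSpec],
                         is_deviant: np.ndarray,
                         fs: float, n_samples: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Stacked ERP signal for a batch of trials: (n, channels, T)."""
    n = is_deviant.shape[0]
    t_ms = np.arange(n_samples) / fs * 1000.0
    window_ms = n_samples / fs * 1000.0
    out = np.zeros((n, len(components[0].topography), n_samples))
    for comp in components:
        mean_lat = comp.latency_mean + profile.latency_shift_ms
        if not (0.0 <= comp.latency_mean < window_ms):
            raise ConfigurationError(
                f"component {comp.name}: latency {comp.latency_mean} ms "
                f"outside the [0, {window_ms}) ms trial window")
        # jitter drawn for every trial (keeps the rng stream independent of
        # the class pattern); clipped so the bump centre stays in-window
        lat = mean_lat + rng.normal(
            0.0, comp.latency_jitter_sd * profile.jitter_scale, size=n)
        lat = np.clip(lat, 0.0, np.nextafter(window_ms, 0.0))
        active = is_deviant if comp.deviant_only else np.ones(n, dtype=bool)
        amp = comp.amplitude * profile.amp_scale
        if comp.name == "P3":
            amp = amp * profile.p3_gain
        sd = comp.width * _FWHM_TO_SD
        bump = amp * np.exp(-((t_ms[None, :] - lat[:, None]) ** 2)
                            / (2.0 * sd ** 2))          # (n, T)
        bump[~active] = 0.0
        out += comp.topography[None, :, None] * bump[:, None, :]
    return out


def simulate_trial(profile: SubjectProfile,
                   components: list[ERPComponentSpec],
                   is_deviant: bool,
                   rng: np.random.Generator,
                   fs: float = 100.0,
                   n_samples: int = 100,
                   white_noise_fraction: float = 0.3) -> np.ndarray:
    """Simulate one trial; returns a (channels, T) matrix in microvolts.

    Deviant trials carry every component; standard trials only the
    non-deviant-locked ones. Deterministic given the rng state.
    """
    flag = np.array([bool(is_deviant)])
    signal = _component_waveforms(profile, components, flag, fs, n_samples,
                                  rng)[0]
    noise = profile.noise_sd * _noise(rng, (signal.shape[0],), n_samples,
                                      white_noise_fraction)
    return signal + noise


def deviant_count(n_trials: int, imbalance_ratio: float) -> int:
    """Number of deviant trials: round(n / (1 + ratio)), at least 1."""
    return max(1, round(n_trials / (1.0 + imbalance_ratio)))


def simulate_subject(profile: SubjectProfile, config: SynthConfig,
                     rng: np.random.Generator,
                     components: list[ERPComponentSpec] | None = None
                     ) -> EpochSet:
    """Simulate one subject's full epoched session."""
    if components is None:
        components = default_components(config.channels)
    n = config.n_trials
    n_dev = deviant_count(n, config.imbalance_ratio)
    labels = np.zeros(n, dtype=np.int8)
    labels[rng.permutation(n)[:n_dev]] = 1
    signal = _component_waveforms(profile, components, labels == 1,
                                  config.fs, config.trial_len, rng)
    noise = profile.noise_sd * _noise(rng, (n, config.channels),
                                     config.trial_len,
                                     config.white_noise_fraction)
    return EpochSet(trials=signal + noise, labels=labels, fs=config.fs,
                    subject_id=profile.subject_id)


def _draw_profile(subject_id: str, group: str, gain: float,
                  config: SynthConfig, rng: np.random.Generator
                  ) -> SubjectProfile:
    lo, hi = config.jitter_scale_range
    return SubjectProfile(
        subject_id=subject_id,
        group=group,
        p3_gain=gain * float(np.exp(rng.normal(0.0, config.gain_rel_sd))),
        noise_sd=config.noise_sd
        * float(np.exp(rng.normal(0.0, config.noise_rel_sd))),
        jitter_scale=float(rng.uniform(lo, hi)),
        latency_shift_ms=float(rng.normal(0.0, config.latency_shift_sd_ms)),
    )


def simulate_cohort(config: SynthConfig,
                    group_gains: dict[str, float] | None = None,
                    components: list[ERPComponentSpec] | None = None
                    ) -> tuple[list[EpochSet], list[SubjectProfile]]:
    """Simulate a three-group cohort; the ground-truth profiles are
    returned alongside the data for recovery tests."""
    if group_gains is None:
        group_gains = dict(DEFAULT_GROUP_GAINS)
    missing = set(GROUPS) - set(group_gains)
    if missing:
        raise ConfigurationError(f"group_gains missing groups: {sorted(missing)}")
    rng = np.random.default_rng(config.seed)
    cohort: list[EpochSet] = []
    profiles: list[SubjectProfile] = []
    for group in GROUPS:
        for i in range(config.n_subjects_per_group):
            sid = f"{group}{i:02d}"
            profile = _draw_profile(sid, group, group_gains[group], config, rng)
            # independent per-subject stream so a subject's data does not
            # depend on how many subjects precede it
            sub_rng = np.random.default_rng(rng.integers(2 ** 31))
            cohort.append(simulate_subject(profile, config, sub_rng,
                                           components))
            profiles.append(profile)
    return cohort, profiles


def save_cohort(cohort: list[EpochSet], profiles: list[SubjectProfile],
                out_dir) -> None:
    """Write one HDF5 file per subject plus a JSON ground-truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ep in cohort:
        save_epochs(ep, out / f"{ep.subject_id}.h5")
    manifest = [
        {"subject_id": p.subject_id, "group": p.group,
         "p3_gain": p.p3_gain, "noise_sd": p.noise_sd,
         "jitter_scale": p.jitter_scale,
         "latency_shift_ms": p.latency_shift_ms, "amp_scale": p.amp_scale}
        for p in profiles
    ]
    (out / "profiles.json").write_text(json.dumps(manifest, indent=2))
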