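"""Epoched-EEG container and its HDF5 on-disk format.

An :class:`EpochSet` is the currency passed between every stage of the
pipeline: one subject's single-trial epochs (trials x channels x time, in
microvolts), a binary label per trial (1 = deviant/target, 0 = standard),
the sampling rate and channel names.

On disk each subject is one HDF5 file with datasets ``/trials`` (float32)
and ``/labels`` (int8) and root attributes ``fs``, ``subject_id`` and
``channel_names``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .errors import ConfigurationError

__all__ = ["EpochSet", "load_epochs", "save_epochs"]


@dataclass
class EpochSet:
    """One subject's epoched trials with binary deviant/standard labels.

    Parameters
    ----------
    trials : ndarray, shape (n, channels, T)
        Single-trial EEG in microvolts.
    labels : ndarray, shape (n,)
        1 for deviant (rare target) trials, 0 for standard trials.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
    subject_id : str
    """

    trials: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.trials.ndim != 3:
            raise ConfigurationError(
                f"trials must be (n, channels, T), got shape {self.trials.shape}")
        if self.labels.shape != (self.trials.shape[0],):
            raise ConfigurationError(
                f"labels length {self.labels.shape} does not match "
                f"{self.trials.shape[0]} trials")
        if not np.isfinite(self.trials).all():
            raise ConfigurationError("trials contain non-finite values")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ConfigurationError("channel_names length != channel count")

    # -- basic views ---------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[2]

    @property
    def deviant_mask(self) -> np.ndarray:
        return self.labels == 1

    def subset(self, idx: np.ndarray | list[int]) -> "EpochSet":
        """Return a new EpochSet restricted to the given trial indices."""
        idx = np.asarray(idx)
        return replace(self, trials=self.trials[idx], labels=self.labels[idx])

    def unlabeled(self) -> "EpochSet":
        """View with all labels zeroed — what the trainer may see for a
        target subject (labels must never leak into training)."""
        return replace(self, labels=np.zeros(self.n_trials, dtype=np.int8))


def save_epochs(epochs: EpochSet, path) -> None:
    """Write one subject to the HDF5 epoch container.

    ``track_times=False`` keeps output byte-identical across runs for the
    same data.
    """
    with h5py.File(path, "w", track_order=True) as f:
        f.create_dataset("trials", data=epochs.trials.astype(np.float32),
                         track_times=False)
        f.create_dataset("labels", data=epochs.labels.astype(np.int8),
                         track_times=False)
        f.attrs["fs"] = float(epochs.fs)
        f.attrs["subject_id"] = epochs.subject_id
        f.attrs["channel_names"] = [str(c) for c in epochs.channel_names]


def load_epochs(path) -> EpochSet:
    """Read one subject from the HDF5 epoch container."""
    with h5py.File(path, "r") as f:
        return EpochSet(
            trials=f["trials"][()].astype(np.float64),
            labels=f["labels"][()],
            fs=float(f.attrs["fs"]),
            channel_names=[str(c) for c in f.attrs["channel_names"]],
            subject_id=str(f.attrs["subject_id"]),
        )
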