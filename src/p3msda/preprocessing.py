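"""Trial-level cleaning, ERP averaging, latency alignment and P3 peak maps.

The pipeline feeding the source-domain selector is: amplitude rejection ->
cross-correlation alignment of deviant trials -> deviant-ERP averaging ->
extraction of the scalp topography at the P3 peak.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import correlate, correlation_lags

from . import montage
from .containers import EpochSet
from .errors import ConfigurationError, EmptySelectionError

__all__ = ["ERPTemplate", "P3Map", "reject_amplitude", "align_trials",
           "average_erp", "extract_p3_map", "DEFAULT_P3_WINDOW_MS"]

#: default P3 search window (ms post-onset)
DEFAULT_P3_WINDOW_MS: tuple[float, float] = (250.0, 600.0)


@dataclass
class ERPTemplate:
    """A class-averaged ERP: (channels, T) microvolts."""

    erp: np.ndarray
    n_averaged: int
    fs: float

    def __post_init__(self) -> None:
        self.erp = np.asarray(self.erp, dtype=float)
        if self.n_averaged < 1:
            raise ConfigurationError("n_averaged must be >= 1")


@dataclass
class P3Map:
    """Scalp topography at the P3 peak: the per-channel ERP amplitude at
    one sample index inside the search window."""

    topography: np.ndarray       # (channels,), microvolts
    peak_time: int               # sample index
    window: tuple[int, int]      # (start, end) samples, half-open

    def __post_init__(self) -> None:
        if not (self.window[0] <= self.peak_time < self.window[1]):
            raise ConfigurationError("peak_time outside window")


def reject_amplitude(epochs: EpochSet, threshold: float) -> EpochSet:
    """Drop every trial whose absolute amplitude exceeds ``threshold`` uV
    on any channel/sample. Labels are filtered in lockstep. Idempotent."""
    if threshold <= 0:
        raise ConfigurationError("threshold must be > 0")
    keep = np.abs(epochs.trials).max(axis=(1, 2)) <= threshold
    if not keep.any():
        raise EmptySelectionError(
            f"amplitude rejection at {threshold} uV removed all "
            f"{epochs.n_trials} trials")
    return epochs.subset(np.flatnonzero(keep))


def _roi_trace(x: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Mean over the region-of-interest channels; x is (..., ch, T)."""
    return x[..., roi, :].mean(axis=-2)


def _best_lag(trace: np.ndarray, ref: np.ndarray, max_lag: int) -> int:
    """Lag (applied to ``trace``) maximising cross-correlation with ``ref``,
    restricted to |lag| <= max_lag. Ties break toward the smallest shift."""
    cc = correlate(ref, trace, mode="full")
    lags = correlation_lags(len(ref), len(trace), mode="full")
    ok = np.abs(lags) <= max_lag
    cc, lags = cc[ok], lags[ok]
    # prefer the smallest |lag| (then the earlier one) among ties
    order = np.lexsort((lags, np.abs(lags)))
    cc, lags = cc[order], lags[order]
    return int(lags[np.argmax(cc)])


def _shift(trial: np.ndarray, lag: int) -> np.ndarray:
    """Shift a (ch, T) trial by ``lag`` samples with zero padding (no
    wraparound, so late components never teleport to trial start)."""
    if lag == 0:
        return trial
    out = np.zeros_like(trial)
    if lag > 0:
        out[:, lag:] = trial[:, :-lag]
    else:
        out[:, :lag] = trial[:, -lag:]
    return out


def align_trials(epochs: EpochSet, template: ERPTemplate, max_lag: int,
                 roi: np.ndarray | None = None) -> EpochSet:
    """Latency-align deviant trials to an ERP template.

    Each deviant trial's region-of-interest mean trace is cross-correlated
    with the template's; the trial is shifted (zero-padded) by the lag in
    [-max_lag, max_lag] that maximises the correlation. Standard trials are
    left untouched, and neither trial count nor labels change.

    This is a cross-correlation stand-in for more elaborate iterative ERP
    alignment schemes; it recovers pure shifts exactly and is sufficient
    for the Gaussian-bump jitter the simulator plants.
    """
    if max_lag >= epochs.n_samples // 2:
        raise ConfigurationError("max_lag must be < T/2")
    if roi is None:
        roi = montage.roi_channels(epochs.n_channels)
    if max_lag == 0:
        return replace(epochs)
    ref = _roi_trace(template.erp, roi)
    trials = epochs.trials.copy()
    for i in np.flatnonzero(epochs.deviant_mask):
        lag = _best_lag(_roi_trace(trials[i], roi), ref, max_lag)
        trials[i] = _shift(trials[i], lag)
    return replace(epochs, trials=trials)


def average_erp(epochs: EpochSet, which: str = "deviant") -> ERPTemplate:
    """Channelwise mean over the trials of one class."""
    if which not in ("deviant", "standard"):
        raise ConfigurationError(f"unknown class {which!r}")
    mask = epochs.deviant_mask if which == "deviant" else ~epochs.deviant_mask
    n = int(mask.sum())
    if n == 0:
        raise EmptySelectionError(f"no {which} trials to average")
    return ERPTemplate(erp=epochs.trials[mask].mean(axis=0), n_averaged=n,
                       fs=epochs.fs)


def extract_p3_map(template: ERPTemplate,
                   window_ms: tuple[float, float] = DEFAULT_P3_WINDOW_MS,
                   roi: np.ndarray | None = None) -> P3Map:
    """Scalp map at the P3 peak.

    The peak is the argmax, inside the search window, of the ERP averaged
    over the centro-parietal region-of-interest channels; ties break toward
    the earliest sample. The topography is the full-channel ERP column at
    that sample.
    """
    n_ch, n_t = template.erp.shape
    start = int(np.floor(window_ms[0] / 1000.0 * template.fs))
    end = int(np.ceil(window_ms[1] / 1000.0 * template.fs))
    start, end = max(start, 0), min(end, n_t)
    if start >= end:
        raise ConfigurationError(
            f"empty P3 search window {window_ms} ms for T={n_t}")
    if roi is None:
        roi = montage.roi_channels(n_ch)
    trace = _roi_trace(template.erp, roi)
    peak = start + int(np.argmax(trace[start:end]))  # argmax: earliest tie
    return P3Map(topography=template.erp[:, peak].copy(), peak_time=peak,
                 window=(start, end))
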