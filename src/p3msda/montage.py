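"""Synthetic sensor layout.

Real montage geometry is deliberately not required: channels are placed on
a sunflower (Fibonacci) spiral filling the unit disc, which gives an even
2-D scatter for any channel count. Scalp positions are only used for two
things: building smooth Gaussian component topographies and nominating a
"Pz-like" centro-parietal channel set for P3 peak finding.

Coordinate convention: +y is anterior (front of head), -y posterior,
unit-disc radius 1.
"""

from __future__ import annotations

import numpy as np

__all__ = ["channel_positions", "gaussian_topography", "roi_channels",
           "FOCI"]

# canonical component foci on the unit disc (x, y); chosen to mimic the
# usual ERP geometry: early visual components posterior, P3
# centro-parietal, late negativity fronto-central.
FOCI: dict[str, tuple[float, float]] = {
    "occipital": (0.0, -0.75),
    "centro_parietal": (0.0, -0.25),
    "fronto_central": (0.0, 0.35),
}

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def channel_positions(n_channels: int) -> np.ndarray:
    """(n_channels, 2) x/y positions on a sunflower spiral in the unit disc."""
    k = np.arange(n_channels)
    r = np.sqrt((k + 0.5) / n_channels)
    theta = k * _GOLDEN_ANGLE
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def gaussian_topography(n_channels: int, focus: tuple[float, float],
                        spread: float = 0.45) -> np.ndarray:
    """Per-channel weights in (0, 1]: Gaussian falloff from ``focus``.

    ``spread`` is the spatial SD in unit-disc radii; the peak channel gets
    a weight close to 1 (exactly 1 only if a channel sits on the focus).
    """
    pos = channel_positions(n_channels)
    d2 = ((pos - np.asarray(focus)) ** 2).sum(axis=1)
    return np.exp(-d2 / (2.0 * spread ** 2))


def roi_channels(n_channels: int, focus: tuple[float, float] | None = None,
                 k: int = 5) -> np.ndarray:
    """Indices of the ``k`` channels nearest ``focus`` (default: the
    centro-parietal P3 focus), sorted by distance.

    This is the default channel set used for P3 peak finding and trial
    alignment on synthetic cohorts.
    """
    if focus is None:
        focus = FOCI["centro_parietal"]
    pos = channel_positions(n_channels)
    d2 = ((pos - np.asarray(focus)) ** 2).sum(axis=1)
    k = min(k, n_channels)
    order = np.argsort(d2, kind="stable")
    return order[:k]
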