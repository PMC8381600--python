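"""Source-domain selection: subject features and strength clustering.

Transfer works best from donors whose target-evoked response is strong, so
labeled subjects are scored by one of four criteria and clustered into
strong / medium / weak groups; the strong group supplies the source
domains.

Criteria
--------
``p3_map``
    The scalp topography (one value per channel) of the aligned deviant
    ERP at its P3 peak — carries both strength and spatial distribution.
``deviant_energy``
    Total squared amplitude of the deviant ERP over all channels and the
    whole epoch.
``energy_ratio``
    Deviant-ERP energy over standard-ERP energy — a contrast measure.
``snr``
    Deviant-ERP energy over the mean residual energy of single deviant
    trials about that ERP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .containers import EpochSet
from .errors import ConfigurationError, DegenerateInputError, EmptySelectionError
from .preprocessing import (DEFAULT_P3_WINDOW_MS, align_trials, average_erp,
                            extract_p3_map)

__all__ = [
    "SubjectFeature", "GroupAssignment",
    "criterion_p3_map", "criterion_deviant_energy", "criterion_energy_ratio",
    "criterion_snr", "compute_feature", "cluster_subjects",
    "select_source_subjects", "CRITERIA",
]

GROUP_ORDER = ("strong", "medium", "weak")


@dataclass
class SubjectFeature:
    """One subject's feature under one clustering criterion; ``vector`` has
    one entry per channel for ``p3_map`` and length 1 for the scalar
    criteria."""

    subject_id: str
    criterion: str
    vector: np.ndarray

    def __post_init__(self) -> None:
        self.vector = np.atleast_1d(np.asarray(self.vector, dtype=float))
        # +inf is allowed as the documented SNR saturation sentinel
        if np.isnan(self.vector).any():
            raise DegenerateInputError(
                f"{self.subject_id}: NaN feature values")

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.vector))


@dataclass
class GroupAssignment:
    """Subject -> strong/medium/weak mapping plus per-group mean feature
    magnitudes (descending by construction)."""

    groups: dict[str, str]
    group_centers: dict[str, float]
    degenerate: bool = False

    def members(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]


def _erp_energy(erp: np.ndarray) -> float:
    return float(np.sum(erp ** 2))


def criterion_p3_map(epochs: EpochSet, max_lag: int = 10,
                     window_ms: tuple[float, float] = DEFAULT_P3_WINDOW_MS,
                     roi: np.ndarray | None = None) -> SubjectFeature:
    """P3-peak scalp map of the aligned deviant ERP.

    Deviant trials are first aligned (cross-correlation against the
    unaligned deviant ERP), then re-averaged; the topography at the P3
    peak is the feature vector.
    """
    template0 = average_erp(epochs, "deviant")
    aligned = align_trials(epochs, template0, max_lag=max_lag, roi=roi)
    template = average_erp(aligned, "deviant")
    p3 = extract_p3_map(template, window_ms=window_ms, roi=roi)
    return SubjectFeature(epochs.subject_id, "p3_map", p3.topography)


def criterion_deviant_energy(epochs: EpochSet) -> SubjectFeature:
    """Energy of the deviant ERP over the full epoch and all channels."""
    erp = average_erp(epochs, "deviant").erp
    return SubjectFeature(epochs.subject_id, "deviant_energy",
                          [_erp_energy(erp)])


def criterion_energy_ratio(epochs: EpochSet) -> SubjectFeature:
    """Deviant-ERP energy / standard-ERP energy."""
    e_dev = _erp_energy(average_erp(epochs, "deviant").erp)
    e_std = _erp_energy(average_erp(epochs, "standard").erp)
    if e_std == 0.0:
        raise DegenerateInputError(
            f"{epochs.subject_id}: standard-ERP energy is zero")
    return SubjectFeature(epochs.subject_id, "energy_ratio", [e_dev / e_std])


def criterion_snr(epochs: EpochSet) -> SubjectFeature:
    """Deviant-ERP energy / mean single-trial residual energy.

    The "noise" of a trial is its difference from the deviant ERP; with
    identical trials the noise energy is zero and the score saturates at
    ``inf`` (returned as a sentinel, flagged by the caller).
    """
    mask = epochs.deviant_mask
    if mask.sum() < 2:
        raise DegenerateInputError(
            f"{epochs.subject_id}: SNR needs >= 2 deviant trials")
    erp = average_erp(epochs, "deviant").erp
    resid = epochs.trials[mask] - erp[None]
    noise_energy = float(np.mean(np.sum(resid ** 2, axis=(1, 2))))
    if noise_energy == 0.0:
        warnings.warn(f"{epochs.subject_id}: zero residual energy, SNR=inf",
                      stacklevel=2)
        return SubjectFeature(epochs.subject_id, "snr", [np.inf])
    return SubjectFeature(epochs.subject_id, "snr",
                          [_erp_energy(erp) / noise_energy])


CRITERIA = {
    "p3_map": criterion_p3_map,
    "deviant_energy": criterion_deviant_energy,
    "energy_ratio": criterion_energy_ratio,
    "snr": criterion_snr,
}


def compute_feature(epochs: EpochSet, criterion: str = "p3_map",
                    **kwargs) -> SubjectFeature:
    """Dispatch to one of the four clustering criteria by name."""
    try:
        fn = CRITERIA[criterion]
    except KeyError:
        raise ConfigurationError(
            f"unknown criterion {criterion!r}; choose from {sorted(CRITERIA)}")
    return fn(epochs, **kwargs)


def cluster_subjects(features: list[SubjectFeature], k: int = 3,
                     seed: int = 0, n_init: int = 10,
                     normalize: bool = False) -> GroupAssignment:
    """k-means the subject features into strength groups.

    Clusters are relabeled strong/medium/weak by descending mean member
    feature magnitude (L2 norm; for scalar criteria, the scalar itself).
    ``normalize=True`` clusters unit-norm vectors instead of raw ones
    (spatial-pattern rather than strength clustering).
    """
    if len(features) < k:
        raise ConfigurationError(f"need >= {k} subjects, got {len(features)}")
    crits = {f.criterion for f in features}
    if len(crits) != 1:
        raise ConfigurationError(f"mixed criteria {sorted(crits)}")
    dims = {f.vector.shape for f in features}
    if len(dims) != 1:
        raise ConfigurationError("inhomogeneous feature vector lengths")

    X = np.stack([f.vector for f in features])
    if normalize:
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        X = X / norms
    degenerate = bool(np.allclose(X, X[0]))

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    cluster_ids = km.fit_predict(X)

    # order clusters by descending mean member magnitude
    mags = np.array([f.magnitude for f in features])
    order = np.argsort(
        [-mags[cluster_ids == c].mean() if (cluster_ids == c).any() else np.inf
         for c in range(k)], kind="stable")
    names = list(GROUP_ORDER[:k])
    relabel = {int(c): names[rank] for rank, c in enumerate(order)}

    groups = {f.subject_id: relabel[int(c)]
              for f, c in zip(features, cluster_ids)}
    centers = {
        name: float(mags[[relabel[int(c)] == name for c in cluster_ids]].mean())
        if any(relabel[int(c)] == name for c in cluster_ids) else np.nan
        for name in names
    }
    if degenerate:
        warnings.warn("all subject features identical; grouping is arbitrary",
                      stacklevel=2)
    return GroupAssignment(groups=groups, group_centers=centers,
                           degenerate=degenerate)


def select_source_subjects(assignment: GroupAssignment, group: str = "strong",
                           n: int | None = None, seed: int = 0) -> list[str]:
    """Sample ``n`` subjects (without replacement, seeded) from one group;
    ``n=None`` returns the whole group (in insertion order)."""
    members = assignment.members(group)
    if not members:
        raise EmptySelectionError(f"group {group!r} is empty")
    if n is None or n == len(members):
        return list(members)
    if n > len(members):
        raise ConfigurationError(
            f"requested {n} subjects from group {group!r} of size {len(members)}")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(members), size=n, replace=False)
    return [members[i] for i in sorted(idx)]
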