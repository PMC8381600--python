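"""Subject-strength criteria and the strength-group clustering."""

import itertools

import numpy as np
import pytest

from p3msda.containers import EpochSet
from p3msda.errors import ConfigurationError, DegenerateInputError
from p3msda.source_selection import (SubjectFeature, cluster_subjects,
                                     compute_feature, criterion_deviant_energy,
                                     criterion_energy_ratio, criterion_p3_map,
                                     criterion_snr, select_source_subjects)
from conftest import make_subject


def epochs_from(trials, labels, subject_id="s"):
    return EpochSet(trials=np.asarray(trials, dtype=float),
                    labels=np.asarray(labels), fs=100.0,
                    subject_id=subject_id)


def scalar_features(values):
    return [SubjectFeature(f"s{i}", "deviant_energy", [v])
            for i, v in enumerate(values)]


class TestCriteria:
    def test_deviant_energy_hand_sum(self):
        # deviant ERP all ones over 2 channels x 3 samples -> energy 6
        trials = np.ones((2, 2, 3))
        f = criterion_deviant_energy(epochs_from(trials, [1, 1]))
        assert f.vector[0] == pytest.approx(6.0)

    def test_deviant_energy_zero_and_quadratic_scaling(self):
        z = criterion_deviant_energy(epochs_from(np.zeros((2, 2, 3)),
                                                 [1, 1]))
        assert z.vector[0] == 0.0
        base = np.full((1, 2, 3), 2.0)
        e1 = criterion_deviant_energy(epochs_from(base, [1])).vector[0]
        e2 = criterion_deviant_energy(epochs_from(2 * base, [1])).vector[0]
        assert e2 == pytest.approx(4 * e1)

    def test_energy_ratio_identical_classes_is_one(self, rng):
        t = rng.standard_normal((1, 2, 5))
        ep = epochs_from(np.concatenate([t, t]), [1, 0])
        assert criterion_energy_ratio(ep).vector[0] == pytest.approx(1.0)

    def test_energy_ratio_quadratic_in_amplitude(self, rng):
        t = rng.standard_normal((1, 2, 5))
        ep = epochs_from(np.concatenate([2 * t, t]), [1, 0])
        assert criterion_energy_ratio(ep).vector[0] == pytest.approx(4.0)

    def test_energy_ratio_zero_denominator_raises(self):
        ep = epochs_from(np.stack([np.ones((2, 3)), np.zeros((2, 3))]),
                         [1, 0])
        with pytest.raises(DegenerateInputError):
            criterion_energy_ratio(ep)

    def test_snr_identical_trials_saturates(self):
        t = np.ones((3, 2, 5))
        with pytest.warns(UserWarning, match="SNR"):
            f = criterion_snr(epochs_from(t, [1, 1, 1]))
        assert np.isinf(f.vector[0])

    def test_snr_single_deviant_rejected(self):
        ep = epochs_from(np.ones((2, 2, 5)), [1, 0])
        with pytest.raises(DegenerateInputError):
            criterion_snr(ep)

    def test_snr_of_pure_noise_is_small(self, rng):
        trials = rng.standard_normal((100, 2, 50))
        ep = epochs_from(trials, np.ones(100, dtype=int))
        f = criterion_snr(ep)
        # ERP of pure noise has energy ~ sigma^2/n per point
        assert f.vector[0] < 0.1

    def test_snr_decreases_with_noise(self):
        f = {}
        for sd in (4.0, 8.0):
            ep = make_subject(noise_sd=sd, n_trials=200, seed=4)
            f[sd] = criterion_snr(ep).vector[0]
        assert f[8.0] < f[4.0]

    def test_p3_map_norm_orders_gains(self):
        strong = make_subject("hi", p3_gain=3.0, n_trials=200, seed=6)
        weak = make_subject("lo", p3_gain=0.5, n_trials=200, seed=6)
        f_hi = criterion_p3_map(strong, max_lag=3)
        f_lo = criterion_p3_map(weak, max_lag=3)
        assert f_hi.magnitude > f_lo.magnitude
        assert len(f_hi.vector) == strong.n_channels

    def test_p3_map_zero_signal_near_zero(self, rng):
        n, sd = 200, 3.0
        trials = sd * rng.standard_normal((n, 4, 100))
        ep = epochs_from(trials, (np.arange(n) < 40).astype(int))
        f = criterion_p3_map(ep, max_lag=0)
        # each entry ~ N(0, sd/sqrt(40)); alignment off so pure averaging
        assert np.all(np.abs(f.vector) < 3 * sd / np.sqrt(40) + 1e-9)

    def test_deterministic_on_duplicate_input(self):
        ep = make_subject(seed=8)
        f1 = compute_feature(ep, "p3_map", max_lag=3)
        f2 = compute_feature(ep, "p3_map", max_lag=3)
        np.testing.assert_array_equal(f1.vector, f2.vector)

    def test_unknown_criterion_rejected(self, small_subject):
        with pytest.raises(ConfigurationError):
            compute_feature(small_subject, "banana")


def exhaustive_kmeans_1d(values, k=3):
    """Best k-partition of scalars by total within-cluster sum of squares,
    found by brute-force enumeration of all assignments."""
    best, best_ss = None, np.inf
    for assign in itertools.product(range(k), repeat=len(values)):
        if len(set(assign)) != k:
            continue
        ss = 0.0
        for c in range(k):
            pts = [v for v, a in zip(values, assign) if a == c]
            ss += sum((p - np.mean(pts)) ** 2 for p in pts)
        if ss < best_ss - 1e-12:
            best_ss, best = ss, assign
    return best


class TestClusterSubjects:
    def test_matches_exhaustive_oracle_on_six_points(self):
        values = [10.0, 9.0, 5.0, 4.5, 1.0, 0.8]
        asg = cluster_subjects(scalar_features(values), seed=0)
        oracle = exhaustive_kmeans_1d(values)
        # oracle partition: {10, 9} / {5, 4.5} / {1, 0.8}
        assert asg.groups == {"s0": "strong", "s1": "strong",
                              "s2": "medium", "s3": "medium",
                              "s4": "weak", "s5": "weak"}
        # same partition structure as the brute-force optimum
        oracle_parts = {frozenset(i for i, a in enumerate(oracle) if a == c)
                        for c in range(3)}
        ours = {frozenset(i for i, (s, g) in
                          enumerate(sorted(asg.groups.items())) if g == name)
                for name in ("strong", "medium", "weak")}
        assert ours == oracle_parts

    def test_group_centers_descend(self):
        asg = cluster_subjects(scalar_features([9, 8, 5, 4, 1, 0.5]), seed=1)
        c = asg.group_centers
        assert c["strong"] >= c["medium"] >= c["weak"]

    def test_relabeling_subjects_permutes_assignment(self):
        values = [10.0, 9.0, 5.0, 4.5, 1.0, 0.8]
        feats = scalar_features(values)
        perm = [3, 0, 5, 1, 4, 2]
        permuted = [SubjectFeature(f"s{i}", "deviant_energy",
                                   [values[p]])
                    for i, p in enumerate(perm)]
        a1 = cluster_subjects(feats, seed=0)
        a2 = cluster_subjects(permuted, seed=0)
        for i, p in enumerate(perm):
            assert a2.groups[f"s{i}"] == a1.groups[f"s{p}"]

    def test_identical_features_flagged_degenerate(self):
        with pytest.warns(UserWarning, match="identical"):
            asg = cluster_subjects(scalar_features([2.0] * 6), seed=0)
        assert asg.degenerate

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            cluster_subjects(scalar_features([1.0, 2.0]))

    def test_mixed_criteria_rejected(self):
        feats = scalar_features([1.0, 2.0, 3.0])
        feats[0].criterion = "snr"
        with pytest.raises(ConfigurationError, match="mixed"):
            cluster_subjects(feats)

    def test_planted_groups_recovered_small(self):
        # 2 subjects/group mini version of the recovery property
        feats = []
        for i, gain in enumerate([3.0, 3.1, 1.5, 1.4, 0.5, 0.6]):
            ep = make_subject(f"s{i}", p3_gain=gain, n_trials=150,
                              seed=20 + i)
            feats.append(criterion_p3_map(ep, max_lag=3))
        asg = cluster_subjects(feats, seed=0)
        assert [asg.groups[f"s{i}"] for i in range(6)] == \
            ["strong", "strong", "medium", "medium", "weak", "weak"]


class TestSelectSourceSubjects:
    def make_assignment(self):
        return cluster_subjects(scalar_features([9, 8, 7, 4, 3, 1]), seed=0)

    def test_full_group_returned_in_order(self):
        asg = self.make_assignment()
        members = asg.members("strong")
        assert select_source_subjects(asg, "strong", len(members)) == members

    def test_zero_returns_empty(self):
        assert select_source_subjects(self.make_assignment(), "strong", 0) \
            == []

    def test_seeded_subset_reproducible(self):
        asg = self.make_assignment()
        a = select_source_subjects(asg, "strong", 1, seed=5)
        b = select_source_subjects(asg, "strong", 1, seed=5)
        assert a == b and len(a) == 1

    def test_oversampling_rejected(self):
        with pytest.raises(ConfigurationError):
            select_source_subjects(self.make_assignment(), "weak", 10)
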