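"""Sliding-window ν-SVM decoding and its permutation chance band."""

import itertools

import numpy as np
import pytest

from odortrace import (DecodeConfig, SlidingDecoder, SynthConfig, compute_dff,
                       decode_from, features_at, generate_traceset,
                       permutation_chance, sliding_decode)

from conftest import make_traceset


def pattern_data(class_means, n_frames=40, noise=0.0, seed=0, zero_after=None,
                 n_trials=2):
    """Static per-class patterns held through the recording.

    class_means: (n_classes, n_units).  Returns a dff TraceSet with
    ``n_trials`` per class; patterns optionally zeroed from frame
    ``zero_after`` on.
    """
    rng = np.random.default_rng(seed)
    k, u = class_means.shape
    data = np.zeros((u, n_frames, k * n_trials))
    odors, trials = [], []
    s = 0
    for c in range(k):
        for t in range(n_trials):
            tr = np.tile(class_means[c][:, None], (1, n_frames))
            if zero_after is not None:
                tr[:, zero_after:] = 0.0
            data[:, :, s] = tr + rng.normal(0, noise, (u, n_frames))
            odors.append(f"od{c}")
            trials.append(t + 1)
            s += 1
    return make_traceset(data, stim_onset_frame=5, stim_duration_s=2.0,
                         odors=odors, trials=trials)


def separated_means(k=5, u=30, seed=1, scale=2.0):
    rng = np.random.default_rng(seed)
    return rng.normal(0, scale, (k, u))


class TestFeatures:
    def test_single_frame_window(self):
        ts = pattern_data(separated_means(), noise=0.1)
        X, y = features_at(ts, 7, width_s=1 / ts.frame_rate)
        np.testing.assert_allclose(X, ts.data[:, 7, :].T)
        assert list(y) == ts.stimuli["odor"].tolist()

    def test_two_second_window_is_ten_frames(self):
        ts = pattern_data(separated_means(), noise=0.1)
        X, _ = features_at(ts, 4, width_s=2.0)
        np.testing.assert_allclose(X, ts.data[:, 4:14, :].mean(axis=1).T)

    def test_matches_windowed_mean_oracle(self):
        rng = np.random.default_rng(3)
        ts = make_traceset(rng.normal(size=(6, 30, 4)), stim_onset_frame=5,
                           odors=["a", "a", "b", "b"], trials=[1, 2, 1, 2])
        X, _ = features_at(ts, 10, width_s=1.0)
        for s in range(4):
            for u in range(6):
                assert X[s, u] == pytest.approx(
                    np.mean([ts.data[u, f, s] for f in range(10, 15)]))

    def test_window_outside_recording_rejected(self):
        ts = pattern_data(separated_means())
        with pytest.raises(ValueError, match="exceeds the recording"):
            features_at(ts, 39, width_s=2.0)


class TestDecodeFrom:
    def test_separable_static_patterns_decode_perfectly(self):
        """Noiseless persistent patterns: success 1 at every test time;
        cross-checked against a nearest-centroid oracle."""
        means = separated_means()
        ts = pattern_data(means, noise=0.0)
        succ = decode_from(ts, 5, DecodeConfig(train_window_s=1.0))
        np.testing.assert_allclose(succ, 1.0)

        # nearest-centroid oracle agrees: the held-out trial's pattern is
        # closest to its own class mean at every frame
        for c in range(5):
            d = ((means - means[c]) ** 2).sum(axis=1)
            assert d.argmin() == c

    def test_patterns_zeroed_after_offset_fall_to_chance(self):
        means = separated_means()
        ts = pattern_data(means, noise=0.05, zero_after=15)
        succ = decode_from(ts, 5, DecodeConfig(train_window_s=1.0, seed=0))
        assert succ[:15].mean() > 0.9
        cfg = DecodeConfig(train_window_s=1.0, n_permutations=100, seed=4)
        _, upper, _ = permutation_chance(ts, cfg, train_frames=np.array([5]))
        assert succ[20:].mean() <= upper[0]

    def test_identical_class_statistics_stay_at_chance(self):
        """Two classes drawn from one distribution hover around 0.5."""
        rng = np.random.default_rng(8)
        data = rng.normal(0, 1, (20, 30, 8))
        ts = make_traceset(data, stim_onset_frame=5, stim_duration_s=2.0,
                           odors=["x"] * 4 + ["y"] * 4,
                           trials=[1, 2, 3, 4] * 2)
        succ = decode_from(ts, 5, DecodeConfig(train_window_s=1.0))
        cfg = DecodeConfig(train_window_s=1.0, n_permutations=200, seed=1,
                           eval_window=(0, 30))
        mean_c, upper, _ = permutation_chance(ts, cfg,
                                              train_frames=np.array([5]))
        assert abs(succ.mean() - 0.5) < max(upper[0] - mean_c[0], 0.25)

    def test_unit_reordering_invariance(self):
        means = separated_means(k=3, u=12)
        ts = pattern_data(means, noise=0.2, seed=5)
        perm = np.random.default_rng(0).permutation(12)
        shuffled = ts.select_units(perm)
        cfg = DecodeConfig(train_window_s=1.0)
        np.testing.assert_allclose(decode_from(ts, 5, cfg),
                                   decode_from(shuffled, 5, cfg))

    def test_single_class_rejected(self):
        ts = pattern_data(separated_means(k=1, u=10))
        with pytest.raises(ValueError, match="at least 2"):
            decode_from(ts, 5, DecodeConfig())

    def test_single_trial_class_flagged_resubstitution(self):
        """A class with one trial stays in training and is scored by
        resubstitution instead of crashing the ν-SVM."""
        means = separated_means(k=3, u=15)
        ts = pattern_data(means, noise=0.01)
        keep = [0, 1, 2, 3, 4]           # drop trial 2 of class 2
        ts2 = make_traceset(ts.data[:, :, keep], stim_onset_frame=5,
                            stim_duration_s=2.0,
                            odors=[ts.stimuli["odor"].iloc[i] for i in keep],
                            trials=[ts.stimuli["trial"].iloc[i] for i in keep])
        succ = decode_from(ts2, 5, DecodeConfig(train_window_s=1.0))
        assert succ.mean() > 0.9


class TestSlidingDecode:
    def test_resubstitution_reaches_one_at_train_window(self):
        """Separable data, train = test window → success is trivially 1."""
        ts = pattern_data(separated_means(), noise=0.02)
        cfg = DecodeConfig(train_window_s=1.0, cv="resubstitution",
                           train_stride=10, n_permutations=5)
        res = SlidingDecoder(ts, cfg).fit(compute_chance=False)
        i = list(res.train_frames).index(10)
        assert res.success[i, 10:15].mean() == pytest.approx(1.0)

    def test_monotone_in_signal_amplitude(self):
        """More signal never hurts the odor-window stimulus average."""
        prev = -1.0
        for amp in (0.02, 0.2, 2.0):
            cfg = SynthConfig(n_animals=2, units_per_animal=15, seed=3,
                              response_amp_mean=amp, response_amp_sd=amp * 0.3,
                              bleach_a=0.0, bleach_c=1.0)
            dff = compute_dff(generate_traceset(cfg)[0])
            dcfg = DecodeConfig(seed=0)
            res = SlidingDecoder(dff, dcfg).fit(
                compute_chance=False, train_frames=np.array([30]))
            assert res.stim_avg[0] >= prev - 0.05
            prev = res.stim_avg[0]

    def test_summary_mentions_configuration(self):
        ts = pattern_data(separated_means(k=3, u=10), noise=0.1)
        cfg = DecodeConfig(train_window_s=1.0, train_stride=20,
                           n_permutations=10, seed=0)
        res = SlidingDecoder(ts, cfg).fit()
        s = res.summary()
        assert "ν=0.9" in s and "permutation" in s


class TestPermutationNull:
    def test_chance_mean_near_one_over_k(self):
        """Balanced k-class problem: permuted-label success ≈ 1/k."""
        ts = pattern_data(separated_means(k=4, u=20), noise=0.05)
        cfg = DecodeConfig(train_window_s=1.0, n_permutations=150, seed=2)
        mean_c, upper, perm = permutation_chance(ts, cfg,
                                                 train_frames=np.array([5]))
        assert mean_c[0] == pytest.approx(0.25, abs=0.08)
        assert upper[0] >= mean_c[0]

    def test_single_permutation_degenerate_percentile(self):
        ts = pattern_data(separated_means(k=3, u=10), noise=0.1)
        cfg = DecodeConfig(train_window_s=1.0, n_permutations=1, seed=7)
        mean_c, upper, perm = permutation_chance(ts, cfg,
                                                 train_frames=np.array([5]))
        assert upper[0] == mean_c[0] == perm[0, 0]

    def test_matches_exhaustive_enumeration(self):
        """3 trials × 2 classes, resubstitution: the sampled permutation
        distribution matches exhaustive enumeration of all 20 relabelings."""
        rng = np.random.default_rng(11)
        data = rng.normal(0, 1, (8, 20, 6)) + np.linspace(0, 1, 6)
        ts = make_traceset(data, stim_onset_frame=3, stim_duration_s=1.0,
                           odors=["p", "p", "p", "q", "q", "q"],
                           trials=[1, 2, 3, 1, 2, 3])
        cfg = DecodeConfig(train_window_s=0.4, cv="resubstitution",
                           n_permutations=600, seed=13, eval_window=(3, 8))

        # oracle: run the identical decoder on every distinct relabeling
        values = []
        base = ["p", "p", "p", "q", "q", "q"]
        seen = set()
        for perm in itertools.permutations(range(6)):
            labels = tuple(base[i] for i in perm)
            if labels in seen:
                continue
            seen.add(labels)
            ts_perm = make_traceset(data, stim_onset_frame=3,
                                    stim_duration_s=1.0, odors=list(labels),
                                    trials=[1, 2, 3, 1, 2, 3])
            res = SlidingDecoder(ts_perm, cfg).fit(
                compute_chance=False, train_frames=np.array([3]))
            values.append(res.stim_avg[0])
        assert len(values) == 20

        _, _, perm_mat = permutation_chance(ts, cfg,
                                            train_frames=np.array([3]))
        sampled = perm_mat[:, 0]
        # support: every sampled value is one of the enumerated outcomes
        assert np.isin(np.round(sampled, 9), np.round(values, 9)).all()
        # uniform-over-arrangements mean within Monte-Carlo error
        assert sampled.mean() == pytest.approx(np.mean(values), abs=0.06)


def test_sliding_decode_wrapper_equivalent():
    ts = pattern_data(separated_means(k=3, u=10), noise=0.1)
    cfg = DecodeConfig(train_window_s=1.0, train_stride=15, n_permutations=3,
                       seed=0)
    a = sliding_decode(ts, cfg)
    b = SlidingDecoder(ts, cfg).fit(compute_chance=False)
    np.testing.assert_allclose(a.success, b.success)
    assert a.chance_upper is None
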