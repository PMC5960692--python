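"""Time-resolved population-pattern correlation and the animal bootstrap."""

import itertools

import numpy as np
import pytest
from scipy import stats

from odortrace import (SynthConfig, bootstrap_corr, compute_dff, corr_matrix,
                       corr_trace, generate_traceset, pairwise_window_corr,
                       pattern_at)
from odortrace.patterncorr import PatternCorrelation

from conftest import make_traceset


def two_trials(data1, data2, animals=None, **kw):
    data = np.stack([data1, data2], axis=-1)
    return make_traceset(data, odors=["A", "A"], trials=[1, 2],
                         animals=animals, **kw)


@pytest.fixture
def rand_pair():
    rng = np.random.default_rng(2)
    a = rng.normal(0, 1, (12, 60))
    b = rng.normal(0, 1, (12, 60))
    ts = two_trials(a, b, stim_onset_frame=10, stim_duration_s=4.0)
    return ts.select_stimulus("A", 1), ts.select_stimulus("A", 2), a, b


class TestPatternAt:
    def test_single_frame_window_is_population_slice(self, rand_pair):
        ts_a, _, a, _ = rand_pair
        vec = pattern_at(ts_a, (7, 8))
        np.testing.assert_array_equal(vec.values, a[:, 7])

    def test_named_odor_window_is_five_frames(self):
        """t = 1–2 s at 5 Hz covers exactly 5 frames."""
        rng = np.random.default_rng(0)
        data = rng.random((4, 175))
        ts = two_trials(data, data).select_stimulus("A", 1)
        lo, hi = ts.window_frames(1.0, 2.0)
        assert hi - lo == 5
        vec = pattern_at(ts, (lo, hi))
        np.testing.assert_allclose(vec.values, data[:, 30:35].mean(axis=1))

    def test_matches_brute_force_means(self, rand_pair):
        ts_a, _, a, _ = rand_pair
        vec = pattern_at(ts_a, (5, 20))
        expected = [np.mean([a[u, f] for f in range(5, 20)]) for u in range(12)]
        np.testing.assert_allclose(vec.values, expected)

    def test_empty_window_rejected(self, rand_pair):
        with pytest.raises(ValueError, match="window"):
            pattern_at(rand_pair[0], (10, 10))


class TestCorrMatrix:
    def test_self_correlation_unit_diagonal_symmetric(self, rand_pair):
        ts_a = rand_pair[0]
        m = corr_matrix(ts_a, ts_a)
        np.testing.assert_allclose(np.diag(m.r), 1.0)
        np.testing.assert_allclose(m.r, m.r.T, atol=1e-12)

    def test_perfect_anticorrelation(self):
        a = np.tile([[1.0], [2.0], [3.0]], (1, 5))
        b = np.tile([[3.0], [2.0], [1.0]], (1, 5))
        ts = two_trials(a, b, stim_onset_frame=1, stim_duration_s=0.2)
        m = corr_matrix(ts.select_stimulus("A", 1), ts.select_stimulus("A", 2))
        np.testing.assert_allclose(m.r, -1.0)

    def test_p_values_match_t_cdf_oracle(self, rand_pair):
        """Two-sided p from the t transform, df = n_units − 2, to 1e-10."""
        ts_a, ts_b, a, b = rand_pair
        m = corr_matrix(ts_a, ts_b)
        n = 12
        for i, j in itertools.product(range(0, 60, 13), range(0, 60, 17)):
            r = np.corrcoef(a[:, i], b[:, j])[0, 1]
            t = r * np.sqrt((n - 2) / (1 - r**2))
            p = 2 * stats.t.sf(abs(t), n - 2)
            assert m.r[i, j] == pytest.approx(r, abs=1e-12)
            assert m.p[i, j] == pytest.approx(p, abs=1e-10)
        np.testing.assert_array_equal(m.mask, m.p < 0.005)

    def test_matches_scipy_pearsonr(self, rand_pair):
        ts_a, ts_b, a, b = rand_pair
        m = corr_matrix(ts_a, ts_b)
        r, p = stats.pearsonr(a[:, 3], b[:, 44])
        assert m.r[3, 44] == pytest.approx(r, abs=1e-12)
        assert m.p[3, 44] == pytest.approx(p, abs=1e-10)

    def test_zero_variance_pattern_masked(self):
        a = np.random.default_rng(0).normal(size=(5, 10))
        b = a.copy()
        a[:, 4] = 7.0                     # flat pattern at frame 4
        ts = two_trials(a, b, stim_onset_frame=1, stim_duration_s=0.2)
        m = corr_matrix(ts.select_stimulus("A", 1), ts.select_stimulus("A", 2))
        assert np.isnan(m.r[4, :]).all()
        assert not m.mask[4, :].any()

    def test_affine_rescaling_invariance(self, rand_pair):
        """Pearson r is unchanged by per-time-point affine maps."""
        ts_a, ts_b, a, b = rand_pair
        scaled = two_trials(3.0 * a + 2.0, -0.5 * b + 1.0,
                            stim_onset_frame=10, stim_duration_s=4.0)
        m1 = corr_matrix(ts_a, ts_b)
        m2 = corr_matrix(scaled.select_stimulus("A", 1),
                         scaled.select_stimulus("A", 2))
        np.testing.assert_allclose(np.abs(m2.r), np.abs(m1.r), atol=1e-10)

    def test_mismatched_units_rejected(self, rand_pair):
        ts_a = rand_pair[0]
        other = ts_a.select_units([0, 1, 2])
        with pytest.raises(ValueError, match="unit sets"):
            corr_matrix(ts_a, other)


class TestCorrTrace:
    def test_single_frame_reference_is_matrix_row(self, rand_pair):
        m = corr_matrix(rand_pair[0], rand_pair[1])
        tr = corr_trace(m, (8, 9))
        np.testing.assert_array_equal(tr.values, m.r[8, :])

    def test_constant_matrix_gives_constant_trace(self, rand_pair):
        m = corr_matrix(rand_pair[0], rand_pair[1])
        m.r[:] = 0.5
        np.testing.assert_allclose(corr_trace(m, (0, 10)).values, 0.5)

    def test_matches_row_mean_oracle(self, rand_pair):
        m = corr_matrix(rand_pair[0], rand_pair[1])
        tr = corr_trace(m, (5, 15))
        np.testing.assert_allclose(tr.values, m.r[5:15].mean(axis=0))


class TestBootstrap:
    def test_single_animal_has_zero_sd(self, rand_pair):
        ts_a, ts_b, *_ = rand_pair
        tr = bootstrap_corr(ts_a, ts_b, (5, 10), n_boot=50, seed=0)
        np.testing.assert_allclose(tr.boot_sd, 0.0, atol=1e-12)
        np.testing.assert_allclose(tr.boot_mean, tr.values, atol=1e-12)

    def test_two_animals_match_enumeration_oracle(self):
        """With 2 animals the bootstrap draws {AA, AB, BA, BB} equiprobably;
        the SD over replicates matches the closed-form enumeration."""
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, (8, 20))
        b = rng.normal(0, 1, (8, 20))
        animals = ["fA"] * 4 + ["fB"] * 4
        ts = two_trials(a, b, animals=animals, stim_onset_frame=5,
                        stim_duration_s=1.0)
        ts_a, ts_b = ts.select_stimulus("A", 1), ts.select_stimulus("A", 2)
        ref = (2, 4)

        # oracle: brute-force corr traces of the four equiprobable pools
        def pooled_trace(rows):
            va, vb = a[rows], b[rows]
            out = np.empty(20)
            for j in range(20):
                out[j] = np.mean([np.corrcoef(va[:, i], vb[:, j])[0, 1]
                                  for i in range(*ref)])
            return out

        idx = {"fA": list(range(4)), "fB": list(range(4, 8))}
        combos = [pooled_trace(idx[x] + idx[y])
                  for x, y in itertools.product("AB", "AB")
                  for x, y in [("f" + x, "f" + y)]]
        combos = np.array(combos)
        oracle_sd = combos.std(axis=0, ddof=0)          # 4 equiprobable draws

        tr = bootstrap_corr(ts_a, ts_b, ref, n_boot=3000, seed=12)
        np.testing.assert_allclose(tr.boot_sd, oracle_sd, atol=0.05)
        support = np.round(combos[:, 7], 9)
        assert np.round(tr.boot_mean[7], 2) == pytest.approx(
            combos[:, 7].mean(), abs=0.05)
        assert len(np.unique(support)) <= 4

    def test_two_seeds_agree_within_monte_carlo_error(self):
        cfg = SynthConfig(n_animals=3, units_per_animal=10, seed=5)
        dff = compute_dff(generate_traceset(cfg)[0])
        ts_a = dff.select_stimulus("ButL", 1)
        ts_b = dff.select_stimulus("ButL", 2)
        ref = dff.window_frames(1.0, 2.0)
        t1 = bootstrap_corr(ts_a, ts_b, ref, n_boot=400, seed=1)
        t2 = bootstrap_corr(ts_a, ts_b, ref, n_boot=400, seed=2)
        scale = np.median(t1.boot_sd) + 1e-6
        assert np.median(np.abs(t1.boot_sd - t2.boot_sd)) < 0.10 * scale + 0.01


class TestPairwiseTables:
    def test_identical_trials_correlate_perfectly(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, (20, 175))
        ts = two_trials(base, base)
        tabs = pairwise_window_corr(ts)
        assert tabs["odor_vs_odor"].loc[("A", 1), ("A", 2)] == pytest.approx(1.0)
        assert tabs["post_vs_post"].loc[("A", 1), ("A", 2)] == pytest.approx(1.0)

    @pytest.mark.parametrize("rho,bound", [(0.0, None), (0.8, 0.1)])
    def test_diagonal_tracks_configured_rho(self, rho, bound):
        """odor-vs-post diagonal ≈ configured ρ (null bound 2/√n at ρ=0)."""
        cfg = SynthConfig(n_animals=4, units_per_animal=50, seed=19,
                          noise_sd=0.01, bleach_a=0.0, bleach_c=1.0,
                          post_pattern_corr=rho)
        dff = compute_dff(generate_traceset(cfg)[0])
        tabs = pairwise_window_corr(dff)
        diag = np.diag(tabs["odor_vs_post"])
        keys = list(tabs["odor_vs_post"].index)
        for k, v in zip(keys, diag):
            if k[0] == cfg.solvent:
                continue
            if bound is None:
                assert abs(v) < 2 / np.sqrt(200)
            else:
                assert v == pytest.approx(rho, abs=bound)

    def test_single_presentation_rejected(self):
        ts = make_traceset(np.zeros((4, 175, 1)), odors=["A"], trials=[1])
        with pytest.raises(ValueError, match="at least two"):
            pairwise_window_corr(ts)


def test_compartment_contrast_in_odor_post_similarity():
    """KC-somata-like populations keep an odor ↔ post-odor correlation that
    ORN-like populations lack."""
    from odortrace import preset

    def mean_diag(name):
        cfg = preset(name, n_animals=3, units_per_animal=40, seed=23)
        dff = compute_dff(generate_traceset(cfg)[0])
        res = PatternCorrelation(dff).fit(n_boot=0)
        d = res.odor_post_diagonal()
        return np.mean([v for (o, t), v in d.items() if o != cfg.solvent])

    kc, orn = mean_diag("kc_soma_like"), mean_diag("orn_like")
    assert kc > 0.4
    assert abs(orn) < 0.2
    assert kc > orn + 0.3
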