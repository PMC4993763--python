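import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dyadsync import (
    CrossCorrelation,
    DyadEnergy,
    DyadSimParams,
    EntrainmentProfile,
    center_of_mass,
    cross_correlation,
    dominance_bouts,
    dominance_ratio,
    gen_energy_dyad,
    synchrony_score,
    windowed_entrainment,
)
from dyadsync.errors import DegenerateInputError, DomainError, UndefinedRatioError


def brute_force_cc(e_s, e_a, max_lag):
    """Independent double-loop oracle for the Pearson-normalized c(tau)."""
    e_s = np.asarray(e_s, float)
    e_a = np.asarray(e_a, float)
    n = len(e_s)
    xs, xa = e_s - e_s.mean(), e_a - e_a.mean()
    out = []
    for tau in range(-max_lag, max_lag + 1):
        total = 0.0
        for i in range(n):
            j = i + tau
            if 0 <= j < n:
                total += xs[j] * xa[i]
        out.append(total / ((n - abs(tau)) * e_s.std() * e_a.std()))
    return np.array(out)


class TestCrossCorrelation:
    def test_matches_double_loop_oracle(self, rng):
        for _ in range(5):
            n = int(rng.integers(20, 200))
            e_s, e_a = rng.random(n), rng.random(n)
            lag = int(rng.integers(1, n // 3))
            cc = cross_correlation(e_s, e_a, lag)
            np.testing.assert_allclose(cc.values, brute_force_cc(e_s, e_a, lag),
                                       atol=1e-9)

    def test_identical_series_have_unit_synchrony(self, rng):
        e = rng.random(100)
        cc = cross_correlation(e, e, 10)
        assert synchrony_score(cc) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        cc = cross_correlation([4, 3, 2, 1], [1, 2, 3, 4], 0)
        assert cc.at_lag(0) == pytest.approx(-1.0)

    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_lagged_copy_peaks_at_positive_lag(self, rng, k):
        # subject repeats the actor k frames later -> argmax at +k
        base = rng.random(300)
        e_s, e_a = base[:-k], base[k:]  # e_s(n) = e_a(n - k)
        cc = cross_correlation(e_s, e_a, 20)
        assert cc.lags[np.argmax(cc.values)] == k

    @given(seed=st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=25)
    def test_swap_antisymmetry(self, seed):
        r = np.random.default_rng(seed)
        e_s, e_a = r.random(60), r.random(60)
        ab = cross_correlation(e_s, e_a, 15).values
        ba = cross_correlation(e_a, e_s, 15).values
        np.testing.assert_allclose(ab, ba[::-1], atol=1e-12)

    def test_zero_lag_is_pearson(self, rng):
        e_s, e_a = rng.random(80), rng.random(80)
        cc = cross_correlation(e_s, e_a, 5)
        assert cc.at_lag(0) == pytest.approx(np.corrcoef(e_s, e_a)[0, 1])
        assert abs(cc.at_lag(0)) <= 1.0

    def test_degenerate_and_domain_errors(self, rng):
        with pytest.raises(DegenerateInputError):
            cross_correlation(np.ones(50), rng.random(50), 5)
        with pytest.raises(DomainError):
            cross_correlation(rng.random(50), rng.random(50), 25)

    def test_raw_normalization_matches_printed_formula(self, rng):
        e_s, e_a = rng.random(40), rng.random(40)
        cc = cross_correlation(e_s, e_a, 6, normalization="raw")
        tau = 4
        expected = sum(e_s[n + tau] * e_a[n] for n in range(40 - tau))
        expected /= e_s.std() * e_a.std()
        assert cc.at_lag(tau) == pytest.approx(expected)


class TestCenterOfMass:
    def _cc(self, lags, values, fps=1.0):
        return CrossCorrelation(np.asarray(lags), np.asarray(values, float), fps)

    def test_symmetric_function_is_balanced(self):
        lags = np.arange(-10, 11)
        cc = self._cc(lags, np.exp(-0.1 * lags ** 2))
        assert center_of_mass(cc) == pytest.approx(0.0, abs=1e-12)

    def test_single_spike_is_point_mass(self):
        lags = np.arange(-10, 11)
        vals = np.zeros(21)
        vals[lags == 2] = 0.7
        cc = self._cc(lags, vals)  # fps 1 -> lag 2 frames = 2 s
        assert center_of_mass(cc) == pytest.approx(2.0)

    def test_hand_summation_oracle_clip_mode(self):
        lags = np.arange(-2, 3)
        vals = np.array([0.1, -0.2, 0.4, 0.3, -0.1])
        cc = self._cc(lags, vals, fps=2.0)
        w = np.clip(vals, 0, None)
        expected = (lags / 2.0 * w).sum() / w.sum()
        assert center_of_mass(cc, weights="clip") == pytest.approx(expected)

    def test_lag_range_restriction(self):
        lags = np.arange(-10, 11)
        vals = np.zeros(21)
        vals[lags == 8] = 1.0
        vals[lags == 1] = 0.5
        cc = self._cc(lags, vals)
        assert center_of_mass(cc, T=5) == pytest.approx(1.0)

    def test_all_zero_weights_degenerate(self):
        lags = np.arange(-3, 4)
        cc = self._cc(lags, np.zeros(7))
        with pytest.raises(DegenerateInputError):
            center_of_mass(cc)

    def test_noise_floor_threshold_recovers_true_lag(self, one_way_dyad):
        de, gt = one_way_dyad
        cc = cross_correlation(de.subject, de.actor, int(15 * de.fps), fps=de.fps)
        assert cc.peak_lag_seconds == pytest.approx(gt["lag_sa"], abs=0.2)
        y = center_of_mass(cc, T=15.0)
        assert abs(y - gt["lag_sa"]) <= 0.5


class TestWindowedEntrainment:
    def test_stationary_coupling_keeps_sign(self, one_way_dyad):
        de, gt = one_way_dyad
        prof = windowed_entrainment(de)
        valid = prof.com_values[~np.isnan(prof.com_values)]
        assert (valid > 0).mean() > 0.8  # actor leads almost everywhere

    def test_direction_flip_flips_sign(self):
        a, _ = gen_energy_dyad(DyadSimParams(duration=80, coupling_sa=0.9,
                                             lag_sa=1.5, noise_sd=0.1, seed=3))
        b, _ = gen_energy_dyad(DyadSimParams(duration=80, coupling_as=0.9,
                                             lag_as=1.5, noise_sd=0.1, seed=4))
        de = DyadEnergy(np.concatenate([a.subject, b.subject]),
                        np.concatenate([a.actor, b.actor]), a.fps)
        prof = windowed_entrainment(de)
        first = prof.com_values[prof.window_centers < 60]
        second = prof.com_values[prof.window_centers > 100]
        assert np.nanmean(first) > 0.5
        assert np.nanmean(second) < -0.5

    def test_constant_window_yields_nan_only_there(self):
        r = np.random.default_rng(0)
        fps = 10.0
        n = int(60 * fps)
        e_s, e_a = 1 + r.random(n), 1 + r.random(n)
        e_s[:int(20 * fps)] = 1.0  # first 20 s constant
        de = DyadEnergy(e_s, e_a, fps)
        prof = windowed_entrainment(de, window_len=20, hop=5, max_lag=5)
        assert np.isnan(prof.com_values[0])
        assert not np.isnan(prof.com_values[-1])

    def test_short_recording_rejected(self, rng):
        de = DyadEnergy(rng.random(50), rng.random(50), fps=10)
        with pytest.raises(DomainError):
            windowed_entrainment(de, window_len=20)
        with pytest.raises(DomainError):
            windowed_entrainment(de, window_len=4, max_lag=3)


def rle_oracle(signs, hop):
    """Independent run-length-encoding of +1/-1/0 sign sequences."""
    runs, cur, length = [], 0, 0
    for s in list(signs) + [99]:
        if s == cur:
            length += 1
        else:
            if cur in (1, -1) and length:
                runs.append((cur, length * hop))
            cur, length = s, 1
    return ([d for s, d in runs if s == -1], [d for s, d in runs if s == 1])


class TestDominance:
    def _profile(self, com, hop=1.0):
        centers = np.arange(len(com), dtype=float)
        return EntrainmentProfile(centers, np.asarray(com, float),
                                  window_len=20.0, hop=hop)

    def test_run_length_arithmetic(self):
        bouts = dominance_bouts(self._profile([+1, +1, +1, -1, -1]))
        assert bouts.actor_bouts == [3.0]
        assert bouts.subject_bouts == [2.0]

    def test_all_positive_has_no_subject_bouts(self):
        bouts = dominance_bouts(self._profile([0.2, 0.4, 0.1]))
        assert bouts.subject_bouts == []
        with pytest.raises(UndefinedRatioError):
            dominance_ratio(bouts)

    def test_nan_breaks_runs(self):
        bouts = dominance_bouts(self._profile([1, 1, np.nan, 1, -1]))
        assert bouts.actor_bouts == [2.0, 1.0]
        assert bouts.subject_bouts == [1.0]

    @pytest.mark.parametrize("seed", range(5))
    def test_random_signs_match_rle_oracle(self, seed):
        r = np.random.default_rng(seed)
        signs = r.choice([-1.0, 0.0, 1.0], size=40)
        bouts = dominance_bouts(self._profile(signs, hop=0.5))
        sub, act = rle_oracle(np.sign(signs), 0.5)
        assert bouts.subject_bouts == sub
        assert bouts.actor_bouts == act

    def test_ratio_of_means(self):
        from dyadsync import DominanceBouts
        assert dominance_ratio(DominanceBouts([10.0, 20.0], [10.0, 10.0])) == 1.5
        assert dominance_ratio(DominanceBouts([5.0, 7.0], [7.0, 5.0])) == 1.0
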