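"""Onset rule, phase angle, and chi-square periodogram."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from chronophase import (
    LD12_12,
    chi_square_periodogram,
    daily_profile,
    detect_onsets,
    estimate_period,
    ld_then_dd,
    phase_angle,
    simulate_activity,
)

from conftest import make_series


def onset_rule_oracle(counts, bpd, anchor_bins, thr_frac=0.30, need=3, win=6):
    """Literal transcription of the 30%-of-peak onset rule (per-day scan)."""
    found = []
    start = anchor_bins
    while start + bpd <= len(counts):
        w = list(counts[start : start + bpd])
        peak = max(w)
        hit = None
        if peak > 0:
            thr = thr_frac * peak
            ext = list(counts[start : min(len(counts), start + bpd + win)])
            for i in range(bpd):
                if ext[i] >= thr:
                    confirm = sum(1 for v in ext[i + 1 : i + 1 + win] if v >= thr)
                    if confirm >= need:
                        hit = start + i
                        break
        found.append(hit)
        start += bpd
    return found


class TestDailyProfile:
    def test_identical_days_give_the_day(self):
        day = np.arange(96)
        s = make_series(np.tile(day, 5))
        assert np.array_equal(daily_profile(s, 5), day)

    def test_zero_and_two_average_to_one(self):
        s = make_series(np.concatenate([np.zeros(96), np.full(96, 2)]))
        assert np.array_equal(daily_profile(s, 2), np.ones(96))

    def test_matches_bruteforce_mean(self, rng):
        counts = rng.poisson(5, size=5 * 96)
        s = make_series(counts)
        expect = np.array([counts[b::96][:5].mean() for b in range(96)])
        assert daily_profile(s, 5) == pytest.approx(expect)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            daily_profile(make_series(np.ones(96)), 2)


class TestOnsetDetection:
    def test_worked_example_window(self):
        # Peak 100; first bin >= 30 is the 35 at offset 1; four of the
        # next six bins {20,40,40,35,5,90} reach threshold -> onset there.
        counts = np.zeros(2 * 96)
        pattern = [10, 35, 20, 40, 40, 35, 5, 90, 100]
        anchor = 24  # ZT6 at 15-min bins
        counts[anchor : anchor + len(pattern)] = pattern
        onsets = detect_onsets(make_series(counts))
        assert onsets[0].valid
        assert onsets[0].qualifying_bin_index == anchor + 1
        assert onsets[0].onset_zt == pytest.approx(6.25)

    def test_threshold_is_relative_to_peak(self):
        counts = np.zeros(2 * 96)
        pattern = [10, 35, 20, 40, 40, 35, 5, 90, 100]
        counts[24 : 24 + len(pattern)] = pattern
        a = detect_onsets(make_series(counts))
        b = detect_onsets(make_series(counts * 7))
        assert a[0].qualifying_bin_index == b[0].qualifying_bin_index

    def test_all_zero_window_is_invalid(self):
        onsets = detect_onsets(make_series(np.zeros(2 * 96)))
        assert not onsets[0].valid
        assert onsets[0].onset_zt is None

    def test_silent_leading_days_do_not_shift_onset_zt(self, cry1):
        s = simulate_activity(cry1, LD12_12, 4, 15, seed=3, modality="locomotor")
        padded = make_series(np.concatenate([np.zeros(96), s.counts]))
        d1 = detect_onsets(s)
        d2 = detect_onsets(padded)
        # padded window i (i >= 1) covers exactly the original window i-1
        assert [o.onset_zt for o in d2[1:]] == [o.onset_zt for o in d1[: len(d2) - 1]]

    def test_matches_rule_oracle_on_random_windows(self, rng):
        """1000 random 2-day series agree with the literal rule transcription."""
        bpd = 96
        for _ in range(1000):
            counts = rng.integers(0, 40, size=2 * bpd)
            s = make_series(counts)
            got = [o.qualifying_bin_index for o in detect_onsets(s)]
            expect = onset_rule_oracle(counts, bpd, anchor_bins=24)
            assert got == expect


class TestPhaseAngle:
    def _onsets_at(self, zts):
        from chronophase import OnsetEstimate

        return [OnsetEstimate(i, z, 0, z is not None) for i, z in enumerate(zts)]

    def test_onset_at_dark_onset_gives_zero(self):
        r = phase_angle(self._onsets_at([12.0, 12.0, 12.0]), LD12_12)
        assert r.mean_min == 0.0

    def test_sign_convention_onset_before_dark_is_positive(self):
        r = phase_angle(self._onsets_at([11.5, 11.5, 11.5]), LD12_12)
        assert r.mean_min == pytest.approx(30.0)

    def test_invalid_days_excluded_and_minimum_enforced(self):
        r = phase_angle(self._onsets_at([11.5, None, 12.0, 12.5, None]), LD12_12)
        assert r.n_valid_days == 3
        assert r.mean_min == pytest.approx((30 + 0 - 30) / 3)
        with pytest.raises(ValueError):
            phase_angle(self._onsets_at([12.0, None, None]), LD12_12)

    def test_dd_schedule_rejected(self):
        from chronophase import DD

        with pytest.raises(ValueError):
            phase_angle(self._onsets_at([12.0] * 3), DD)

    def test_equivariance_bout_shift_moves_phase_oppositely(self, wt):
        """Shifting the simulated bout +delta min shifts the angle -delta."""
        delta = 60.0  # minutes, resolvable at 15-min bins
        shifted = dataclasses.replace(
            wt, onset_shift_min={"wheel": 0.0, "locomotor": -delta}
        )
        base = simulate_activity(wt, LD12_12, 6, 15, seed=5, modality="locomotor")
        late = simulate_activity(shifted, LD12_12, 6, 15, seed=5, modality="locomotor")
        a0 = phase_angle(detect_onsets(base), LD12_12).mean_min
        a1 = phase_angle(detect_onsets(late), LD12_12).mean_min
        assert a1 - a0 == pytest.approx(-delta, abs=15.0)


def qp_oracle(x, p):
    """Direct fold-and-average computation of Q_P."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    cols = [[x[i] for i in range(n) if i % p == h] for h in range(p)]
    grand = x.mean()
    num = sum(len(c) * (np.mean(c) - grand) ** 2 for c in cols)
    return n * num / np.sum((x - grand) ** 2)


class TestPeriodogram:
    def test_qp_matches_fold_oracle_on_toy_series(self):
        x = np.array([3, 1, 4, 1, 5, 9, 2, 6, 5, 3, 5, 8])
        s = make_series(x, bin_width_min=60, schedule=ld_then_dd(0))
        # grid covering P=3 bins: 3 h at 60-min bins
        res = chi_square_periodogram(s, p_min_h=3, p_max_h=6, alpha=0.05)
        j = int(np.flatnonzero(np.isclose(res.periods_h, 3.0))[0])
        assert res.qp[j] == pytest.approx(qp_oracle(x, 3))
        assert res.df[j] == 2
        assert res.threshold[j] == pytest.approx(stats.chi2.ppf(0.95, 2))

    def test_qp_affine_invariance(self, rng):
        x = rng.poisson(10, size=240).astype(float)
        s1 = make_series(x, bin_width_min=60, schedule=ld_then_dd(0))
        s2 = make_series(3.5 * x + 11, bin_width_min=60, schedule=ld_then_dd(0))
        r1 = chi_square_periodogram(s1, p_min_h=20, p_max_h=28)
        r2 = chi_square_periodogram(s2, p_min_h=20, p_max_h=28)
        assert r1.qp == pytest.approx(r2.qp)

    def test_noiseless_square_wave_recovers_24h(self, wt):
        noiseless = dataclasses.replace(
            wt,
            tau_h=24.0,
            baseline_rate={k: 0.0 for k in wt.baseline_rate},
        )
        bpd = 720
        from chronophase import expected_activity

        mu = expected_activity(noiseless, ld_then_dd(0), 12, 2)
        s = make_series(np.round(mu).astype(int), bin_width_min=2, schedule=ld_then_dd(0))
        res = chi_square_periodogram(s)
        assert res.significant
        assert res.tau_hat_h == pytest.approx(24.0)
        # global maximum of Q_P sits at the true period
        assert res.periods_h[np.argmax(res.qp)] == pytest.approx(24.0)

    def test_constant_series_raises(self):
        s = make_series(np.full(2000, 5), bin_width_min=60, schedule=ld_then_dd(0))
        with pytest.raises(ValueError):
            chi_square_periodogram(s)

    def test_short_series_raises(self):
        s = make_series(np.arange(40), bin_width_min=60, schedule=ld_then_dd(0))
        with pytest.raises(ValueError):
            chi_square_periodogram(s)


class TestEstimatePeriod:
    def test_skip_zero_equals_whole_series_periodogram(self, wt):
        s = simulate_activity(wt, ld_then_dd(0), 12, 2, seed=8)
        full = chi_square_periodogram(s)
        crop = estimate_period(s, skip_days=0, use_days=12)
        assert crop.tau_hat_h == full.tau_hat_h
        assert crop.qp == pytest.approx(full.qp)

    def test_insufficient_days_raises(self, wt):
        s = simulate_activity(wt, ld_then_dd(0), 5, 2, seed=8)
        with pytest.raises(ValueError):
            estimate_period(s, skip_days=1, use_days=12)

    def test_period_recovery_within_bin_resolution(self, wt):
        """Mean tau over 10 seeds within 0.1 h of the true 23.77 h."""
        taus = []
        for seed in range(10):
            s = simulate_activity(wt, ld_then_dd(0), 13, 2, seed=seed)
            taus.append(estimate_period(s).tau_hat_h)
        assert abs(np.mean(taus) - wt.tau_h) < 0.1
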