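"""Three-step prey-encounter detector: filter, smooth, cluster, merge."""
import numpy as np
import pandas as pd
import pytest

from foragemetrics.pee import (_binned_sd, _merge_events, count_pee,
                               detect_pee, highpass_butterworth,
                               smoothed_dynamic_sd, two_means_high_state)
from foragemetrics.types import AccelSeries, DepthSeries, Dive, PeeEvent


class TestHighpass:
    def test_dc_removed(self):
        out = highpass_butterworth(np.full(2000, 9.81), fs=16.0)
        assert np.max(np.abs(out)) < 1e-6

    def test_stopband_sine_attenuated(self):
        # 0.05 Hz is deep in the stopband of a 0.33 Hz order-3 filter
        t = np.arange(0, 400, 1 / 16)
        out = highpass_butterworth(np.sin(2 * np.pi * 0.05 * t), fs=16.0)
        mid = out[len(out) // 4: -len(out) // 4]
        assert np.max(np.abs(mid)) < 0.01

    def test_passband_sine_preserved(self):
        t = np.arange(0, 400, 1 / 16)
        out = highpass_butterworth(np.sin(2 * np.pi * 4.0 * t), fs=16.0)
        mid = out[len(out) // 4: -len(out) // 4]
        assert np.max(np.abs(mid)) == pytest.approx(1.0, rel=0.05)

    def test_short_signal_raises(self):
        with pytest.raises(ValueError):
            highpass_butterworth(np.zeros(5), fs=16.0)

    def test_cutoff_above_nyquist_raises(self):
        with pytest.raises(ValueError):
            highpass_butterworth(np.zeros(100), fs=16.0, cutoff=9.0)


class TestSmoothedSd:
    def _series(self, ax, fs=16.0):
        return AccelSeries(0.0, fs, ax, ax.copy(), ax.copy())

    def test_zero_signal_all_zero(self):
        sd3 = smoothed_dynamic_sd(self._series(np.zeros(16 * 30)))
        assert np.allclose(sd3[["sd_x", "sd_y", "sd_z"]].to_numpy(), 0.0)

    def test_constant_per_second_sd_gives_zero_running_sd(self):
        # identical 16-sample pattern each second -> per-second SDs all
        # equal -> the running SD of a constant is zero
        pattern = np.array([1.0, -1.0] * 8)
        x = np.tile(pattern, 40)
        sds = _binned_sd(x, 16.0)
        assert np.allclose(sds, sds[0])
        from foragemetrics.pee import _running_sd
        assert np.allclose(_running_sd(sds), 0.0)

    def test_iid_noise_per_second_sd_near_sigma(self):
        rng = np.random.default_rng(1)
        sigma = 0.7
        sds = _binned_sd(rng.normal(0, sigma, 16 * 3000), 16.0)
        assert sds.mean() == pytest.approx(sigma, rel=0.03)

    def test_fractional_rate_binning(self):
        rng = np.random.default_rng(2)
        sds = _binned_sd(rng.normal(0, 1.0, 2500), 12.5)
        assert sds.size == 200
        assert sds.mean() == pytest.approx(1.0, rel=0.05)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            smoothed_dynamic_sd(self._series(np.zeros(32)))


class TestTwoMeans:
    def test_two_level_exact(self):
        high, (lo, hi) = two_means_high_state(np.array([0, 0, 0, 10, 10.0]))
        assert list(high) == [False, False, False, True, True]
        assert (lo, hi) == (0.0, 10.0)

    def test_degenerate_all_equal(self):
        high, _ = two_means_high_state(np.full(50, 3.3))
        assert not high.any()

    def test_separated_gaussians_recovered_exactly(self):
        rng = np.random.default_rng(3)
        lab = rng.integers(0, 2, 500).astype(bool)
        v = np.where(lab, rng.normal(8, 0.1, 500), rng.normal(1, 0.1, 500))
        high, _ = two_means_high_state(v)
        assert np.array_equal(high, lab)

    def test_matches_brute_force_partition(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            v = rng.uniform(0, 5, rng.integers(3, 15))
            high, _ = two_means_high_state(v, eps=0.0)
            s = np.sort(v)
            best_ss, best_j = np.inf, 0
            for j in range(1, v.size):
                ss = s[:j].var() * j + s[j:].var() * (v.size - j)
                if ss < best_ss - 1e-12:
                    best_ss, best_j = ss, j
            assert high.sum() == v.size - best_j

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        v = np.concatenate([rng.normal(1, 0.2, 80), rng.normal(6, 0.4, 20)])
        h1, _ = two_means_high_state(v)
        h2, _ = two_means_high_state(v * 37.5)
        assert np.array_equal(h1, h2)


def _sd3(high_x, high_y, high_z, n=30):
    """Synthetic smoothed-SD frame with given high-second index sets."""
    def col(idx):
        v = np.full(n, 0.1)
        v[list(idx)] = 5.0
        return v
    return pd.DataFrame({"t": np.arange(n, dtype=float),
                         "sd_x": col(high_x), "sd_y": col(high_y),
                         "sd_z": col(high_z)})


class TestDetectPee:
    def test_triple_intersection(self):
        ev = detect_pee(_sd3(range(2, 11), range(3, 9), range(0, 21)))
        assert len(ev) == 1
        assert ev[0].start == 3.0 and ev[0].end == 9.0

    def test_one_axis_never_high_means_no_events(self):
        ev = detect_pee(_sd3(range(2, 11), range(3, 9), []))
        assert ev == []

    def test_close_runs_merge(self):
        # sub-second gaps are merged; the 1 Hz grid keeps >= 1 s gaps apart
        assert _merge_events([(0.0, 2.0), (2.5, 4.0)]) == [(0.0, 4.0)]
        assert _merge_events([(0.0, 2.0), (3.0, 4.0)]) == [(0.0, 2.0),
                                                           (3.0, 4.0)]

    def test_merge_idempotent(self):
        merged = _merge_events([(0, 1.5), (1.9, 3.0), (5.0, 6.0)])
        assert _merge_events(merged) == merged

    def test_flat_signal_yields_no_events(self):
        n = 30
        flat = pd.DataFrame({"t": np.arange(n, dtype=float),
                             "sd_x": np.full(n, 0.1),
                             "sd_y": np.full(n, 0.1),
                             "sd_z": np.full(n, 0.1)})
        assert detect_pee(flat) == []

    def test_misaligned_clock_raises(self):
        bad = _sd3([1], [1], [1])
        bad.loc[5, "t"] = 5.5
        with pytest.raises(ValueError):
            detect_pee(bad)


def _dive(dive_id, start, end):
    prof = DepthSeries(np.arange(start, end + 1.0),
                       np.full(int(end - start) + 1, 100.0))
    return Dive(0, dive_id, start, end, prof, 100.0)


class TestCountPee:
    def test_counts_per_dive_and_day(self):
        dives = [_dive(0, 100, 700), _dive(1, 900, 1500)]
        ev = [PeeEvent(0, s, s + 1) for s in
              (150, 200, 250, 950, 1000, 1050, 1100)]
        per_dive, per_day = count_pee(ev, dives)
        assert dict(zip(per_dive["dive_id"], per_dive["npee"])) == {0: 3, 1: 4}
        assert per_day["npee_day"].tolist() == [7]

    def test_no_events(self):
        per_dive, per_day = count_pee([], [_dive(0, 100, 700)])
        assert per_dive["npee"].tolist() == [0]
        assert per_day.empty

    def test_event_at_dive_end_belongs_to_dive(self):
        per_dive, _ = count_pee([PeeEvent(0, 700.0, 701.0)],
                                [_dive(0, 100, 700)])
        assert per_dive["npee"].tolist() == [1]

    def test_surface_events_count_toward_days_only(self):
        dives = [_dive(0, 100, 700)]
        ev = [PeeEvent(0, 800.0, 801.0), PeeEvent(0, 300.0, 301.0)]
        per_dive, per_day = count_pee(ev, dives)
        assert per_dive["npee"].sum() == 1
        assert per_day["npee_day"].sum() == 2

    def test_overlapping_dives_raise(self):
        with pytest.raises(ValueError):
            count_pee([], [_dive(0, 100, 700), _dive(1, 600, 1200)])


class TestDetectorOnSyntheticTrips:
    def _match_stats(self, truth, detected):
        def overlap(a, b):
            return a.start < b.end and b.start < a.end
        sens = np.mean([any(overlap(t, d) for d in detected) for t in truth])
        prec = np.mean([any(overlap(d, t) for t in truth) for d in detected])
        return sens, prec

    def test_recovery_and_scale_invariance(self, trip, pipeline):
        part = pipeline["parts"][0]
        truth, detected = trip.truth_pee, part["events"]
        sens, prec = self._match_stats(truth, detected)
        assert sens >= 0.90 and prec >= 0.90
        # multiplying all axes by a constant leaves events unchanged
        from foragemetrics.pee import smoothed_dynamic_sd
        scaled = AccelSeries(trip.accel.t0, trip.accel.fs,
                             3.7 * trip.accel.ax, 3.7 * trip.accel.ay,
                             3.7 * trip.accel.az)
        ev2 = detect_pee(smoothed_dynamic_sd(scaled))
        assert [(e.start, e.end) for e in ev2] == \
            [(e.start, e.end) for e in detected]
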