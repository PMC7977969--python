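import numpy as np
import pytest

import mealflow as mf
from mealflow.bite_counting import BiteEvents
from mealflow.chew_counting import (ChewConfig, PeakConfig, count_chews, count_peaks,
                                    dynamic_threshold, segment_between_bites,
                                    short_time_energy)
from mealflow.frames_io import ConfigError
from mealflow.optical_flow import FlowSeries


def brute_force_peaks(s, drop):
    """Independent prominence oracle: for each local max, scan each side to
    the nearest strictly higher sample (or the signal end), take the minimum
    of each scanned stretch, and use the larger minimum as the base."""
    s = np.asarray(s, dtype=float)
    peaks = []
    for i in range(1, len(s) - 1):
        if not (s[i] > s[i - 1] and s[i] >= s[i + 1]):
            continue
        left_min = s[i]
        j = i - 1
        while j >= 0 and s[j] <= s[i]:
            left_min = min(left_min, s[j])
            j -= 1
        right_min = s[i]
        j = i + 1
        while j < len(s) and s[j] <= s[i]:
            right_min = min(right_min, s[j])
            j += 1
        if s[i] - max(left_min, right_min) >= drop:
            peaks.append(i)
    return peaks


def _flow(r, valid=None, fps=6.0):
    r = np.asarray(r, dtype=float)
    if valid is None:
        valid = np.ones(len(r), dtype=bool)
    return FlowSeries(r_values=r, frame_index=list(range(len(r))),
                      valid=np.asarray(valid), fps=fps)


class TestShortTimeEnergy:
    def test_zero_and_constant_signals_have_zero_energy(self):
        assert np.all(short_time_energy(np.zeros(30), 6) == 0)
        assert np.all(short_time_energy(np.full(30, 2.5), 6) == 0)

    def test_sinusoid_energy_matches_brute_force(self):
        a, w = 0.8, 12
        t = np.arange(120)
        sig = a * np.sin(2 * np.pi * t / 12)
        got = short_time_energy(sig, w, hop=w)
        mean = sig.mean()
        expected = [np.sum((sig[k:k + w] - mean) ** 2) for k in range(0, 120, w)]
        np.testing.assert_allclose(got, expected)
        # full windows of a whole cycle hold ~ w * a^2 / 2
        np.testing.assert_allclose(got[:-1], w * a ** 2 / 2, rtol=0.05)

    def test_empty_signal_empty_series(self):
        assert short_time_energy(np.zeros(0)).size == 0


class TestDynamicThreshold:
    def test_single_segment_halved(self):
        assert dynamic_threshold([3.0], beta=0.5) == 1.5

    def test_all_zero_energies(self):
        assert dynamic_threshold([0, 0, 0], beta=0.7) == 0.0

    def test_matches_sorted_median_oracle(self, rng):
        e = rng.lognormal(0, 1, size=51)
        srt = np.sort(e)
        assert dynamic_threshold(e, 0.5) == pytest.approx(0.5 * srt[25])

    def test_empty_rejected(self):
        with pytest.raises(ConfigError):
            dynamic_threshold([])


class TestSegmentation:
    def test_plain_inter_bite_segment(self):
        flow = _flow(np.ones(400))
        bites = BiteEvents([(10, 12), (100, 103)])
        segs = segment_between_bites(flow, bites)
        assert segs[0] == (12, 100)

    def test_truncation_at_52_seconds(self):
        flow = _flow(np.ones(500))
        bites = BiteEvents([(10, 12), (400, 402)])
        segs = segment_between_bites(flow, bites)
        assert segs[0] == (12, 12 + 312)  # 52 s * 6 fps

    def test_tail_after_last_bite_is_kept_head_before_first_is_not(self):
        flow = _flow(np.ones(100))
        segs = segment_between_bites(flow, BiteEvents([(40, 45)]))
        assert segs == [(45, 100)]

    def test_random_layouts_never_overlap_bites_or_exceed_cap(self, rng):
        for _ in range(100):
            n = int(rng.integers(100, 1200))
            flow = _flow(rng.normal(size=n))
            starts = np.sort(rng.choice(np.arange(0, n - 5), size=4, replace=False))
            events = []
            prev_end = 0
            for s in starts:
                s = max(s, prev_end)
                e = min(s + int(rng.integers(1, 5)), n)
                if e > s:
                    events.append((int(s), int(e)))
                    prev_end = e
            bites = BiteEvents(events)
            for s, e in segment_between_bites(flow, bites):
                assert e - s <= 312
                for bs, be in events:
                    assert e <= bs or s >= be

    def test_no_bites_no_segments(self):
        assert segment_between_bites(_flow(np.ones(50)), BiteEvents([])) == []


class TestPeakCounting:
    def test_monotone_signal_has_no_peaks(self):
        assert count_peaks(np.arange(20.0)) == []

    @pytest.mark.parametrize("sig,drop,expected", [
        ([0, 1, 0, 1, 0], 0.5, [1, 3]),
        ([0, 0.3, 0, 0.3, 0], 0.5, []),
    ])
    def test_prominence_threshold_examples(self, sig, drop, expected):
        assert count_peaks(np.array(sig), PeakConfig(drop_threshold=drop)) == expected

    def test_plateau_counts_once_at_first_index(self):
        sig = np.array([0, 1, 1, 1, 0, 0])
        assert count_peaks(sig) == [1]

    def test_short_signal_no_peaks(self):
        assert count_peaks(np.array([0.0, 5.0])) == []

    def test_random_walk_matches_brute_force_oracle(self, rng):
        sig = np.cumsum(rng.normal(size=500))
        got = count_peaks(sig, PeakConfig(drop_threshold=0.5))
        assert got == brute_force_peaks(sig, 0.5)

    def test_oracle_equivalence_across_many_signals(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(3, 120))
            kind = rng.integers(3)
            if kind == 0:
                sig = rng.normal(size=n)
            elif kind == 1:
                sig = np.cumsum(rng.normal(size=n))
            else:
                sig = np.round(rng.normal(size=n))  # heavy ties and plateaus
            drop = float(rng.uniform(0.1, 2.0))
            assert count_peaks(sig, PeakConfig(drop_threshold=drop)) == \
                brute_force_peaks(sig, drop)


class TestCountChews:
    def _meal(self, r, bite_events, **cfg):
        return count_chews(_flow(r), BiteEvents(bite_events),
                           ChewConfig(**cfg))

    def test_zero_flow_counts_zero_chews(self):
        summary = self._meal(np.zeros(200), [(10, 15), (100, 105)])
        assert summary.n_chews == 0

    def test_sinusoid_segment_counts_cycles(self):
        # 30 s of 1.5 Hz chewing at 6 fps between two bites -> 45 cycles;
        # a second, near-silent segment stays inactive
        fps, f = 6.0, 1.5
        n = 500
        r = np.zeros(n)
        t = np.arange(int(30 * fps))
        r[20:20 + len(t)] = np.sin(2 * np.pi * f * t / fps)
        r[300:440] = 0.001 * np.sin(2 * np.pi * f * np.arange(140) / fps)
        summary = self._meal(r, [(10, 18), (290, 298)], normalize_amplitude=False)
        active = [s for s in summary.segments if s.active]
        assert len(active) == 1
        assert abs(summary.n_chews - 45) <= 1

    def test_noiseless_exact_cycle_count(self):
        # noiseless sinusoidal chewing with amplitude >= 2x drop threshold
        # counts exactly the number of full cycles
        fps, f, cycles = 6.0, 1.5, 15
        n_sin = int(cycles * fps / f)
        r = np.zeros(200)
        r[30:30 + n_sin] = 2.0 * np.sin(2 * np.pi * f * np.arange(n_sin) / fps)
        summary = self._meal(r, [(10, 20)], normalize_amplitude=False,
                             drop_threshold=0.5)
        assert summary.n_chews == cycles

    def test_scale_equivariance_of_peak_rule(self):
        rng = np.random.default_rng(21)
        r = np.zeros(400)
        r[50:350] = np.sin(2 * np.pi * 1.5 * np.arange(300) / 6.0) + \
            0.1 * rng.normal(size=300)
        base = self._meal(r, [(10, 20)], normalize_amplitude=False,
                          drop_threshold=0.5).n_chews
        scaled = self._meal(7.3 * r, [(10, 20)], normalize_amplitude=False,
                            drop_threshold=7.3 * 0.5).n_chews
        assert base == scaled

    def test_normalized_mode_is_scale_invariant(self):
        r = np.zeros(400)
        r[50:350] = 0.02 * np.sin(2 * np.pi * 1.5 * np.arange(300) / 6.0)
        a = self._meal(r, [(10, 20)]).n_chews
        b = self._meal(1000 * r, [(10, 20)]).n_chews
        assert a == b > 0

    def test_deactivating_segment_only_decreases_count(self):
        fps, f = 6.0, 1.5
        r = np.zeros(700)
        for start in (50, 300, 550):
            r[start:start + 120] = np.sin(2 * np.pi * f * np.arange(120) / fps)
        bites = [(30, 40), (280, 290), (530, 540)]
        full = self._meal(r, bites, normalize_amplitude=False)
        # silencing one chewing burst drops its segment below threshold
        r2 = r.copy()
        r2[300:420] = 0.0
        fewer = self._meal(r2, bites, normalize_amplitude=False)
        assert fewer.n_chews <= full.n_chews

    def test_invalid_gap_bridged_by_interpolation(self):
        fps, f = 6.0, 1.5
        n_sin = 120
        r = np.zeros(200)
        r[40:40 + n_sin] = 2.0 * np.sin(2 * np.pi * f * np.arange(n_sin) / fps)
        valid = np.ones(200, dtype=bool)
        valid[70:73] = False  # 0.5-s dropout, below the 1-s bridge limit
        flow = _flow(r, valid)
        summary = count_chews(flow, BiteEvents([(10, 20)]),
                              ChewConfig(normalize_amplitude=False))
        expected_cycles = n_sin // 4
        assert abs(summary.n_chews - expected_cycles) <= 1

    def test_long_invalid_run_splits_segment(self):
        r = np.ones(100)
        valid = np.ones(100, dtype=bool)
        valid[40:60] = False  # 3.3 s, above the bridge limit
        summary = count_chews(_flow(r, valid), BiteEvents([(0, 5)]), ChewConfig())
        spans = [(s.start_frame, s.end_frame) for s in summary.segments]
        assert len(spans) == 2
        assert spans[0][1] <= 40 and spans[1][0] >= 60

    def test_fixture_recovery_within_10pct(self):
        script = mf.default_script(seed=17, label_flip_p=0.02,
                                   noise_sigma=0.1 * 2 * 0.01)
        flow, probs, gt = mf.signal_fixture(script)
        bites = mf.count_bites(probs)
        summary = count_chews(flow, bites, ChewConfig())
        err = abs(summary.n_chews - gt.true_chew_count_total) / gt.true_chew_count_total
        assert err <= 0.10
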