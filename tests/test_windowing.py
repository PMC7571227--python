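import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldvbeat import (
    RPeakList,
    SyntheticConfig,
    WindowingConfig,
    extract_windows,
    generate_cohort,
    load_windows,
    measure_pulse_statistics,
    save_windows,
    undersample,
)
from ldvbeat.windowing import BEAT, NO_BEAT, WindowDataset


def brute_force_starts(rpeaks, n, cfg):
    """Independent enumerator of the labeling grid: generate every candidate
    start and filter by the stopping inequality."""
    out = []
    r = list(rpeaks)
    for i in range(len(r) - 1):
        limit = r[i + 1] + cfg.overrun
        for j in range(10_000):
            s = r[i] + j * cfg.step
            end = s + cfg.window_len
            if (end >= limit) if cfg.strict_stop else (end > limit):
                break
            if end <= n:
                out.append((s, BEAT if s == r[i] else NO_BEAT))
        else:  # pragma: no cover
            raise AssertionError("unbounded grid")
    if r and r[-1] + cfg.window_len <= n:
        out.append((r[-1], BEAT))
    return out


class TestExtractWindows:
    def test_hand_enumerated_two_beat_cycle(self):
        """R at {0, 450}, signal 600, defaults: starts 0,15,...,435 in the
        cycle (stopping rule start+75 <= 510) plus the final beat window."""
        ldv = np.arange(600, dtype=float)
        ds = extract_windows(ldv, np.array([0, 450]), WindowingConfig())
        assert len(ds) == 31
        assert int(ds.y.sum()) == 2
        np.testing.assert_array_equal(
            ds.start_samples, list(range(0, 436, 15)) + [450]
        )
        # window content is the raw signal slice
        np.testing.assert_array_equal(ds.X[1], np.arange(15, 90, dtype=float))

    def test_empty_rpeaks_empty_dataset(self):
        ds = extract_windows(np.zeros(1000), np.array([], dtype=int))
        assert len(ds) == 0

    def test_single_rpeak_gives_only_its_beat_window(self):
        ds = extract_windows(np.zeros(1000), np.array([100]))
        assert len(ds) == 1
        assert ds.y[0] == BEAT and ds.start_samples[0] == 100

    def test_final_incomplete_beat_window_dropped(self):
        ds = extract_windows(np.zeros(120), np.array([100]))
        assert len(ds) == 0

    def test_every_beat_window_starts_on_an_rpeak(self, default_recording):
        rec, gt = default_recording
        ds = extract_windows(rec.ldv, gt.r_peak_samples)
        beat_starts = ds.start_samples[ds.y == BEAT]
        assert set(beat_starts) <= set(gt.r_peak_samples)

    @settings(max_examples=250, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(1, 400), min_size=1, max_size=6),
        st.integers(5, 100),
        st.integers(1, 50),
        st.integers(0, 80),
        st.booleans(),
    )
    def test_matches_bruteforce_enumerator(self, rrs, wd, ws, overlap, strict):
        ws = min(ws, wd)
        r = np.cumsum([10] + rrs)
        n = int(r[-1] + 200)
        cfg = WindowingConfig(window_len=wd, step=ws, overrun=overlap,
                              strict_stop=strict)
        ds = extract_windows(np.zeros(n), r, cfg)
        expected = brute_force_starts(r, n, cfg)
        assert list(zip(ds.start_samples.tolist(), ds.y.tolist())) == expected

    def test_closed_form_cycle_count(self):
        """Windows per cycle = floor((RR + overrun - window_len)/step) + 1
        when RR + overrun >= window_len."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            wd = int(rng.integers(5, 100))
            ws = int(rng.integers(1, wd + 1))
            ov = int(rng.integers(0, 80))
            rr = int(rng.integers(max(1, wd - ov), 500))
            cfg = WindowingConfig(window_len=wd, step=ws, overrun=ov)
            r = np.array([0, rr])
            n = rr + ov + wd + ws  # long enough for the whole grid
            ds = extract_windows(np.zeros(n), r, cfg)
            in_cycle = np.sum(ds.start_samples < rr) + np.sum(
                (ds.start_samples >= rr) & (ds.y == NO_BEAT)
            )
            expected = (rr + ov - wd) // ws + 1
            assert in_cycle == expected


class TestUndersample:
    def _dataset(self, n_beat, n_nobeat, subject="a", wd=5, seed=0):
        rng = np.random.default_rng(seed)
        n = n_beat + n_nobeat
        y = np.array([BEAT] * n_beat + [NO_BEAT] * n_nobeat)
        return WindowDataset(
            rng.normal(size=(n, wd)), y, np.arange(n) * 10,
            np.array([subject] * n, dtype=object),
        )

    def test_balances_exactly(self):
        ds = undersample(self._dataset(1, 29), seed=1)
        assert len(ds) == 2
        assert int(ds.y.sum()) == 1

    def test_already_balanced_returned_as_same_set(self):
        src = self._dataset(5, 5)
        out = undersample(src, seed=3)
        assert sorted(out.start_samples.tolist()) == sorted(src.start_samples.tolist())

    def test_seeded_determinism(self):
        src = self._dataset(10, 100)
        a = undersample(src, seed=42)
        b = undersample(src, seed=42)
        np.testing.assert_array_equal(a.start_samples, b.start_samples)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            undersample(self._dataset(0, 10))

    def test_insufficient_pool_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            undersample(self._dataset(5, 3))

    def test_per_subject_balance(self):
        a = self._dataset(3, 30, subject="a")
        b = self._dataset(7, 70, subject="b", seed=1)
        out = undersample(WindowDataset.concatenate([a, b]), seed=0)
        for subj, k in (("a", 3), ("b", 7)):
            mask = out.subject_ids == subj
            assert int(out.y[mask].sum()) == k
            assert int((out.y[mask] == NO_BEAT).sum()) == k

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(1, 20), st.integers(0, 200), st.integers(0, 2**31 - 1))
    def test_output_always_class_balanced(self, n_beat, extra, seed):
        ds = self._dataset(n_beat, n_beat + extra)
        out = undersample(ds, seed=seed)
        assert int((out.y == BEAT).sum()) == int((out.y == NO_BEAT).sum()) == n_beat


class TestPulseStatistics:
    def test_single_beat_delay_read_off_exactly(self):
        cfg = SyntheticConfig(duration_s=2.0, hr_mean_bpm=30.0, hr_sd_bpm=0.0,
                              pulse_delay_ms=102.0, pulse_delay_sd_ms=0.0,
                              noise_sd=0.0, resp_amp=0.0, jugular_amp_frac=0.0,
                              seed=1)
        from ldvbeat import generate_recording

        rec, gt = generate_recording(cfg)
        rp = RPeakList(gt.r_peak_samples, rec.fs)
        stats = measure_pulse_statistics([rec], [rp])
        assert stats.delay_mean_ms == pytest.approx(102.0, abs=2.0)

    def test_noise_free_cohort_recovers_delay_and_width(self):
        cfg = SyntheticConfig(
            duration_s=30.0, pulse_delay_ms=100.0, pulse_delay_sd_ms=0.0,
            pulse_width_ms=140.0, pulse_width_sd_ms=0.0, hr_sd_bpm=0.0,
            noise_sd=0.0, resp_amp=0.0, jugular_amp_frac=0.0,
        )
        cohort = generate_cohort(4, cfg, subject_jitter=0.0, seed=3)
        stats = measure_pulse_statistics(
            [rec for rec, _ in cohort],
            [RPeakList(gt.r_peak_samples, rec.fs) for rec, gt in cohort],
        )
        assert stats.delay_mean_ms == pytest.approx(100.0, abs=2.0)
        assert stats.width_mean_ms == pytest.approx(140.0, abs=6.0)

    def test_flat_subject_skipped_with_warning(self):
        from ldvbeat import Recording

        rec = Recording("flat", 500.0, np.zeros(5000), np.zeros(5000))
        rp = RPeakList(np.array([100, 600]), 500.0)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                measure_pulse_statistics([rec], [rp])


class TestWindowArchive:
    def test_round_trip(self, tmp_path, default_recording):
        rec, gt = default_recording
        ds = extract_windows(rec.ldv, gt.r_peak_samples, subject_id="s1")
        p = tmp_path / "w.npz"
        save_windows(ds, p)
        back = load_windows(p)
        np.testing.assert_array_equal(back.X, ds.X)
        np.testing.assert_array_equal(back.y, ds.y)
        assert list(back.subject_ids) == list(ds.subject_ids)
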