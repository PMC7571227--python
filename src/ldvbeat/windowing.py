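"""Sliding-window extraction and labeling of LDV signals, and pulse statistics.

The labeler turns a continuous LDV trace plus ECG-derived R peaks into a
supervised dataset: for every cardiac cycle a grid of fixed-length windows
starts at the R peak and advances by a fixed step until the window end
passes the next R peak by a configured overrun.  The window that starts
exactly at the R peak is labeled *beat*; every other window in the cycle is
*no-beat*.  With the default 500 Hz geometry (window 75 samples = 150 ms,
step 15 samples, overrun 60 samples) the beat window spans the onset of the
carotid pulse, which peaks ~102 ms after R.

Because no-beat windows vastly outnumber beat windows, a per-subject random
undersampler balances the classes before training.

:func:`measure_pulse_statistics` reproduces the measurement that motivates
the window geometry: average the 800 ms of LDV following every R peak into
one mean waveform per subject, then read off the pulse-peak latency and its
full width at half maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import Recording
from .qrs import RPeakList

BEAT = 1
NO_BEAT = 0


@dataclass(frozen=True)
class WindowingConfig:
    """Geometry of the sliding-window labeler.

    Attributes
    ----------
    window_len : int
        Window length in samples (75 = 150 ms at 500 Hz).
    step : int
        Grid step in samples between consecutive window starts.
    overrun : int
        How many samples a window's end may extend past the next R peak
        before the grid stops for that cycle.
    fs : float
        Sampling rate, Hz.
    strict_stop : bool
        If False (default) a window is emitted while
        ``start + window_len <= next_R + overrun``; if True the inequality
        is strict.  The prose definition of the stopping rule admits an
        off-by-one; both readings are exposed.
    """

    window_len: int = 75
    step: int = 15
    overrun: int = 60
    fs: float = 500.0
    strict_stop: bool = False

    def __post_init__(self):
        if not 0 < self.step <= self.window_len:
            raise ValueError("need 0 < step <= window_len")
        if self.overrun < 0:
            raise ValueError("overrun must be >= 0")
        if not self.fs > 0:
            raise ValueError("fs must be positive")


@dataclass
class WindowDataset:
    """Labeled fixed-length LDV windows.

    ``X`` is an (N, window_len) matrix of raw LDV values, ``y`` the binary
    labels (1 = beat), ``start_samples`` the window start indices in the
    source signal and ``subject_ids`` the per-window subject tags.
    """

    X: np.ndarray
    y: np.ndarray
    start_samples: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X.reshape(1, -1) if self.X.size else self.X.reshape(0, 0)
        self.y = np.asarray(self.y, dtype=int)
        self.start_samples = np.asarray(self.start_samples, dtype=int)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        n = len(self.y)
        if not (self.X.shape[0] == n == len(self.start_samples) == len(self.subject_ids)):
            raise ValueError("field lengths disagree")
        if n and not np.isin(self.y, [BEAT, NO_BEAT]).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx) -> "WindowDataset":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return WindowDataset(
            self.X[idx].reshape(len(idx), self.X.shape[1]),
            self.y[idx],
            self.start_samples[idx],
            self.subject_ids[idx],
        )

    @staticmethod
    def concatenate(parts: list["WindowDataset"]) -> "WindowDataset":
        parts = [p for p in parts if len(p)]
        if not parts:
            return _empty_dataset(0)
        return WindowDataset(
            np.vstack([p.X for p in parts]),
            np.concatenate([p.y for p in parts]),
            np.concatenate([p.start_samples for p in parts]),
            np.concatenate([p.subject_ids for p in parts]),
        )


def _empty_dataset(window_len: int) -> WindowDataset:
    return WindowDataset(
        np.empty((0, window_len)), np.empty(0, int), np.empty(0, int),
        np.empty(0, object),
    )


def extract_windows(
    ldv,
    rpeaks: RPeakList | np.ndarray,
    cfg: WindowingConfig | None = None,
    subject_id: str = "s00",
) -> WindowDataset:
    """Extract and label the per-cycle window grid from one LDV trace.

    For each consecutive R-peak pair (R_i, R_{i+1}) windows start at
    R_i, R_i+step, R_i+2*step, ... while ``start + window_len`` does not
    exceed ``R_{i+1} + overrun`` (the grid restarts at each R peak, so the
    beat window is always grid-aligned).  Windows running past the end of
    the signal are dropped.  After the last R peak only its beat window is
    emitted, and only if complete.  Fewer than two R peaks therefore yield
    at most that final beat window; an empty peak list yields an empty
    dataset.
    """
    if cfg is None:
        cfg = WindowingConfig()
    ldv = np.asarray(ldv, dtype=float)
    n = len(ldv)
    r = np.asarray(rpeaks.samples if isinstance(rpeaks, RPeakList) else rpeaks, dtype=int)
    if len(r) and (r[0] < 0 or r[-1] >= n):
        raise ValueError("R peaks outside signal bounds")
    W, S, V = cfg.window_len, cfg.step, cfg.overrun

    starts: list[int] = []
    labels: list[int] = []
    for i in range(len(r) - 1):
        limit = r[i + 1] + V
        s = r[i]
        while (s + W < limit) if cfg.strict_stop else (s + W <= limit):
            if s + W <= n:
                starts.append(int(s))
                labels.append(BEAT if s == r[i] else NO_BEAT)
            s += S
    if len(r) and r[-1] + W <= n:
        starts.append(int(r[-1]))
        labels.append(BEAT)

    if not starts:
        return _empty_dataset(W)
    X = np.stack([ldv[s: s + W] for s in starts])
    return WindowDataset(
        X, np.array(labels), np.array(starts),
        np.array([subject_id] * len(starts), dtype=object),
    )


def undersample(ds: WindowDataset, seed: int = 0) -> WindowDataset:
    """Balance the classes by per-subject random undersampling.

    All beat windows are kept; for each subject, as many no-beat windows as
    that subject has beat windows are drawn uniformly without replacement
    from the subject's own no-beat pool.  Deterministic given ``seed``.

    Raises
    ------
    ValueError
        If the input lacks one of the classes, or a subject's no-beat pool
        is smaller than its beat count.
    """
    if len(ds) == 0 or len(np.unique(ds.y)) < 2:
        raise ValueError("undersample needs both classes present")
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for subj in sorted(set(ds.subject_ids)):
        mask = ds.subject_ids == subj
        beat_idx = np.flatnonzero(mask & (ds.y == BEAT))
        nobeat_idx = np.flatnonzero(mask & (ds.y == NO_BEAT))
        if len(nobeat_idx) < len(beat_idx):
            raise ValueError(
                f"subject {subj}: no-beat pool ({len(nobeat_idx)}) smaller "
                f"than beat count ({len(beat_idx)})"
            )
        sel = rng.choice(nobeat_idx, size=len(beat_idx), replace=False)
        keep.extend(beat_idx.tolist())
        keep.extend(sel.tolist())
    return ds.subset(np.sort(np.array(keep, dtype=int)))


@dataclass
class PulseStats:
    """Across-subject carotid pulse statistics (milliseconds)."""

    delay_mean_ms: float
    delay_sd_ms: float
    width_mean_ms: float
    width_sd_ms: float
    n_subjects: int


def _fwhm(wave: np.ndarray, p: int) -> float:
    """Full width at half maximum of the peak at index ``p``, in samples.

    The half-maximum level is measured relative to the waveform baseline
    (its minimum), not to scipy's contour-line prominence, which is clipped
    when a peak sits close to the segment edge.  Crossings are linearly
    interpolated; a side that never crosses is clipped at the segment edge.
    """
    base = float(wave.min())
    level = base + 0.5 * (float(wave[p]) - base)
    left = 0.0
    for i in range(p, 0, -1):
        if wave[i - 1] < level:
            frac = (wave[i] - level) / (wave[i] - wave[i - 1])
            left = i - frac
            break
    right = float(len(wave) - 1)
    for i in range(p, len(wave) - 1):
        if wave[i + 1] < level:
            frac = (wave[i] - level) / (wave[i] - wave[i + 1])
            right = i + frac
            break
    return right - left


def measure_pulse_statistics(
    recordings: list[Recording],
    rpeaks: list[RPeakList],
    segment_ms: float = 800.0,
    search_ms: tuple[float, float] = (20.0, 400.0),
) -> PulseStats:
    """Measure the post-R pulse delay and width of each subject's mean LDV wave.

    Per subject, every ``segment_ms`` of LDV following an R peak is averaged
    into one mean waveform; the primary pulse is the largest local maximum
    with latency in ``(search_ms[0], search_ms[1]]``; its latency is the
    delay and its baseline-relative full width at half maximum the width.
    Subjects whose mean waveform has no local maximum in the search interval
    are skipped with a warning.  Returns across-subject mean and SD of both
    quantities (SD is 0 with a single contributing subject).
    """
    delays: list[float] = []
    widths: list[float] = []
    for rec, rp in zip(recordings, rpeaks):
        fs = rec.fs
        seg_len = int(round(segment_ms / 1000.0 * fs))
        segs = [
            rec.ldv[s: s + seg_len]
            for s in np.asarray(rp.samples, dtype=int)
            if s + seg_len <= len(rec.ldv)
        ]
        if not segs:
            warnings.warn(f"subject {rec.subject_id}: no complete post-R segments")
            continue
        wave = np.mean(np.stack(segs), axis=0)
        lo = search_ms[0] / 1000.0 * fs
        hi = search_ms[1] / 1000.0 * fs
        peaks, _ = sps.find_peaks(wave)
        peaks = peaks[(peaks > lo) & (peaks <= hi)]
        if len(peaks) == 0:
            warnings.warn(
                f"subject {rec.subject_id}: no pulse peak in "
                f"({search_ms[0]}, {search_ms[1]}] ms"
            )
            continue
        p = int(peaks[np.argmax(wave[peaks])])
        delays.append(p / fs * 1000.0)
        widths.append(_fwhm(wave, p) / fs * 1000.0)
    if not delays:
        raise ValueError("no subject produced a measurable pulse")
    ddof = 1 if len(delays) > 1 else 0
    return PulseStats(
        float(np.mean(delays)),
        float(np.std(delays, ddof=ddof)),
        float(np.mean(widths)),
        float(np.std(widths, ddof=ddof)),
        len(delays),
    )


def save_windows(ds: WindowDataset, path) -> None:
    """Persist a window dataset as a compressed ``.npz`` archive."""
    np.savez_compressed(
        path,
        X=ds.X,
        y=ds.y,
        start_samples=ds.start_samples,
        subject_ids=np.asarray(ds.subject_ids, dtype=str),
    )


def load_windows(path) -> WindowDataset:
    """Load a window dataset written by :func:`save_windows`."""
    with np.load(path, allow_pickle=False) as z:
        return WindowDataset(
            z["X"], z["y"], z["start_samples"],
            z["subject_ids"].astype(object),
        )
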