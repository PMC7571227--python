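"""Full-length deployment simulation: sweep, pick beats, estimate heart rate.

A trained classifier is slid across an entire LDV recording (no ECG
anchoring: the grid starts at sample 0 and advances by the window step).
Window starts whose beat probability exceeds a threshold (default 0.9) are
beat candidates; candidates closer together than a refractory interval
(default 250 ms) are merged, keeping the most probable.  Instantaneous
heart rate is 60 / inter-beat-interval, with implausible intervals
(outside 0.3-2.0 s) discarded, and the mean heart rate is compared against
the ECG-derived gold standard per subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .classify import TrainedClassifier, predict, predict_proba
from .evaluate import MetricsReport, ROCResult, compute_metrics, roc_auc
from .io import Recording
from .qrs import RPeakList
from .windowing import BEAT, NO_BEAT, WindowingConfig

#: Physiologically plausible inter-beat-interval bounds, seconds.
IBI_BOUNDS_S = (0.3, 2.0)


@dataclass
class BeatDetections:
    """Above-threshold beat events: strictly increasing times, probabilities."""

    times_s: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.times_s) != len(self.probabilities):
            raise ValueError("times and probabilities must align")
        if len(self.times_s) > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("detection times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_s)


@dataclass
class HRSeries:
    """Instantaneous heart rate (bpm) stamped at the closing beat of each IBI."""

    times_s: np.ndarray
    bpm: np.ndarray
    mean_bpm: float


def sweep_classify(
    rec: Recording,
    model: TrainedClassifier,
    cfg: WindowingConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Classify every grid window of a full-length LDV signal.

    Windows start at 0, step, 2*step, ... using the LDV channel only.
    Returns the window start samples and their beat probabilities.
    """
    if cfg is None:
        cfg = WindowingConfig()
    n = len(rec.ldv)
    if n < cfg.window_len:
        raise ValueError(
            f"recording length {n} shorter than window {cfg.window_len}"
        )
    windows = sliding_window_view(rec.ldv, cfg.window_len)[:: cfg.step]
    starts = np.arange(0, n - cfg.window_len + 1, cfg.step)
    probs = predict_proba(model, np.ascontiguousarray(windows))
    return starts, probs


def detect_beats(
    start_times_s,
    probabilities,
    threshold: float = 0.9,
    refractory_s: float = 0.25,
) -> BeatDetections:
    """Threshold and de-duplicate sweep probabilities into beat events.

    Windows with probability strictly above ``threshold`` are kept; kept
    windows closer than ``refractory_s`` to their predecessor are chained
    into a run, and each run contributes its single most probable window
    (earliest on ties).  Detection time is the window start time.  An empty
    result is allowed.
    """
    t = np.asarray(start_times_s, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if t.shape != p.shape:
        raise ValueError("starts and probabilities must align")
    keep = p > threshold
    t, p = t[keep], p[keep]
    times: list[float] = []
    probs: list[float] = []
    i = 0
    while i < len(t):
        j = i
        while j + 1 < len(t) and t[j + 1] - t[j] < refractory_s:
            j += 1
        run = slice(i, j + 1)
        best = i + int(np.argmax(p[run]))  # argmax returns earliest on ties
        times.append(float(t[best]))
        probs.append(float(p[best]))
        i = j + 1
    return BeatDetections(np.array(times), np.array(probs))


def compute_hr(dets: BeatDetections, ibi_bounds_s: tuple[float, float] = IBI_BOUNDS_S) -> HRSeries:
    """Instantaneous and mean heart rate from beat detections.

    bpm = 60 / (t_{i+1} - t_i), stamped at t_{i+1}; intervals outside
    ``ibi_bounds_s`` are excluded as physiologically implausible.  Requires
    at least two detections.
    """
    if len(dets) < 2:
        raise ValueError("need >= 2 detections to compute heart rate")
    ibi = np.diff(dets.times_s)
    ok = (ibi >= ibi_bounds_s[0]) & (ibi <= ibi_bounds_s[1])
    if not ok.any():
        raise ValueError("no physiologically plausible inter-beat interval")
    bpm = 60.0 / ibi[ok]
    times = dets.times_s[1:][ok]
    return HRSeries(times, bpm, float(np.mean(bpm)))


def hr_from_rpeaks(rpeaks: RPeakList) -> HRSeries:
    """Gold-standard heart-rate series from ECG R peaks."""
    dets = BeatDetections(rpeaks.times_s, np.ones(len(rpeaks)))
    return compute_hr(dets)


def hr_error(ldv_hr: HRSeries, ecg_hr: HRSeries) -> float:
    """Absolute difference of the two mean heart rates, bpm (symmetric)."""
    if len(ldv_hr.bpm) == 0 or len(ecg_hr.bpm) == 0:
        raise ValueError("heart-rate series must be nonempty")
    return float(abs(ldv_hr.mean_bpm - ecg_hr.mean_bpm))


def full_length_metrics(
    starts,
    probabilities,
    rpeaks: RPeakList,
    cfg: WindowingConfig | None = None,
) -> tuple[MetricsReport, ROCResult]:
    """Score a full-length sweep against the ECG gold standard.

    A sweep window is gold-labeled *beat* iff its start lies in
    [R, R + step) for some R peak — the unique grid window starting in
    correspondence of that beat.  Hard predictions threshold the
    probabilities at 0.5; metrics are macro-averaged and the ROC uses the
    raw probabilities.
    """
    if cfg is None:
        cfg = WindowingConfig()
    starts = np.asarray(starts, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    r = np.asarray(rpeaks.samples, dtype=int)
    if len(r) == 0:
        raise ValueError("no R peaks to score against")
    # beat iff some R in (start - step, start]
    idx = np.searchsorted(r, starts, side="right") - 1
    has_r = idx >= 0
    y_true = np.where(has_r & (starts - r[np.clip(idx, 0, None)] < cfg.step), BEAT, NO_BEAT)
    y_pred = np.where(p > 0.5, BEAT, NO_BEAT)
    return compute_metrics(y_true, y_pred), roc_auc(p, y_true)
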