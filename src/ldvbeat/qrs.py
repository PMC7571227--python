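"""Pan-Tompkins QRS detection on the ECG channel.

The classic real-time detector: band-pass 5-15 Hz, five-point derivative,
squaring, 150 ms moving-window integration, then adaptive dual thresholds
with running signal/noise peak estimates, a 200 ms refractory period and a
search-back pass at 1.66x the running RR estimate.  Each accepted fiducial
is finally refined to the local ECG maximum within +/-50 ms.

All thresholds adapt to the signal, so detection is invariant under
amplitude scaling of the input.  Internal constants follow the original
1985 description and are exposed as keyword arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


@dataclass
class RPeakList:
    """Strictly increasing R-peak sample indices with their sampling rate."""

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=int)
        if len(self.samples) > 1 and not np.all(np.diff(self.samples) > 0):
            raise ValueError("R-peak samples must be strictly increasing")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times_s(self) -> np.ndarray:
        return self.samples / self.fs


def _preprocess(ecg: np.ndarray, fs: float, band=(5.0, 15.0), mwi_s=0.150):
    """Band-pass -> derivative -> square -> centered moving-window integrate."""
    nyq = fs / 2.0
    sos = sps.butter(2, [band[0] / nyq, band[1] / nyq], btype="bandpass", output="sos")
    filtered = sps.sosfiltfilt(sos, ecg)
    # five-point derivative, gain-normalized
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0)
    deriv = np.convolve(filtered, kernel, mode="same")
    squared = deriv**2
    win = max(1, int(round(mwi_s * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")
    return mwi


def pan_tompkins(
    ecg,
    fs: float,
    refractory_s: float = 0.200,
    searchback_factor: float = 1.66,
    learning_s: float = 2.0,
    refine_s: float = 0.050,
) -> RPeakList:
    """Detect R peaks in a single-lead ECG.

    Parameters
    ----------
    ecg : array-like
        ECG samples (any amplitude scale).
    fs : float
        Sampling rate, Hz; at least 100 Hz.
    refractory_s : float
        Minimum separation between accepted peaks.
    searchback_factor : float
        Missed-beat search-back is triggered when no peak is accepted for
        this multiple of the running RR estimate.
    learning_s : float
        Length of the initial segment used to seed the adaptive thresholds.
    refine_s : float
        Half-width of the window around the integrator fiducial searched
        for the local ECG maximum.

    Returns
    -------
    RPeakList
        May be empty (a flat signal is not an error).

    Raises
    ------
    ValueError
        If the signal is shorter than the detector warm-up (2 s) or fs is
        too low.
    """
    ecg = np.asarray(ecg, dtype=float)
    if fs < 100:
        raise ValueError(f"fs={fs} too low; need >= 100 Hz")
    if len(ecg) < int(2.0 * fs):
        raise ValueError("signal shorter than detector warm-up (2 s)")

    mwi = _preprocess(ecg, fs)
    refractory = int(round(refractory_s * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if len(cand) == 0 or np.max(mwi) <= 0:
        return RPeakList(np.array([], dtype=int), fs)

    learn = mwi[: int(learning_s * fs)]
    spki = 0.25 * float(np.max(learn)) if len(learn) else 0.25 * float(np.max(mwi))
    npki = 0.5 * float(np.mean(learn)) if len(learn) else 0.0

    accepted: list[int] = []
    rr_history: list[float] = []
    rr_avg = None

    def threshold1():
        return npki + 0.25 * (spki - npki)

    i = 0
    while i < len(cand):
        idx = cand[i]
        peak = mwi[idx]
        thr1 = threshold1()
        is_qrs = False
        if peak > thr1 and (not accepted or idx - accepted[-1] > refractory):
            is_qrs = True
            spki = 0.125 * peak + 0.875 * spki
        else:
            npki = 0.125 * peak + 0.875 * npki

        if is_qrs:
            if accepted:
                rr = (idx - accepted[-1]) / fs
                rr_history.append(rr)
                rr_history[:] = rr_history[-8:]
                rr_avg = float(np.mean(rr_history))
            accepted.append(int(idx))
        elif accepted and rr_avg is not None:
            # search-back: no beat for too long -> revisit skipped candidates
            gap = (idx - accepted[-1]) / fs
            if gap > searchback_factor * rr_avg:
                thr2 = 0.5 * thr1
                window = [
                    c for c in cand
                    if accepted[-1] + refractory < c <= idx and mwi[c] > thr2
                ]
                if window:
                    best = int(max(window, key=lambda c: mwi[c]))
                    spki = 0.25 * mwi[best] + 0.75 * spki
                    rr = (best - accepted[-1]) / fs
                    rr_history.append(rr)
                    rr_history[:] = rr_history[-8:]
                    rr_avg = float(np.mean(rr_history))
                    accepted.append(best)
                    accepted.sort()
        i += 1

    # refine to the local raw-ECG maximum around each integrator fiducial
    half = int(round(refine_s * fs))
    refined: list[int] = []
    for idx in accepted:
        lo, hi = max(0, idx - half), min(len(ecg), idx + half + 1)
        r = lo + int(np.argmax(ecg[lo:hi]))
        if not refined or r - refined[-1] >= refractory:
            refined.append(r)
        elif ecg[r] > ecg[refined[-1]]:
            refined[-1] = r

    return RPeakList(np.array(refined, dtype=int), fs)
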