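"""Reading and writing paired ECG + LDV recordings.

A :class:`Recording` couples a single-lead ECG trace (volts) with a
laser-Doppler-vibrometry (LDV) trace of carotid-wall vibrational velocity
(mm/s), sampled synchronously.  The canonical sampling rate is 500 Hz and
LDV hardware that reports raw volts is converted at 5 mm/s per volt.

Two on-disk formats are supported:

* **csv** — plain text, with ``# key=value`` comment header lines carrying
  ``fs``, ``subject_id`` and ``ldv_units`` (``mm_per_s`` or ``V``), a header
  row ``t,ecg,ldv`` and one row per sample.  Values are written with 12
  significant digits, so a round trip is lossless to that precision.
* **archive** — a compressed NumPy ``.npz`` container with arrays ``ecg``
  and ``ldv`` and scalar metadata ``fs``, ``subject_id``, ``t0``.  Round
  trips are bit-exact.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: LDV hardware conversion factor, velocity per output volt.
LDV_MM_PER_S_PER_VOLT = 5.0

#: Canonical sampling rate of the acquisition setup, Hz.
CANONICAL_FS = 500.0


class FormatError(ValueError):
    """Raised when an input file does not conform to a documented dialect."""


@dataclass
class Recording:
    """A synchronized two-channel ECG + LDV recording for one subject.

    Attributes
    ----------
    subject_id : str
        Identifier of the recorded subject.
    fs : float
        Sampling rate in Hz (both channels share it).
    ecg : ndarray
        ECG channel in volts.
    ldv : ndarray
        LDV vibrational-velocity channel in mm/s.
    t0 : float
        Start-time offset of the first sample in seconds.
    """

    subject_id: str
    fs: float
    ecg: np.ndarray
    ldv: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.ldv = np.asarray(self.ldv, dtype=float)
        if self.ecg.ndim != 1 or self.ldv.ndim != 1:
            raise ValueError("channels must be 1-D")
        if len(self.ecg) != len(self.ldv):
            raise ValueError(
                f"channel length mismatch: ecg={len(self.ecg)} ldv={len(self.ldv)}"
            )
        if len(self.ecg) < 1:
            raise ValueError("recording must contain at least one sample")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return len(self.ecg)

    @property
    def duration_s(self) -> float:
        return len(self.ecg) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample time stamps in seconds."""
        return self.t0 + np.arange(len(self.ecg)) / self.fs


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = os.path.splitext(str(path))[1].lower()
    return "archive" if ext == ".npz" else "csv"


def read_recording(path, format: str | None = None, dialect: str = "canonical") -> Recording:
    """Read a paired ECG+LDV recording from ``path``.

    Parameters
    ----------
    path : path-like
        File to read.
    format : {"csv", "archive"}, optional
        Inferred from the extension when omitted (``.npz`` -> archive).
    dialect : {"canonical", "zenodo"}
        ``canonical`` is the dialect this package writes.  ``zenodo`` is a
        best-effort loader for the released carotid-LDV deposit
        (zenodo record 3892521), whose native layout is not formally
        documented; it assumes a delimited text file with a time column and
        one ECG and one LDV column (matched case-insensitively by name, or
        taken as columns 2 and 3 of ``t, ecg, ldv`` order), the LDV given as
        raw vibrometer volts and converted at 5 mm/s/V, and the sampling
        rate inferred from the median time step (500 Hz expected).  Confirm
        the column mapping against the actual deposit before relying on it.

    Returns
    -------
    Recording
        Channels aligned sample-for-sample; LDV in mm/s (the 5 mm/s/V
        conversion is applied when the file declares raw volts).
    """
    fmt = _infer_format(path, format)
    if dialect == "zenodo":
        return _read_zenodo(path)
    if dialect != "canonical":
        raise ValueError(f"unknown dialect: {dialect!r}")
    if fmt == "archive":
        with np.load(path, allow_pickle=False) as z:
            return Recording(
                subject_id=str(z["subject_id"]),
                fs=float(z["fs"]),
                ecg=z["ecg"].astype(float),
                ldv=z["ldv"].astype(float),
                t0=float(z["t0"]) if "t0" in z else 0.0,
            )
    if fmt != "csv":
        raise ValueError(f"unknown format: {fmt!r}")

    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    try:
        fs = float(meta["fs"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: missing or malformed fs header") from exc
    if fs <= 0:
        raise FormatError(f"{path}: non-positive fs={fs}")

    df = pd.read_csv(path, comment="#")
    for col in ("ecg", "ldv"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing channel column {col!r}")
    ecg = df["ecg"].to_numpy(dtype=float)
    ldv = df["ldv"].to_numpy(dtype=float)
    if np.isnan(ecg).any() or np.isnan(ldv).any():
        raise FormatError(f"{path}: unequal channel lengths or missing values")

    units = meta.get("ldv_units", "mm_per_s")
    if units == "V":
        ldv = ldv * LDV_MM_PER_S_PER_VOLT
    elif units != "mm_per_s":
        raise FormatError(f"{path}: unknown ldv_units={units!r}")

    t0 = float(df["t"].iloc[0]) if "t" in df.columns and len(df) else 0.0
    return Recording(
        subject_id=meta.get("subject_id", os.path.splitext(os.path.basename(str(path)))[0]),
        fs=fs,
        ecg=ecg,
        ldv=ldv,
        t0=t0,
    )


def _read_zenodo(path) -> Recording:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = {str(c).strip().lower(): c for c in df.columns}
    t_col = next((cols[k] for k in ("t", "time", "time_s", "seconds") if k in cols), None)
    ecg_col = next((cols[k] for k in ("ecg", "ecg_v", "lead_ii", "ii") if k in cols), None)
    ldv_col = next((cols[k] for k in ("ldv", "ldv_v", "vibrometer", "velocity") if k in cols), None)
    if ecg_col is None or ldv_col is None:
        if df.shape[1] < 3:
            raise FormatError(f"{path}: cannot identify t/ecg/ldv columns")
        t_col, ecg_col, ldv_col = df.columns[:3]
    t = df[t_col].to_numpy(dtype=float) if t_col is not None else None
    if t is not None and len(t) > 1:
        fs = 1.0 / float(np.median(np.diff(t)))
    else:
        fs = CANONICAL_FS
    return Recording(
        subject_id=os.path.splitext(os.path.basename(str(path)))[0],
        fs=fs,
        ecg=df[ecg_col].to_numpy(dtype=float),
        ldv=df[ldv_col].to_numpy(dtype=float) * LDV_MM_PER_S_PER_VOLT,
        t0=float(t[0]) if t is not None and len(t) else 0.0,
    )


def write_recording(rec: Recording, path, format: str | None = None):
    """Write ``rec`` to ``path``; the file is readable by :func:`read_recording`.

    The archive format round-trips bit-for-bit; CSV round-trips to 12
    significant digits.  Returns the path written.
    """
    fmt = _infer_format(path, format)
    if fmt == "archive":
        np.savez_compressed(
            path,
            ecg=rec.ecg,
            ldv=rec.ldv,
            fs=rec.fs,
            subject_id=rec.subject_id,
            t0=rec.t0,
        )
        return path
    if fmt != "csv":
        raise ValueError(f"unknown format: {fmt!r}")
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:.12g}\n")
        fh.write(f"# subject_id={rec.subject_id}\n")
        fh.write("# ldv_units=mm_per_s\n")
        fh.write("t,ecg,ldv\n")
        t = rec.times
        for i in range(len(rec)):
            fh.write(f"{t[i]:.12g},{rec.ecg[i]:.12g},{rec.ldv[i]:.12g}\n")
    return path
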