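"""Slide a labeling grid over the LDV signal and balance the classes.

For every cardiac cycle, 150 ms windows start at the ECG R peak and advance
in 30 ms steps until they overrun the next R peak by 120 ms.  The window
starting exactly at R is *beat*; the rest are *no-beat*.  Undersampling
then keeps one random no-beat window per beat window, per subject.
"""

from ldvbeat import (
    SyntheticConfig,
    extract_windows,
    generate_recording,
    measure_pulse_statistics,
    pan_tompkins,
    undersample,
)
from ldvbeat.qrs import RPeakList

rec, _ = generate_recording(SyntheticConfig(duration_s=60.0, seed=3))
rpeaks = pan_tompkins(rec.ecg, rec.fs)

ds = extract_windows(rec.ldv, rpeaks, subject_id="demo")
beat = int(ds.y.sum())
print(f"windows: {len(ds)} total, {beat} beat, {len(ds) - beat} no-beat "
      f"(ratio 1:{(len(ds) - beat) / beat:.0f})")

balanced = undersample(ds, seed=3)
print(f"after undersampling: {len(balanced)} windows, "
      f"{int(balanced.y.sum())} per class")

stats = measure_pulse_statistics([rec], [rpeaks])
print(f"pulse delay {stats.delay_mean_ms:.0f} ms, "
      f"width {stats.width_mean_ms:.0f} ms after the R peak")

# ~30 windows tile each cardiac cycle, so no-beat windows outnumber beat
# windows ~30:1 before balancing.  The measured delay/width justify the
# 150 ms window: the carotid pulse rises within it.
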