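"""Simulate a small cohort of paired ECG + carotid-LDV recordings.

Each subject gets a 500 Hz two-channel recording: an ECG with a QRS+T
template per beat, and an LDV trace whose carotid pulse peaks ~102 ms after
each R peak with ~142 ms width, plus a jugular secondary pulse, breathing
drift and noise.  Ground-truth beat anchors come back alongside the signal.
"""

import numpy as np

from ldvbeat import SyntheticConfig, generate_cohort

cohort = generate_cohort(
    n_subjects=4,
    base_cfg=SyntheticConfig(duration_s=30.0),
    subject_jitter=0.1,   # between-subject amplitude/delay/width/rate spread
    seed=42,
)

for rec, gt in cohort:
    delays_ms = (gt.ldv_pulse_peak_samples - gt.r_peak_samples) / rec.fs * 1e3
    print(
        f"{rec.subject_id}: {len(rec)} samples at {rec.fs:.0f} Hz, "
        f"{len(gt.r_peak_samples)} beats, "
        f"mean pulse delay {np.mean(delays_ms):.1f} ms"
    )

# Each line shows one subject: the number of simulated heartbeats in 30 s
# and the average lag of the carotid pulse peak behind the ECG R peak.
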