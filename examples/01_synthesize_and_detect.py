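"""Synthesize a noisy single-lead ECG and detect its R-peaks.

Generates one subject's 60-second recording with baseline wander, mains
pickup and white noise, runs the cleaning chain (baseline subtraction,
smoothing, edge trim) and the Pan-Tompkins-style detector, and scores
the detections against the generator's exact ground truth.
"""

import numpy as np

from morsebeat import denoise, detect_r_peaks
from morsebeat.synthetic import (NoiseSpec, sample_subject_template,
                                 synthesize_recording, white_std_for_snr)

template = sample_subject_template(seed=42)
sigma = white_std_for_snr(template, snr_db=10.0)
record, truth = synthesize_recording(
    template, duration=60.0, noise=NoiseSpec(white_std=sigma), seed=42)

clean = denoise(record)            # drops 600 samples at each end
peaks = detect_r_peaks(clean)
truth_in = truth[(truth >= 600) & (truth < len(record) - 600)] - 600

matched = sum(np.min(np.abs(peaks - t)) <= 20 for t in truth_in)
print(f"subject rhythm: {60 / template.rr_mean:.0f} bpm, "
      f"white-noise SNR 10 dB")
print(f"true beats in the trimmed record : {truth_in.size}")
print(f"detected R-peaks                 : {peaks.size}")
print(f"matched within +-20 ms           : {matched}")
print(f"sensitivity = {matched / truth_in.size:.3f}, "
      f"precision = {matched / peaks.size:.3f}")
# both should be 1.000: every beat found, no false alarms, despite the
# noise being only 10 dB below the signal
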