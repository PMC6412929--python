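"""From one heartbeat to its Morse-wavelet scalogram image.

Cuts a 784-sample beat, computes the continuous wavelet transform with
a generalized Morse wavelet (gamma = 3, P^2 = 60, 12 voices per
octave), and renders the coefficient magnitudes as a 224 x 224 RGB
image — the representation the classifier consumes.
"""

from morsebeat import (MorseParams, beat_scalogram, peak_frequency,
                       render, save_png)
from morsebeat.synthetic import sample_subject_template, synthesize_beat

params = MorseParams()  # gamma=3, P^2=60 -> beta=20, 12 voices/octave
print(f"Morse wavelet: gamma={params.gamma:g}, P^2={params.tbp:g}, "
      f"beta={params.beta:g}")
print(f"peak (angular) frequency of the mother wavelet: "
      f"{peak_frequency(params):.5f} rad/sample")
# (beta/gamma)^(1/gamma) = (20/3)^(1/3) ~= 1.88207

beat = synthesize_beat(sample_subject_template(seed=7), fs=1000.0)
scalo = beat_scalogram(beat, fs=1000.0, params=params)
n_scales, n_time = scalo.shape
print(f"scalogram: {n_scales} scales x {n_time} samples, "
      f"center frequencies {scalo.scale_axis.center_frequencies[-1]:.1f}"
      f"-{scalo.scale_axis.center_frequencies[0]:.1f} Hz")

image = render(scalo, size=(224, 224))
save_png(image, "beat_scalogram.png")
print("wrote beat_scalogram.png (224 x 224 RGB); bright bands mark the "
      "QRS energy across scales")
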