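# morsebeat

ECG biometrics from generalized-Morse-wavelet scalograms.

The electrocardiogram is a behaviorally stable, hard-to-spoof biometric:
each person's heartbeat has a characteristic morphology that persists
across recordings. `morsebeat` implements a complete single-lead (lead I)
pipeline for exploiting it:

1. **Preprocessing** — baseline wander is removed by subtracting a
   500-sample moving average, mains/wideband noise by a 10-sample moving
   average; 600 samples are trimmed from each end to discard filter edge
   distortion; R-peaks are detected with Pan–Tompkins-style stages
   (derivative → squaring → moving-window integration → adaptive
   threshold, 0.25 s refractory period); a 784-sample window centered on
   each R-peak becomes one beat.
2. **Time–frequency transform** — each beat is analyzed with the
   continuous wavelet transform using a generalized Morse wavelet,
   defined in the frequency domain as

       Ψ_{β,γ}(ω) = U(ω) · a_{β,γ} · ω^β · e^{−ω^γ}

   with symmetry parameter γ = 3, time–bandwidth product P² = βγ = 60
   (so β = 20), and a geometric scale axis with 12 voices per octave.
   The filter peaks at ω = (β/γ)^{1/γ} and is zero for ω ≤ 0 (analytic).
   The *scalogram* is the matrix of coefficient magnitudes |CWT(a, b)|.
3. **Rendering** — scalograms are min–max normalized, mapped through a
   64-entry jet-like colormap, and bilinearly resized (28 × 28 for the
   small CNN, 224 × 224 for large backbones).
4. **Classification** — a small CNN (three 3×3 convolutions with 8/16/32
   filters, two 2×2 max-pools, one fully connected layer, softmax),
   trained with SGDM, RMSProp or Adam at initial learning rate 1e-4,
   implemented in numpy with seeded, bit-reproducible training. External
   pretrained backbones can be plugged in through a registry.
5. **Evaluation** — closed-set identification accuracy CC/(CC+WC);
   one-against-all verification with accuracy, sensitivity, specificity,
   FPR, FNR, the ROC curve, and the equal error rate (EER).

A seeded synthetic-ECG generator (five Gaussian waves per beat, per-subject
morphology, jittered RR intervals, baseline/mains/white noise, exact
ground-truth R-peaks) makes every stage testable without clinical data.

## Worked example

```python
from morsebeat.config import PipelineConfig
from morsebeat.pipeline import run_synthetic_pipeline

report = run_synthetic_pipeline(PipelineConfig(n_subjects=5,
                                               beats_per_subject=60, seed=1))
print(report.n_beats, report.identification.test_accuracy)
```

Running `python examples/03_identify_cohort.py` (the same experiment,
with the training curve) prints:

```
beats in the balanced dataset : 300
training / test split         : 135 / 150
  epoch  1: loss 1.607  train acc 0.659  val acc 0.733
  ...
  epoch 10: loss 0.711  train acc 1.000  val acc 1.000
test identification accuracy  : 1.000
```

300 beats (5 subjects × 60) are split 50:50 into training and test
halves; the training half is split again 90:10 for validation. The loss
falls across the 10 Adam epochs and the held-out half is classified
perfectly — at low noise the subjects' beat morphologies are fully
separable in scalogram space. `examples/` contains one script per
capability (detection, scalograms, identification, verification, file
formats); `morsebeat --help` exposes the same stages as CLI subcommands
(`simulate`, `preprocess`, `scalogram`, `train`, `evaluate`, `pipeline`).

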