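# Methods

This note records the models, parameter choices and numerical decisions
behind `morsebeat`, and what the synthetic experiments do and do not
demonstrate.

## Preprocessing

Raw single-lead ECG is cleaned by two uniform moving averages, both
denominated in **samples** (the defaults assume 1000 Hz):

- **Baseline removal** (width 500): a 500-sample moving average is a
  low-pass estimate of the baseline wander (respiration, electrode
  movement, < ~1 Hz); the record minus this estimate is the corrected
  signal. Subtraction — not plain filtering — is what removes the
  low-frequency component: at 0.3 Hz the 500-sample average passes
  ≈ 96% of the drift, so the residual after subtraction is ≈ 4%.
- **Smoothing** (width 10): a 10-sample average has a spectral null at
  exactly fs/10 (100 Hz at 1 kHz) and strong attenuation across the
  50–60 Hz mains band.
- **Edge trim** (600 samples per side) discards the reflect-padded
  filter transients. Widths and trim are config keys so other sampling
  rates can rescale them explicitly.

**R-peak detection** uses Pan–Tompkins-style stages on the absolute
amplitude (so inverted leads still work): five-point derivative,
squaring, 150 ms moving-window integration, then a running signal/noise
two-level threshold (exponential updates, factor 0.125) with a 0.25 s
refractory period. Each accepted detection is relocalized to the
maximum absolute amplitude within ±100 ms, which compensates the
integrator group delay. Beats are **centered** windows [r−392, r+392)
of 784 samples; windows crossing a record boundary are dropped. The
window length is a config key; the centering is symmetric because no
asymmetric convention is forced by the data.

## Generalized Morse wavelet and CWT

The wavelet family is defined in the frequency domain,
Ψ(ω) = U(ω)·a·ω^β·e^(−ω^γ), parameterized by the symmetry γ (default 3,
the zero-skew / minimum-Heisenberg-area member) and the time–bandwidth
product P² = βγ (default 60, hence β = 20). The normalization
a = 2(eγ/β)^(β/γ) sets the peak response to exactly 2 — the standard
convention for analytic wavelets, under which a unit real sinusoid
yields unit-modulus coefficients at the matching scale. The peak sits
at ω* = (β/γ)^(1/γ), the closed-form argmax used for frequency
labeling.

Scales are geometric with 12 voices per octave. The range is chosen by
two rules: the smallest scale is where the dilated filter's response at
Nyquist falls to 1e-8 of its peak (no passband aliasing); the largest
keeps the wavelet's time-domain standard deviation — computed by
Parseval quadrature of |Ψ′|²/|Ψ|² — below a quarter of the signal
length (boundary-effect guard). For 784-sample beats this yields 72
scales spanning ≈ 5.9 octaves.

The transform is computed in the frequency domain: the beat is
reflect-extended by its own length on each side, zero-padded to the
next power of two, and each scale's row is the inverse FFT of
(spectrum × Ψ(sω)), i.e. the L1-normalized dilation ψ((t−b)/s)/s. One
coefficient per input sample is kept (no time decimation). A
`boundary="periodic"` mode skips the extension and is exactly covariant
under circular shifts. The test suite checks the FFT route against an
independent brute-force oracle (wavelet by direct quadrature of the
inverse Fourier integral, correlation by explicit summation); agreement
is ≈ 1e-9 relative, far inside the 1e-6 bound asserted.

Note that the sampling rate only labels the frequency axis; the
coefficient matrix of a given sample sequence is rate-independent, so
axis labeling at 128 Hz versus 1000 Hz changes no pixels downstream.

## Image rendering

Magnitudes are min–max normalized per beat (constant matrices map to
zero), mapped through a 64-entry jet-like lookup table (closed-form
blue→cyan→yellow→red ramps, linear interpolation between entries;
grayscale replication available), and resized by corner-aligned
bilinear interpolation. Magnitude is mapped **linearly** by default —
log compression is offered as a config flag but off, since the dynamic
range of a single beat's scalogram is modest. The min–max step makes
the image invariant to the beat's amplitude gain, which is desirable
for a biometric (electrode gain varies between sessions). Low scale
(high frequency) is the top image row by default.

## Classifier

The small CNN is: input 28×28×3 → conv 3×3×8 (pad 1) → ReLU → maxpool
2/2 → conv 3×3×16 (pad 1) → ReLU → maxpool 2/2 → conv 3×3×32 (pad 1) →
ReLU → fully connected → softmax, with categorical cross-entropy loss
and Glorot-uniform initialization. ReLU after each convolution is
adopted; without a nonlinearity the stack would collapse to a linear
map. The implementation is pure numpy (im2col convolutions, exact
backprop — verified against numerical gradients), single-threaded and
bit-reproducible given a seed.

Optimizers: SGDM (momentum 0.9), RMSProp (squared-gradient decay 0.9,
ε = 1e-8), Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) — the conventional
defaults, since only the initial learning rate (1e-4) is pinned by the
protocol. The final fully connected layer's weight and bias learning
rates are scaled by a multiplier (default 10 in the pipeline config, a
standard fine-tuning knob; 0 freezes the layer bitwise). Large
pretrained backbones (AlexNet/GoogLeNet/ResNet-class) are *not*
re-implemented; they enter only through a registry of adapters exposing
the same forward/backward interface, and all shipped experiments run on
the small CNN.

Splits are stratified per class with a floor-then-remainder rule and a
seeded shuffle: the dataset is divided 50:50 into training and test
halves, and the training half again 90:10 into training and validation
parts.

## Evaluation protocols

Identification is closed-set: accuracy = CC/(CC+WC) on the held-out
half. Verification is one-against-all: the enrolled subject's beats are
the positives and one beat from each of the same number of other
subjects (first beat per subject, deterministic) the negatives; the
balanced set is split 50:50 stratified, a two-class model is trained on
one half, and metrics are reported on the other. Decisions use the
strictly-greater rule (score ties count as rejections). The ROC is
computed over all decision thresholds (scikit-learn, no intermediate
dropping) and the EER by linear interpolation between the adjacent ROC
points straddling the FPR = FNR diagonal — standard biometric practice;
the EER is invariant under monotone rescaling of the scores.

At desk scale the verification cohort is 21 subjects × 20 beats, which
leaves a 20-item training half; there the trainer uses per-sample
updates (minibatch 1), because with ~2 updates per epoch the softmax
threshold stays uncalibrated even when the score ranking is already
perfect (EER 0).

## Synthetic data: what it does and does not show

Each subject is five Gaussian waves (P, Q, R, S, T) with amplitudes,
offsets and widths drawn once per subject from physiological lead-I
ranges (R: 0.8–1.5 mV, σ 8–14 ms; Q/S negative; T broad and late; mean
RR 0.75–1.10 s, jitter σ 30 ms; R strictly dominant by construction).
Beats are placed at jittered RR intervals (first R at RR/2), and three
noise terms are added: baseline wander 0.1 mV at 0.3 Hz, mains 0.05 mV
at 60 Hz, and white noise (default σ 0.02 mV; the 10 dB detector
experiments set σ from the closed-form beat-train power). Defaults are
1000 Hz sampling and balanced cohorts (exactly N beats per subject).

The Gaussian-sum model was chosen over a dynamical-system ECG simulator
because its expected values are closed-form, making oracle tests exact.
It deliberately does **not** model: pathological morphologies, ectopic
beats, respiration-modulated RR dynamics, electrode motion artifacts,
or session-to-session drift. Passing tests therefore demonstrate the
pipeline's correctness and its behavior under stationary noise — not
clinical-grade identification rates; real inter-subject variability is
both richer (harder) and more structured (easier for deep models) than
the simulator's.

Problem sizes for the shipped experiments — 5 subjects × 60 beats for
identification, 21 × 20 for verification, 60-beat records for detector
scoring — were chosen so a full run completes in seconds on one CPU
core while every protocol element (balanced cohorts, 50:50 split,
one-against-all construction) is exercised at full fidelity.

## Numerical details and degenerate inputs

- Moving averages use reflect padding (output length = input length);
  a constant signal is an exact fixed point.
- Ψ is evaluated in log space (`exp(β log ω − ω^γ)`) to avoid overflow
  at large β; Ψ(ω ≤ 0) is exactly 0.
- Min–max normalization of a constant scalogram returns all zeros.
- Tied maxima in a pooling window split the gradient evenly; argmax
  label ties resolve to the lowest index.
- An all-zero or too-short record yields an empty peak list, not an
  error; non-finite samples raise.
- `epochs = 0` returns the initialized model untouched; identical
  config + seed reproduces images, curves and reports byte for byte on
  one thread.

## Known limitations

- The detector's adaptive threshold is tuned for adult resting rhythms;
  sustained tachycardia beyond ~240 bpm violates the refractory
  assumption.
- The wavelet scale range assumes beats of a few hundred to a few
  thousand samples; very short signals (< 4 samples per octave of
  span) are rejected rather than analyzed.
- The numpy CNN is CPU-bound and meant for desk-scale cohorts
  (hundreds of images); large-scale training belongs in an external
  backbone plugged in through the adapter registry.
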