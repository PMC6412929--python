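"""Generalized Morse wavelets, scale grids, CWT and scalograms.

The generalized Morse family is defined directly in the frequency domain:

    Psi_{beta,gamma}(omega) = U(omega) * a_{beta,gamma} * omega**beta
                              * exp(-omega**gamma)

where ``U`` is the unit step (the wavelet is analytic: zero response for
non-positive frequencies), ``beta`` controls decay/compactness and
``gamma`` the symmetry of the envelope. Practitioners often parameterize
the family by the time-bandwidth product ``P^2 = beta * gamma`` instead
of ``beta``; ``gamma = 3`` gives a zero-skewness (Airy) wavelet and is
the default here together with ``P^2 = 60``. The normalization constant
``a_{beta,gamma} = 2 * (e*gamma/beta)**(beta/gamma)`` sets the peak of
the frequency response to exactly 2, the usual convention for analytic
wavelets (a real sinusoid then yields unit-modulus coefficients at the
matching scale).

The transform is evaluated in the frequency domain: the signal is
reflect-extended, zero-padded to a power of two, and each scale's
coefficients are the inverse FFT of (signal spectrum x dilated wavelet
filter). Scales are geometric with a fixed number of voices per octave.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

#: Relative filter magnitude allowed at the Nyquist frequency for the
#: smallest scale (guards against aliasing of the wavelet passband).
NYQUIST_TAIL = 1e-8


def beta_from_tbp(tbp: float, gamma: float) -> float:
    """Decay parameter ``beta`` from the time-bandwidth product ``P^2``.

    ``P^2 = beta * gamma``, hence ``beta = P^2 / gamma``.
    """
    if not (tbp > 0):
        raise ValueError(f"time-bandwidth product must be > 0, got {tbp}")
    if not (gamma > 0):
        raise ValueError(f"gamma must be > 0, got {gamma}")
    return tbp / gamma


@dataclass(frozen=True)
class MorseParams:
    """Generalized Morse wavelet parameterization.

    Attributes
    ----------
    gamma
        Symmetry parameter (> 0). ``gamma = 3`` minimizes the Heisenberg
        area and gives zero demodulated skewness.
    tbp
        Time-bandwidth product ``P^2 = beta * gamma`` (> 0).
    voices_per_octave
        Number of geometrically spaced scales per octave (>= 1).
    """

    gamma: float = 3.0
    tbp: float = 60.0
    voices_per_octave: int = 12

    def __post_init__(self) -> None:
        if not (self.gamma > 0):
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not (self.tbp > 0):
            raise ValueError(f"tbp must be > 0, got {self.tbp}")
        if self.voices_per_octave < 1:
            raise ValueError("voices_per_octave must be >= 1")

    @property
    def beta(self) -> float:
        """Decay/compactness parameter, ``P^2 / gamma``."""
        return beta_from_tbp(self.tbp, self.gamma)

    @property
    def norm_constant(self) -> float:
        """Peak normalization ``a = 2 (e*gamma/beta)**(beta/gamma)``."""
        b, g = self.beta, self.gamma
        return 2.0 * (np.e * g / b) ** (b / g)


def morse_psi_hat(omega, params: MorseParams):
    """Frequency response of the Morse wavelet at angular frequency omega.

    ``omega`` is in rad/sample; scalar or array. Exactly zero for
    ``omega <= 0`` (analyticity); strictly positive, unimodal otherwise.
    """
    omega = np.asarray(omega, dtype=np.float64)
    b, g, a = params.beta, params.gamma, params.norm_constant
    out = np.zeros_like(omega)
    pos = omega > 0
    # evaluate in log space to avoid overflow of omega**beta for large beta
    w = omega[pos]
    out[pos] = a * np.exp(b * np.log(w) - w ** g)
    return out if out.ndim else float(out)


def peak_frequency(params: MorseParams) -> float:
    """Angular frequency (rad/sample) maximizing the Morse response.

    Setting the derivative of ``beta*log(w) - w**gamma`` to zero gives
    the closed form ``(beta/gamma)**(1/gamma)``.
    """
    return (params.beta / params.gamma) ** (1.0 / params.gamma)


def morse_time_std(params: MorseParams) -> float:
    """Time-domain standard deviation of the mother wavelet, in samples.

    ``|psi(t)|`` is even (the frequency response is real), so the energy
    centroid sits at t = 0 and, by Parseval,

        sigma_t^2 = int |Psi'(w)|^2 dw / int |Psi(w)|^2 dw.

    Evaluated by trapezoidal quadrature on a dense grid covering the
    filter's support.
    """
    b, g = params.beta, params.gamma
    wp = peak_frequency(params)
    # upper limit: where the response falls below 1e-14 of its peak
    hi = brentq(lambda w: morse_psi_hat(w, params) - 1e-14 * 2.0,
                wp, wp * 50.0, xtol=1e-12)
    w = np.linspace(1e-12, hi, 40001)
    psi = morse_psi_hat(w, params)
    dpsi = psi * (b / w - g * w ** (g - 1.0))
    num = np.trapezoid(dpsi * dpsi, w)
    den = np.trapezoid(psi * psi, w)
    return float(np.sqrt(num / den))


@dataclass(frozen=True)
class ScaleGrid:
    """Geometric scale axis for the CWT of a fixed-length signal.

    ``scales`` are dimensionless dilation factors ``a`` (strictly
    increasing, constant ratio ``2**(1/voices_per_octave)``);
    ``center_frequencies`` are the corresponding wavelet peak frequencies
    in Hz at sampling rate ``fs``, strictly decreasing.
    """

    scales: np.ndarray
    center_frequencies: np.ndarray
    fs: float
    n_samples: int

    def __len__(self) -> int:
        return self.scales.size


def build_scale_grid(n_samples: int, fs: float,
                     params: MorseParams | None = None) -> ScaleGrid:
    """Build the voices-per-octave scale grid for a signal length.

    The smallest scale is the one at which the dilated filter's response
    at the Nyquist frequency has fallen to ``NYQUIST_TAIL`` of its peak
    (so essentially no passband energy aliases); the largest scale keeps
    the wavelet's time-domain standard deviation below ``n_samples / 4``
    (a boundary-effect guard). Scales between are geometric,
    ``s_j = s_min * 2**(j / voices_per_octave)``.
    """
    params = params or MorseParams()
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4")
    if not (fs > 0):
        raise ValueError(f"fs must be > 0, got {fs}")
    wp = peak_frequency(params)
    target = NYQUIST_TAIL * 2.0  # filter peak value is 2
    # Psi(s * pi) decreases in s for s > wp/pi; bracket and solve.
    s_lo = wp / np.pi
    s_hi = s_lo * 2.0
    while morse_psi_hat(s_hi * np.pi, params) > target:
        s_hi *= 2.0
    s_min = brentq(lambda s: morse_psi_hat(s * np.pi, params) - target,
                   s_lo, s_hi, xtol=1e-12)
    s_max = (n_samples / 4.0) / morse_time_std(params)
    if s_max <= s_min:
        raise ValueError(
            f"signal length {n_samples} too short for one scale at "
            f"P^2={params.tbp}, gamma={params.gamma}")
    v = params.voices_per_octave
    n_octaves = np.log2(s_max / s_min)
    n_scales = int(np.floor(v * n_octaves)) + 1
    scales = s_min * 2.0 ** (np.arange(n_scales) / v)
    freqs = wp / (2.0 * np.pi * scales) * fs
    return ScaleGrid(scales=scales, center_frequencies=freqs,
                     fs=float(fs), n_samples=int(n_samples))


def cwt(signal: np.ndarray, grid: ScaleGrid,
        params: MorseParams | None = None,
        boundary: str = "reflect") -> np.ndarray:
    """Continuous wavelet transform on the grid's scale axis.

    Returns a complex ``(n_scales, n_time)`` matrix, one coefficient per
    input sample (no time decimation). The signal is reflect-extended by
    its own length on each side, zero-padded to the next power of two,
    and each row is the inverse FFT of (spectrum x dilated filter) —
    the discretized wavelet correlation integral with the dilated filter
    applied in frequency (L1 dilation ``psi((t-b)/a) / a``). Negative
    frequencies carry zero response, so coefficients are analytic.

    ``boundary="periodic"`` skips the extension and analyzes the signal
    as one circular period; the transform is then exactly covariant
    under circular shifts of the input.
    """
    params = params or MorseParams()
    if boundary not in ("reflect", "periodic"):
        raise ValueError(f"unknown boundary {boundary!r}")
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    n = x.size
    if n != grid.n_samples:
        raise ValueError(
            f"grid was built for length {grid.n_samples}, signal has {n}")

    pad = n - 1 if (n > 1 and boundary == "reflect") else 0
    ext = np.pad(x, pad, mode="reflect") if pad else x
    nfft = (n if boundary == "periodic"
            else 1 << int(np.ceil(np.log2(ext.size))))
    spectrum = np.fft.fft(ext, nfft)
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft)

    coeffs = np.empty((len(grid), n), dtype=np.complex128)
    for j, s in enumerate(grid.scales):
        filt = morse_psi_hat(s * omega, params)
        row = np.fft.ifft(spectrum * filt)
        coeffs[j] = row[pad:pad + n]
    return coeffs


@dataclass
class Scalogram:
    """Magnitude of CWT coefficients on a scale x time lattice."""

    magnitude: np.ndarray
    scale_axis: ScaleGrid
    time_axis: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=np.float64)
        if self.time_axis is None:
            self.time_axis = np.arange(self.magnitude.shape[1])
        if np.any(self.magnitude < 0) or not np.all(np.isfinite(self.magnitude)):
            raise ValueError("scalogram entries must be finite and >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.magnitude.shape


def scalogram(coeffs: np.ndarray, grid: ScaleGrid) -> Scalogram:
    """Entrywise modulus of a CWT coefficient matrix."""
    coeffs = np.asarray(coeffs)
    if not np.all(np.isfinite(coeffs)):
        raise ValueError("coefficients must be finite")
    return Scalogram(magnitude=np.abs(coeffs), scale_axis=grid)


def beat_scalogram(samples: np.ndarray, fs: float,
                   params: MorseParams | None = None) -> Scalogram:
    """Scale grid + CWT + modulus for one beat, in a single call."""
    params = params or MorseParams()
    grid = build_scale_grid(len(samples), fs, params)
    return scalogram(cwt(samples, grid, params), grid)
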