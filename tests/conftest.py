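"""Shared fixtures and independent oracles for the test suite.

Oracles here deliberately avoid the implementation's code paths: the
time-domain CWT oracle evaluates the wavelet by direct quadrature of
the inverse Fourier integral and correlates by explicit summation, and
the ROC oracle enumerates every decision threshold.
"""

from __future__ import annotations

import numpy as np
import pytest

from morsebeat.config import PipelineConfig
from morsebeat.morse import MorseParams, morse_psi_hat
from morsebeat.pipeline import beats_to_images
from morsebeat.synthetic import NoiseSpec, synthesize_cohort


@pytest.fixture(scope="session")
def params() -> MorseParams:
    return MorseParams()


@pytest.fixture(scope="session")
def small_cohort():
    """4 subjects x 12 low-noise beats plus their templates."""
    segments, templates = synthesize_cohort(
        4, 12, noise=NoiseSpec(white_std=0.01), seed=7)
    return segments, templates


@pytest.fixture(scope="session")
def small_images(small_cohort):
    """Rendered 28x28 images and string labels for the small cohort."""
    segments, _ = small_cohort
    cfg = PipelineConfig(seed=7)
    return beats_to_images(segments, cfg)


# ---------------------------------------------------------------------------
# independent oracles


def time_domain_cwt(x: np.ndarray, scales: np.ndarray,
                    params: MorseParams) -> np.ndarray:
    """Brute-force CWT by explicit time-domain summation.

    The analyzed sequence is the same reflect-extended, zero-padded
    signal the FFT route uses, but the wavelet samples come from direct
    trapezoidal quadrature of ``psi(t) = (1/2pi) int Psi(w) e^{iwt} dw``
    and the correlation is a plain (non-circular) sum.
    """
    n = x.size
    pad = n - 1
    ext = np.pad(x, pad, mode="reflect")
    nfft = 1 << int(np.ceil(np.log2(ext.size)))
    extz = np.zeros(nfft)
    extz[:ext.size] = ext

    wgrid = np.linspace(1e-9, 8.0, 20001)
    psi_hat_vals = morse_psi_hat(wgrid, params)
    lags = np.arange(pad - nfft + 1, pad + n)
    tidx = np.arange(nfft)
    out = np.empty((scales.size, n), dtype=np.complex128)
    for j, a in enumerate(scales):
        tau = lags / a
        psi_tau = np.trapezoid(
            psi_hat_vals[None, :] * np.exp(1j * np.outer(tau, wgrid)),
            wgrid, axis=1) / (2.0 * np.pi)
        for b in range(n):
            d = (b + pad) - tidx
            out[j, b] = np.sum(extz * psi_tau[d - lags[0]]) / a
    return out


def brute_force_roc(scores: np.ndarray, labels: np.ndarray) -> set:
    """All achievable (FPR, TPR) points by exhaustive threshold sweep."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    uniq = np.unique(scores)
    thresholds = np.concatenate(
        [[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]])
    pts = set()
    pos, neg = labels.sum(), (~labels).sum()
    for t in thresholds:
        pred = scores > t
        tpr = np.sum(pred & labels) / pos
        fpr = np.sum(pred & ~labels) / neg
        pts.add((round(float(fpr), 12), round(float(tpr), 12)))
    return pts


def brute_force_eer(roc_points: np.ndarray) -> float:
    """EER by segment-diagonal intersection along the ROC polyline."""
    pts = np.asarray(sorted(map(tuple, roc_points)))
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        denom = (x1 - x0) + (y1 - y0)
        if denom == 0:
            continue
        s = (1.0 - x0 - y0) / denom
        if 0.0 <= s <= 1.0:
            x = x0 + s * (x1 - x0)
            if abs((y0 + s * (y1 - y0)) - (1.0 - x)) < 1e-9:
                return float(x)
    # no interior crossing: the endpoint closest to the diagonal
    d = np.abs(pts[:, 0] - (1.0 - pts[:, 1]))
    return float(pts[np.argmin(d), 0])


def match_peaks(detected: np.ndarray, truth: np.ndarray,
                tol: float) -> tuple[int, int, int]:
    """Greedy one-to-one matching within ``tol`` samples -> (tp, fp, fn)."""
    detected = np.asarray(detected, dtype=float)
    used = np.zeros(detected.size, dtype=bool)
    tp = 0
    for t in truth:
        if detected.size == 0:
            break
        dist = np.abs(detected - t)
        dist[used] = np.inf
        j = int(np.argmin(dist))
        if dist[j] <= tol:
            used[j] = True
            tp += 1
    return tp, int(detected.size - tp), int(truth.size - tp)
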