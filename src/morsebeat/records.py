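"""Core containers for single-lead ECG data.

Amplitudes are in millivolts with an arbitrary offset; sample indices are
zero-based positions at the record's sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Number of samples in a segmented heartbeat window.
DEFAULT_BEAT_LENGTH = 784


@dataclass
class EcgRecord:
    """A single-lead ECG sample sequence.

    Parameters
    ----------
    samples
        Amplitude sequence in mV (arbitrary offset). Must be finite and
        non-empty.
    fs
        Sampling rate in Hz, strictly positive.
    subject_id
        Opaque subject label ("" when unknown).
    lead
        Lead name; limb lead I by default, the only lead the pipeline uses.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    lead: str = "I"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite-valued")
        if not (self.fs > 0):
            raise ValueError(f"fs must be > 0, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    def replace_samples(self, samples: np.ndarray) -> "EcgRecord":
        """Return a copy of this record with a new sample sequence."""
        return EcgRecord(samples=samples, fs=self.fs,
                         subject_id=self.subject_id, lead=self.lead)


@dataclass
class BeatSegment:
    """A fixed-length heartbeat window centered on a detected R-peak.

    ``r_index`` is the R-peak position in the *source record*, not within
    the segment; the window spans ``[r - L//2, r - L//2 + L)`` samples of
    the source.
    """

    samples: np.ndarray
    r_index: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("beat samples must be 1-D")

    def __len__(self) -> int:
        return self.samples.size
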