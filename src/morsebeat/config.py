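"""Flat key-value pipeline configuration.

One documented key set covers every stage; unknown keys are rejected,
and each key defaults to the pipeline's standard value. Config files
are plain ``key = value`` lines (``#`` comments allowed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path


@dataclass
class PipelineConfig:
    # sampling / preprocessing (widths and trim are in samples)
    fs: float = 1000.0
    baseline_width: int = 500
    smooth_width: int = 10
    trim: int = 600
    beat_length: int = 784
    refractory_s: float = 0.25
    # wavelet
    gamma: float = 3.0
    tbp: float = 60.0
    voices_per_octave: int = 12
    # image rendering
    image_size: int = 28
    colormap: str = "jet"
    log_scale: bool = False
    high_freq_top: bool = True
    # training
    method: str = "adam"
    initial_lr: float = 1e-4
    minibatch: int = 10
    epochs: int = 10
    lr_multiplier: float = 10.0
    ratio: str = "90:10"
    train_fraction: float = 0.5
    backbone: str = "simple_cnn"
    transferred_units: str = "X"
    # synthetic cohort
    n_subjects: int = 5
    beats_per_subject: int = 60
    noise_baseline_amp: float = 0.1
    noise_baseline_freq: float = 0.3
    noise_mains_amp: float = 0.05
    noise_mains_freq: float = 60.0
    noise_white_std: float = 0.02
    # verification
    verification: bool = False
    positive_subject: str = ""
    samples_per_person: int = 60
    # bookkeeping
    seed: int = 0

    def __post_init__(self) -> None:
        a, _, b = self.ratio.partition(":")
        pa, pb = int(a), int(b)
        if pa <= 0 or pb <= 0 or pa + pb != 100:
            raise ValueError(
                f"ratio parts must be positive and sum to 100: {self.ratio}")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")

    @property
    def ratio_pair(self) -> tuple[int, int]:
        a, _, b = self.ratio.partition(":")
        return int(a), int(b)

    def to_dict(self) -> dict:
        return asdict(self)


_BOOL = {"true": True, "1": True, "yes": True,
         "false": False, "0": False, "no": False}


def _coerce(raw: str, target_type: type):
    if target_type is bool:
        try:
            return _BOOL[raw.lower()]
        except KeyError:
            raise ValueError(f"not a boolean: {raw!r}") from None
    return target_type(raw)


def load_config(path, overrides: dict | None = None) -> PipelineConfig:
    """Parse a ``key = value`` file; unknown keys raise, never pass
    silently."""
    known = {f.name: f.type for f in fields(PipelineConfig)}
    types = {f.name: type(getattr(PipelineConfig(), f.name))
             for f in fields(PipelineConfig)}
    values: dict = {}
    if path is not None:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            values[key] = _coerce(raw, types[key])
    for key, val in (overrides or {}).items():
        if key not in known:
            raise ValueError(f"unknown config key {key!r}")
        values[key] = val
    return PipelineConfig(**values)


def save_config(path, config: PipelineConfig) -> None:
    with Path(path).open("w") as fh:
        for key, val in config.to_dict().items():
            fh.write(f"{key} = {val}\n")
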