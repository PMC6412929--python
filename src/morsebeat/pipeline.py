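"""End-to-end orchestration: records -> beats -> scalogram images ->
classifier -> identification / verification reports.

The stages mirror the deployment flow of a scalogram-based ECG
biometric system: denoise and trim each recording, detect R-peaks, cut
centered beat windows, transform each beat with the Morse-wavelet CWT,
render the magnitudes as fixed-size RGB images, and train the small CNN
on a stratified split. Every stage is seeded; identical config + seed
reproduces byte-identical images, training curves and reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import cnn, metrics, morse, preprocess
from .config import PipelineConfig
from .imaging import render
from .records import BeatSegment, EcgRecord
from .synthetic import NoiseSpec, synthesize_cohort_recordings

log = logging.getLogger("morsebeat")


def preprocess_and_segment(records: list[EcgRecord],
                           config: PipelineConfig | None = None
                           ) -> list[BeatSegment]:
    """Cleaning chain + R-peak detection + beat segmentation per record."""
    config = config or PipelineConfig()
    segments: list[BeatSegment] = []
    for record in records:
        rec = preprocess.denoise(record,
                                 baseline_width=config.baseline_width,
                                 smooth_width=config.smooth_width,
                                 trim=config.trim)
        peaks = preprocess.detect_r_peaks(rec, refractory_s=config.refractory_s)
        segs = preprocess.segment_beats(rec, peaks,
                                        beat_length=config.beat_length)
        log.info("preprocess: subject=%s peaks=%d beats=%d "
                 "(baseline_width=%d smooth_width=%d trim=%d)",
                 record.subject_id, len(peaks), len(segs),
                 config.baseline_width, config.smooth_width, config.trim)
        segments.extend(segs)
    return segments


def balance_beats(segments: list[BeatSegment],
                  beats_per_subject: int) -> list[BeatSegment]:
    """Keep the first ``beats_per_subject`` beats of every subject,
    dropping subjects with fewer (the balanced-database rule)."""
    by_subject: dict[str, list[BeatSegment]] = {}
    for seg in segments:
        by_subject.setdefault(seg.subject_id, []).append(seg)
    out: list[BeatSegment] = []
    for subject in sorted(by_subject):
        beats = by_subject[subject]
        if len(beats) < beats_per_subject:
            log.warning("subject %s has %d < %d beats; dropped",
                        subject, len(beats), beats_per_subject)
            continue
        out.extend(beats[:beats_per_subject])
    return out


def beats_to_images(segments: list[BeatSegment],
                    config: PipelineConfig | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Morse CWT + rendering for every beat.

    Returns ``(images, labels)`` with images of shape (N, H, W, 3) in
    [0, 1] and labels the subject-id strings. The scale grid is built
    once and shared by all beats (they share length and rate).
    """
    config = config or PipelineConfig()
    params = morse.MorseParams(gamma=config.gamma, tbp=config.tbp,
                               voices_per_octave=config.voices_per_octave)
    grid = morse.build_scale_grid(config.beat_length, config.fs, params)
    size = (config.image_size, config.image_size)
    images, labels = [], []
    for seg in segments:
        coeffs = morse.cwt(seg.samples, grid, params)
        scalo = morse.scalogram(coeffs, grid)
        img = render(scalo, size=size, colormap=config.colormap,
                     log_scale=config.log_scale,
                     high_freq_top=config.high_freq_top,
                     subject_id=seg.subject_id, r_index=seg.r_index)
        images.append(img.pixels)
        labels.append(seg.subject_id)
    log.info("scalogram: %d beats -> %dx%d images (gamma=%g P^2=%g V=%d, "
             "%d scales)", len(segments), size[0], size[1], config.gamma,
             config.tbp, config.voices_per_octave, len(grid))
    return np.stack(images), np.asarray(labels)


def encode_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes, y = np.unique(labels, return_inverse=True)
    return y.astype(np.intp), classes


@dataclass
class IdentificationOutcome:
    """Held-out identification result plus training history."""

    result: metrics.IdentificationResult
    fit: cnn.FitResult
    n_train: int
    n_test: int

    @property
    def test_accuracy(self) -> float:
        return self.result.accuracy


def train_config_from(config: PipelineConfig) -> cnn.TrainConfig:
    return cnn.TrainConfig(method=config.method,
                           initial_lr=config.initial_lr,
                           minibatch=config.minibatch,
                           epochs=config.epochs,
                           last_layer_lr_multiplier=config.lr_multiplier,
                           train_val_ratio=config.ratio_pair,
                           seed=config.seed)


def run_identification(images: np.ndarray, labels: np.ndarray,
                       config: PipelineConfig | None = None
                       ) -> IdentificationOutcome:
    """Train/test split, train the classifier, score held-out beats.

    The dataset is split into training and test halves at
    ``train_fraction`` (stratified, seeded), the training half is split
    again at ``ratio`` into training and validation parts, the
    configured backbone is trained, and identification accuracy is the
    correct-classification fraction on the untouched test half.
    """
    config = config or PipelineConfig()
    y, classes = encode_labels(labels)
    pct = int(round(config.train_fraction * 100))
    train_idx, test_idx = cnn.split_train_validation(
        y, (pct, 100 - pct), seed=config.seed)
    tr_idx, val_idx = cnn.split_train_validation(
        y[train_idx], config.ratio_pair, seed=config.seed + 1)
    x_tr = images[train_idx][tr_idx]
    y_tr = y[train_idx][tr_idx]
    x_val = images[train_idx][val_idx]
    y_val = y[train_idx][val_idx]

    model = cnn.load_backbone(config.backbone, n_classes=len(classes),
                              seed=config.seed)
    tcfg = train_config_from(config)
    fit = cnn.train(model, x_tr, y_tr, tcfg, x_val, y_val)
    _, pred = cnn.predict(model, images[test_idx])
    cc = int(np.sum(pred == y[test_idx]))
    wc = int(test_idx.size - cc)
    fit.test_accuracy = cc / test_idx.size
    log.info("identify: %s %d classes, train=%d val=%d test=%d -> "
             "accuracy=%.4f", config.method, len(classes), len(tr_idx),
             len(val_idx), len(test_idx), fit.test_accuracy)
    return IdentificationOutcome(
        result=metrics.identification_accuracy(cc, wc), fit=fit,
        n_train=int(tr_idx.size), n_test=int(test_idx.size))


def run_verification(images: np.ndarray, labels: np.ndarray,
                     config: PipelineConfig | None = None
                     ) -> metrics.VerificationReport:
    """One-against-all verification for the configured positive subject.

    Builds the balanced binary dataset (positives: the enrolled
    subject's beats; negatives: one beat per other subject), splits it
    50:50 stratified, trains a two-class model on one half, and reports
    the Eqs.-style ratios, ROC and EER on the held-out half.
    """
    config = config or PipelineConfig()
    positive = config.positive_subject or str(np.unique(labels)[0])
    items, y = metrics.build_one_against_all(
        images, labels, positive,
        samples_per_person=config.samples_per_person)
    train_idx, test_idx = cnn.split_train_validation(y, (50, 50),
                                                     seed=config.seed)
    model = cnn.load_backbone(config.backbone, n_classes=2,
                              seed=config.seed)
    tcfg = train_config_from(config)
    cnn.train(model, items[train_idx], y[train_idx], tcfg)
    probs, _ = cnn.predict(model, items[test_idx])
    report = metrics.verification_report(probs[:, 1], y[test_idx])
    log.info("verify: subject=%s n_test=%d accuracy=%.4f eer=%.4f",
             positive, test_idx.size, report.accuracy, report.eer)
    return report


@dataclass
class PipelineReport:
    """What a full synthetic run produced."""

    config: PipelineConfig
    identification: IdentificationOutcome
    verification: metrics.VerificationReport | None = None
    n_beats: int = 0

    def summary_lines(self) -> list[str]:
        lines = [
            f"beats\t{self.n_beats}",
            f"train_size\t{self.identification.n_train}",
            f"test_size\t{self.identification.n_test}",
            f"identification_accuracy\t"
            f"{self.identification.test_accuracy:.6f}",
        ]
        if self.verification is not None:
            v = self.verification
            lines += [
                f"verification_accuracy\t{v.accuracy:.6f}",
                f"sensitivity\t{v.sensitivity:.6f}",
                f"specificity\t{v.specificity:.6f}",
                f"fpr\t{v.fpr:.6f}",
                f"fnr\t{v.fnr:.6f}",
                f"eer\t{v.eer:.6f}",
            ]
        return lines


def noise_from(config: PipelineConfig) -> NoiseSpec:
    return NoiseSpec(baseline_amp=config.noise_baseline_amp,
                     baseline_freq=config.noise_baseline_freq,
                     mains_amp=config.noise_mains_amp,
                     mains_freq=config.noise_mains_freq,
                     white_std=config.noise_white_std)


def run_synthetic_pipeline(config: PipelineConfig | None = None
                           ) -> PipelineReport:
    """Synthesize a cohort of raw recordings and run every stage."""
    config = config or PipelineConfig()
    records, _, _ = synthesize_cohort_recordings(
        config.n_subjects, config.beats_per_subject, fs=config.fs,
        noise=noise_from(config), seed=config.seed,
        beat_length=config.beat_length, trim_margin=config.trim)
    segments = preprocess_and_segment(records, config)
    segments = balance_beats(segments, _common_count(segments, config))
    images, labels = beats_to_images(segments, config)
    outcome = run_identification(images, labels, config)
    verification = None
    if config.verification:
        verification = run_verification(images, labels, config)
    return PipelineReport(config=config, identification=outcome,
                          verification=verification,
                          n_beats=len(segments))


def _common_count(segments: list[BeatSegment],
                  config: PipelineConfig) -> int:
    """Largest per-subject beat count shared by all subjects, capped at
    the configured target (balanced-database rule)."""
    counts: dict[str, int] = {}
    for seg in segments:
        counts[seg.subject_id] = counts.get(seg.subject_id, 0) + 1
    if not counts:
        raise ValueError("no beats were segmented")
    return min(min(counts.values()), config.beats_per_subject)
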