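"""Closed-set identification: who does this heartbeat belong to?

Runs the full pipeline on a synthetic 5-subject cohort (60 beats each):
raw recordings -> denoising -> R-peak detection -> beat windows ->
Morse scalogram images -> small CNN (Adam, learning rate 1e-4,
10 epochs) -> held-out identification accuracy.
"""

from morsebeat.config import PipelineConfig
from morsebeat.pipeline import run_synthetic_pipeline

config = PipelineConfig(n_subjects=5, beats_per_subject=60, seed=1)
report = run_synthetic_pipeline(config)

print(f"beats in the balanced dataset : {report.n_beats}")
print(f"training / test split         : "
      f"{report.identification.n_train} / {report.identification.n_test}")
for row in report.identification.fit.history:
    print(f"  epoch {row['epoch']:2d}: loss {row['loss']:.3f}  "
          f"train acc {row['train_acc']:.3f}  "
          f"val acc {row.get('val_acc', float('nan')):.3f}")
print(f"test identification accuracy  : "
      f"{report.identification.test_accuracy:.3f}")
# at the default low noise the subjects' stable beat morphology makes
# the held-out half fully separable (accuracy 1.000)
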