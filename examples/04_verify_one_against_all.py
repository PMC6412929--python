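"""One-against-all verification: is this heartbeat the enrolled person?

Builds the balanced verification set (the enrolled subject's beats are
the positives; one beat from each other subject the negatives), trains
a two-class model on half, and reports accuracy, sensitivity,
specificity, FPR, FNR and the equal error rate on the held-out half.
"""

from morsebeat.config import PipelineConfig
from morsebeat.pipeline import beats_to_images, run_verification
from morsebeat.synthetic import synthesize_cohort

segments, _ = synthesize_cohort(n_subjects=21, beats_per_subject=20, seed=2)
config = PipelineConfig(samples_per_person=20, minibatch=1, seed=2)
images, labels = beats_to_images(segments, config)
report = run_verification(images, labels, config)

print(f"verification accuracy : {report.accuracy:.3f}")
print(f"sensitivity           : {report.sensitivity:.3f}  "
      "(enrolled beats accepted)")
print(f"specificity           : {report.specificity:.3f}  "
      "(impostor beats rejected)")
print(f"FPR / FNR             : {report.fpr:.3f} / {report.fnr:.3f}")
print(f"equal error rate      : {report.eer:.3f}")
# EER 0.000 means the positive-class score ranks every enrolled beat
# above every impostor beat on the held-out half
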