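"""Reading and writing records, beats and PhysioNet-style files.

Round-trips a recording through the delimited-text format, a beat
dataset through the matrix + label-sidecar format, and a two-lead
record through the PhysioNet header + 16-bit signal layout with lead
selection by name.
"""

import tempfile
from pathlib import Path

import numpy as np

from morsebeat import io, segment_beats
from morsebeat.records import EcgRecord
from morsebeat.synthetic import sample_subject_template, synthesize_recording

workdir = Path(tempfile.mkdtemp())
template = sample_subject_template(seed=5, subject_id="S005")
record, truth = synthesize_recording(template, duration=15.0, seed=5)

io.write_record(workdir / "S005.txt", record)
back = io.read_record(workdir / "S005.txt")
print(f"text record round trip: {len(back)} samples at {back.fs:g} Hz, "
      f"exact={np.array_equal(back.samples, record.samples)}")

beats = segment_beats(record, truth)
io.write_beats(workdir / "beats.tsv", beats)
again = io.read_beats(workdir / "beats.tsv")
print(f"beat matrix round trip: {len(again)} beats x {len(again[0])} "
      f"samples, labels intact={all(b.subject_id == 'S005' for b in again)}")

# PhysioNet-style layout: quantized to 16-bit at gain 1000 per mV
lead1 = EcgRecord(np.round(record.samples * 1000) / 1000, fs=1000.0,
                  lead="I")
lead2 = EcgRecord(-lead1.samples / 2, fs=1000.0, lead="II")
io.write_wfdb_record(workdir / "rec01.hea", [lead1, lead2])
sel = io.read_wfdb_record(workdir / "rec01", lead="I")
print(f"waveform-database reader: picked lead {sel.lead!r} of 2, "
      f"exact={np.array_equal(sel.samples, lead1.samples)}")
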