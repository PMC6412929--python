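"""File formats: delimited-text records, beat matrices, scalograms,
ground-truth R-peak tables, and a minimal PhysioNet waveform reader.

The native record format is one sample per line with ``# key=value``
header comments (``fs`` required)::

    # fs=1000.0
    # subject_id=S000
    # lead=I
    0.0123
    -0.0042
    ...

Beat datasets are stored as a beats x L sample matrix (tab-delimited
text or an .npz container) with a sidecar label file, one
``subject_id<TAB>r_index`` line per beat.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .morse import MorseParams, Scalogram
from .records import BeatSegment, EcgRecord

# ---------------------------------------------------------------------------
# single-channel delimited text records


def write_record(path, record: EcgRecord) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={record.fs!r}\n")
        if record.subject_id:
            fh.write(f"# subject_id={record.subject_id}\n")
        fh.write(f"# lead={record.lead}\n")
        for v in record.samples:
            fh.write(f"{float(v)!r}\n")


def read_record(path) -> EcgRecord:
    path = Path(path)
    meta: dict[str, str] = {}
    samples: list[float] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
            else:
                samples.append(float(line))
    if "fs" not in meta:
        raise ValueError(f"{path}: missing required '# fs=<Hz>' header")
    return EcgRecord(samples=np.asarray(samples), fs=float(meta["fs"]),
                     subject_id=meta.get("subject_id", ""),
                     lead=meta.get("lead", "I"))


# ---------------------------------------------------------------------------
# beat datasets (matrix + label sidecar)


def _labels_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".labels")


def write_beats(path, segments: list[BeatSegment]) -> None:
    """Write a beat dataset; .npz paths get a binary container,
    anything else tab-delimited text. A sidecar ``<path>.labels`` file
    holds one ``subject_id<TAB>r_index`` line per row."""
    path = Path(path)
    matrix = np.vstack([seg.samples for seg in segments])
    if path.suffix == ".npz":
        np.savez(path, beats=matrix)
    else:
        np.savetxt(path, matrix, delimiter="\t")
    with _labels_path(path).open("w") as fh:
        for seg in segments:
            fh.write(f"{seg.subject_id}\t{seg.r_index}\n")


def read_beats(path) -> list[BeatSegment]:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as data:
            matrix = data["beats"]
    else:
        matrix = np.loadtxt(path, delimiter="\t", ndmin=2)
    labels: list[tuple[str, int]] = []
    with _labels_path(path).open() as fh:
        for line in fh:
            subject, _, r = line.rstrip("\n").partition("\t")
            labels.append((subject, int(r)))
    if len(labels) != matrix.shape[0]:
        raise ValueError("label sidecar does not match beat matrix rows")
    return [BeatSegment(samples=row, r_index=r, subject_id=subject)
            for row, (subject, r) in zip(matrix, labels)]


# ---------------------------------------------------------------------------
# ground-truth R-peak tables


def write_rpeaks(path, table: dict[str, np.ndarray]) -> None:
    """One ``subject_id<TAB>comma-separated-indices`` line per subject."""
    with Path(path).open("w") as fh:
        for subject, idx in table.items():
            fh.write(subject + "\t" +
                     ",".join(str(int(i)) for i in idx) + "\n")


def read_rpeaks(path) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            subject, _, idx = line.partition("\t")
            out[subject] = np.array(
                [int(v) for v in idx.split(",") if v], dtype=np.intp)
    return out


# ---------------------------------------------------------------------------
# scalogram export


def write_scalogram(path, scalo: Scalogram, params: MorseParams) -> None:
    """Magnitude matrix (.npz or delimited text) plus a key-value
    metadata sidecar ``<path>.meta`` with the wavelet parameterization
    and scale vector."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, magnitude=scalo.magnitude)
    else:
        np.savetxt(path, scalo.magnitude, delimiter="\t")
    grid = scalo.scale_axis
    with path.with_suffix(path.suffix + ".meta").open("w") as fh:
        fh.write(f"gamma={params.gamma!r}\n")
        fh.write(f"tbp={params.tbp!r}\n")
        fh.write(f"voices_per_octave={params.voices_per_octave}\n")
        fh.write(f"fs={grid.fs!r}\n")
        fh.write(f"n_samples={grid.n_samples}\n")
        fh.write("scales=" +
                 ",".join(repr(float(s)) for s in grid.scales) + "\n")


# ---------------------------------------------------------------------------
# minimal PhysioNet waveform-database reader (header + format-16 signal)


def read_wfdb_record(path, lead: str = "I") -> EcgRecord:
    """Read one lead of a PhysioNet-style record into physical units.

    ``path`` is the header file (or its stem); only the common layout is
    supported: a single format-16 signal file (little-endian 16-bit
    samples interleaved across signals), per-signal gain/baseline, and
    the lead name in the description field. Raises a ``KeyError`` naming
    the available leads when the requested one is absent.
    """
    header = Path(path)
    if header.suffix != ".hea":
        header = header.with_suffix(".hea")
    lines = [ln.strip() for ln in header.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    first = lines[0].split()
    n_sig = int(first[1])
    fs = float(first[2].split("/")[0]) if len(first) > 2 else 250.0
    n_samples = int(first[3]) if len(first) > 3 else 0

    signals = []
    for ln in lines[1:1 + n_sig]:
        tok = ln.split()
        fname, fmt = tok[0], tok[1]
        if fmt.split("x")[0].split(":")[0].split("+")[0] != "16":
            raise ValueError(f"unsupported signal format {fmt!r}; "
                             "only format 16 is handled")
        gain_tok = tok[2] if len(tok) > 2 else "200"
        gain_part = gain_tok.split("/")[0]
        if "(" in gain_part:
            gain_str, base_str = gain_part.rstrip(")").split("(")
            baseline = int(base_str)
        else:
            gain_str = gain_part
            baseline = int(tok[4]) if len(tok) > 4 else 0  # adc zero
        gain = float(gain_str) or 200.0
        description = tok[8] if len(tok) > 8 else f"sig{len(signals)}"
        signals.append({"file": fname, "gain": gain,
                        "baseline": baseline, "desc": description})

    names = [s["desc"] for s in signals]
    matches = [i for i, s in enumerate(signals)
               if s["desc"].upper() == lead.upper()]
    if not matches:
        raise KeyError(
            f"lead {lead!r} not in record; available leads: {names}")
    k = matches[0]

    dat_path = header.parent / signals[k]["file"]
    raw = np.frombuffer(dat_path.read_bytes(), dtype="<i2")
    if n_samples:
        raw = raw[:n_samples * n_sig]
    digital = raw.reshape(-1, n_sig)[:, k].astype(np.float64)
    physical = (digital - signals[k]["baseline"]) / signals[k]["gain"]
    return EcgRecord(samples=physical, fs=fs,
                     subject_id=first[0], lead=signals[k]["desc"])


def write_wfdb_record(path, records: list[EcgRecord],
                      gain: float = 1000.0) -> None:
    """Write a multi-lead record in the header + format-16 layout.

    Mainly for fixtures and interchange; all leads must share length
    and sampling rate. Digital values are ``round(physical * gain)``.
    """
    header = Path(path)
    if header.suffix != ".hea":
        header = header.with_suffix(".hea")
    stem = header.stem
    n_sig = len(records)
    n = len(records[0])
    fs = records[0].fs
    if any(len(r) != n or r.fs != fs for r in records):
        raise ValueError("all leads must share length and sampling rate")
    dat_name = stem + ".dat"
    digital = np.column_stack(
        [np.round(r.samples * gain).astype(np.int64) for r in records])
    if np.any(np.abs(digital) > 32767):
        raise ValueError("samples overflow 16-bit range at this gain")
    lines = [f"{stem} {n_sig} {fs:g} {n}"]
    for rec in records:
        lines.append(f"{dat_name} 16 {gain:g}(0)/mV 16 0 0 0 0 {rec.lead}")
    header.write_text("\n".join(lines) + "\n")
    (header.parent / dat_name).write_bytes(
        digital.astype("<i2").tobytes())
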