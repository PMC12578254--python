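"""Readers and writers for the pipeline's interchange formats.

* EDF+ (16-bit, physical dimension uV, one annotations channel carrying the
  MI/baseline event intervals).  Writing is a minimal self-contained EDF+
  implementation; reading goes through :mod:`mne` with the subject/group
  metadata recovered from the EDF patient-identification field.
* A plain binary matrix (little-endian float64) with a JSON text sidecar
  holding rate, channel names, events and labels.
* Window sets as compressed columnar ``.npz`` archives.
* Feature tables as CSV (exact float round-trip via shortest-repr).
* Normalization statistics and class weights as JSON text.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import ClassWeights, EpochWindow, Event, NormStats, Recording

# ---------------------------------------------------------------------------
# EDF+
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _annotation_bytes(record: int, events: Sequence[Event], fs: float) -> bytes:
    """Time-stamped annotation list for one data record; all event TALs are
    emitted in record 0."""
    out = f"+{record}\x14\x14\x00".encode("ascii")
    if record == 0:
        for ev in events:
            onset, dur = ev.onset / fs, (ev.offset - ev.onset) / fs
            out += f"+{onset:g}\x15{dur:g}\x14{ev.kind}\x14\x00".encode("ascii")
    return out


def write_edf(rec: Recording, path) -> Path:
    """Write a recording as 16-bit EDF+C with an annotations channel.

    The subject id and group label are stored in the patient-identification
    field as ``sub-<id> group-<y>``; physical units are microvolts with a
    symmetric physical range covering the data.  Recordings whose length is
    not a whole number of seconds are zero-padded to the next full 1 s data
    record.
    """
    path = Path(path)
    fs = int(rec.fs)
    if fs != rec.fs:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch, n_samp = rec.data.shape
    n_rec = int(np.ceil(n_samp / fs))
    data = rec.data
    if n_rec * fs != n_samp:
        data = np.pad(data, ((0, 0), (0, n_rec * fs - n_samp)))

    ann_payload = [_annotation_bytes(r, rec.events, rec.fs) for r in range(n_rec)]
    ann_samples = max(16, int(np.ceil(max(len(b) for b in ann_payload) / 2)))

    pm = max(1, int(np.ceil(np.max(np.abs(data)) if data.size else 1.0)))
    scale = 32767.0 / pm
    digital = np.clip(np.round(data * scale), -32768, 32767).astype("<i2")

    ns = n_ch + 1
    header = b"".join([
        _edf_field(0, 8),
        _edf_field(f"sub-{rec.subject_id} group-{rec.y}", 80),
        _edf_field(f"rec-{rec.recording_id}", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (ns + 1), 8),
        _edf_field("EDF+C", 44),
        _edf_field(n_rec, 8),
        _edf_field(1, 8),
        _edf_field(ns, 4),
    ])
    labels = [ch for ch in rec.channel_names] + ["EDF Annotations"]
    per_signal = [
        [_edf_field(lb, 16) for lb in labels],
        [_edf_field("", 80)] * ns,
        [_edf_field("uV", 8)] * n_ch + [_edf_field("", 8)],
        [_edf_field(-pm, 8)] * n_ch + [_edf_field(-1, 8)],
        [_edf_field(pm, 8)] * n_ch + [_edf_field(1, 8)],
        [_edf_field(-32768, 8)] * ns,
        [_edf_field(32767, 8)] * ns,
        [_edf_field("", 80)] * ns,
        [_edf_field(fs, 8)] * n_ch + [_edf_field(ann_samples, 8)],
        [_edf_field("", 32)] * ns,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in per_signal:
            fh.writelines(group)
        for r in range(n_rec):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())
            fh.write(ann_payload[r].ljust(2 * ann_samples, b"\x00"))
    return path


def _parse_edf_patient_field(path) -> tuple[str, int]:
    with open(path, "rb") as fh:
        fh.seek(8)
        patient = fh.read(80).decode("ascii").strip()
    subject, y = "unknown", 0
    for token in patient.split():
        if token.startswith("sub-"):
            subject = token[4:]
        elif token.startswith("group-"):
            y = int(token[6:])
    return subject, y


def read_edf(path, event_kinds: tuple[str, ...] | None = None) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (amplitudes in uV).

    Annotations become events; ``event_kinds`` optionally filters which
    annotation descriptions are kept (by default all are retained, with
    downstream segmentation using only those of kind 'MI').
    """
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts for uV-dimensioned signals
    fs = float(raw.info["sfreq"])
    n = data.shape[1]
    events = []
    for onset, duration, desc in zip(raw.annotations.onset,
                                     raw.annotations.duration,
                                     raw.annotations.description):
        if event_kinds is not None and desc not in event_kinds:
            continue
        a = int(round(onset * fs))
        b = min(int(round((onset + duration) * fs)), n)
        if a < b:
            events.append(Event(a, b, str(desc)))
    subject, y = _parse_edf_patient_field(path)
    return Recording(data=data, fs=fs, channel_names=list(raw.ch_names),
                     events=events, subject_id=subject,
                     recording_id=path.stem, y=y)


# ---------------------------------------------------------------------------
# plain matrix + JSON sidecar
# ---------------------------------------------------------------------------

def write_raw_matrix(rec: Recording, prefix) -> tuple[Path, Path]:
    """Write ``<prefix>.dat`` (little-endian float64, channel-major) and
    ``<prefix>.json`` with all metadata; lossless round-trip."""
    prefix = Path(prefix)
    dat, meta = prefix.with_suffix(".dat"), prefix.with_suffix(".json")
    rec.data.astype("<f8").tofile(dat)
    meta.write_text(json.dumps({
        "dtype": "<f8",
        "n_channels": rec.data.shape[0],
        "n_samples": rec.data.shape[1],
        "fs": rec.fs,
        "channel_names": rec.channel_names,
        "events": [[ev.onset, ev.offset, ev.kind] for ev in rec.events],
        "subject_id": rec.subject_id,
        "recording_id": rec.recording_id,
        "y": rec.y,
    }, indent=1))
    return dat, meta


def read_raw_matrix(prefix) -> Recording:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    data = np.fromfile(prefix.with_suffix(".dat"), dtype=meta["dtype"])
    data = data.reshape(meta["n_channels"], meta["n_samples"])
    return Recording(
        data=data, fs=meta["fs"], channel_names=meta["channel_names"],
        events=[Event(a, b, k) for a, b, k in meta["events"]],
        subject_id=meta["subject_id"], recording_id=meta["recording_id"],
        y=meta["y"],
    )


# ---------------------------------------------------------------------------
# windows, feature tables, fitted statistics
# ---------------------------------------------------------------------------

def write_windows(windows: Sequence[EpochWindow], path) -> Path:
    """Columnar window archive: stacked data plus per-window metadata."""
    path = Path(path)
    np.savez_compressed(
        path,
        data=np.stack([w.data for w in windows]),
        subject=np.array([w.subject_id for w in windows]),
        recording=np.array([w.recording_id for w in windows]),
        label=np.array([w.y for w in windows], dtype=np.int64),
        window_index=np.array([w.window_index for w in windows], dtype=np.int64),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_windows(path) -> list[EpochWindow]:
    with np.load(path, allow_pickle=False) as z:
        return [
            EpochWindow(data=z["data"][i], subject_id=str(z["subject"][i]),
                        recording_id=str(z["recording"][i]),
                        y=int(z["label"][i]), window_index=int(z["window_index"][i]))
            for i in range(len(z["label"]))
        ]


def write_feature_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip",
                     dtype={"subject": str, "recording": str, "qc_flags": str})
    return df


def write_norm_stats(stats: NormStats, weights: ClassWeights | None, path) -> Path:
    """Fitted statistics as JSON text (floats serialized at full precision)."""
    path = Path(path)
    payload = {
        "sd_floor": stats.sd_floor,
        "recordings": {
            rid: {"mean": stats.mean[rid].tolist(), "sd": stats.sd[rid].tolist()}
            for rid in sorted(stats.mean)
        },
        "fitted_on": sorted([list(uid) for uid in stats.fitted_on]),
    }
    if weights is not None:
        payload["class_weights"] = {"healthy": weights.healthy,
                                    "impaired": weights.impaired}
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_norm_stats(path) -> tuple[NormStats, ClassWeights | None]:
    payload = json.loads(Path(path).read_text())
    stats = NormStats(sd_floor=payload["sd_floor"])
    for rid, entry in payload["recordings"].items():
        stats.mean[rid] = np.array(entry["mean"])
        stats.sd[rid] = np.array(entry["sd"])
    stats.fitted_on = {(rid, idx) for rid, idx in payload["fitted_on"]}
    weights = None
    if "class_weights" in payload:
        cw = payload["class_weights"]
        weights = ClassWeights(healthy=cw["healthy"], impaired=cw["impaired"])
    return stats, weights
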