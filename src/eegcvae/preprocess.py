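"""Harmonized EEG preprocessing: montage restriction, filtering, resampling,
epoching, amplitude quality control, per-recording z-scoring, and class
balancing.

All recordings are reduced to a fixed 11-electrode sensorimotor montage and a
common 125 Hz sampling rate, band-pass filtered to 8-50 Hz with a zero-phase
fourth-order Butterworth design (plus a mains notch), and cut into
non-overlapping 1 s windows drawn only from motor-imagery (MI) event
intervals.  Normalization statistics are always estimated on the training
split of each recording and then applied to the held-out windows of the same
recording, so the pipeline is leakage-free by construction.

Conventions: sample indices are 0-based and event intervals are half-open
``[onset, offset)``; signal amplitudes are in microvolts until z-scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal

#: Canonical 11-channel montage shared by the two source datasets, in the
#: fixed order used everywhere downstream (channel-major feature stacking).
CANONICAL_MONTAGE: tuple[str, ...] = (
    "C3", "Cz", "C4", "FC3", "FCz", "FC4", "CP3", "CPz", "CP4", "F3", "F4",
)

#: Target sampling rate after harmonization (Hz). One epoch = 1 s = 125 samples.
TARGET_FS = 125

#: Amplitude rejection threshold in microvolts (strict inequality).
QC_THRESHOLD_UV = 100.0


@dataclass(frozen=True)
class Event:
    """Annotated interval ``[onset, offset)`` in samples; kind is 'MI' or 'baseline'."""

    onset: int
    offset: int
    kind: str


@dataclass
class Recording:
    """A continuous multichannel EEG recording with event annotations.

    ``data`` is channels x samples in microvolts. ``y`` is the subject-level
    group label: 0 = healthy, 1 = orthopedic impairment.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    events: list[Event]
    subject_id: str
    recording_id: str
    y: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")
        n = self.data.shape[1]
        for ev in self.events:
            if not (0 <= ev.onset < ev.offset <= n):
                raise ValueError(f"event {ev} outside recording of {n} samples")
        if self.y not in (0, 1):
            raise ValueError("group label y must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochWindow:
    """One 1 s epoch (11 x 125 at the target rate) with provenance metadata."""

    data: np.ndarray
    subject_id: str
    recording_id: str
    y: int
    window_index: int

    @property
    def uid(self) -> tuple[str, int]:
        return (self.recording_id, self.window_index)


@dataclass
class NormStats:
    """Per-recording, per-channel mean/sd fitted on training windows only."""

    mean: dict[str, np.ndarray] = field(default_factory=dict)
    sd: dict[str, np.ndarray] = field(default_factory=dict)
    fitted_on: set = field(default_factory=set)
    sd_floor: float = 1e-12


@dataclass(frozen=True)
class ClassWeights:
    """Inverse-frequency class weights w_c = N / (2 N_c)."""

    healthy: float
    impaired: float

    def as_array(self) -> np.ndarray:
        return np.array([self.healthy, self.impaired], dtype=np.float64)


def restrict_montage(rec: Recording) -> Recording:
    """Subset and reorder channels to the canonical 11-electrode montage.

    Matching is case-insensitive; a missing canonical channel is a hard error
    naming every absent electrode. No interpolation is performed.
    """
    lookup = {name.lower(): i for i, name in enumerate(rec.channel_names)}
    missing = [ch for ch in CANONICAL_MONTAGE if ch.lower() not in lookup]
    if missing:
        raise ValueError(f"recording {rec.recording_id} missing canonical channels: {missing}")
    order = [lookup[ch.lower()] for ch in CANONICAL_MONTAGE]
    return replace(rec, data=rec.data[order].copy(), channel_names=list(CANONICAL_MONTAGE))


def _mirror_pad(data: np.ndarray, pad: int) -> tuple[np.ndarray, int]:
    """Reflect-pad along time. If the signal is shorter than the requested pad,
    fall back to a full-signal mirror and warn."""
    n = data.shape[1]
    if pad >= n:
        warnings.warn(
            f"signal shorter than requested mirror pad ({n} < {pad} samples); "
            "padding with a full-signal mirror", stacklevel=3,
        )
        pad = n - 1
    return np.pad(data, ((0, 0), (pad, pad)), mode="reflect"), pad


def filter_signal(rec: Recording, mains: int = 50, pad_seconds: float = 3.0) -> Recording:
    """Notch at the mains frequency then band-pass 8-50 Hz, both zero-phase.

    The band-pass is a fourth-order Butterworth applied forward-backward
    (``filtfilt``), i.e. eighth-order in magnitude with exactly zero group
    delay.  The notch is a second-order IIR notch with quality factor Q=30,
    also applied zero-phase.  Signals are mirrored by ``pad_seconds`` at both
    ends before filtering to suppress edge transients, then cropped back.
    """
    if mains not in (50, 60):
        raise ValueError("mains must be 50 or 60 Hz")
    if rec.fs <= 100:
        raise ValueError("filter_signal requires fs > 100 Hz")
    pad = int(round(pad_seconds * rec.fs))
    padded, pad = _mirror_pad(rec.data, pad)
    b_n, a_n = signal.iirnotch(w0=mains, Q=30, fs=rec.fs)
    out = signal.filtfilt(b_n, a_n, padded, axis=1)
    sos = signal.butter(4, [8.0, 50.0], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, out, axis=1)
    out = out[:, pad:pad + rec.n_samples] if pad < rec.n_samples else out[:, pad:-pad]
    return replace(rec, data=np.ascontiguousarray(out))


def _scale_events(events: Sequence[Event], fs_in: float, fs_out: float, n_out: int) -> list[Event]:
    ratio = fs_out / fs_in
    scaled = []
    for ev in events:
        onset = int(round(ev.onset * ratio))
        offset = min(int(round(ev.offset * ratio)), n_out)
        if onset < offset:
            scaled.append(Event(onset, offset, ev.kind))
    return scaled


def resample_to_125(rec: Recording) -> Recording:
    """Resample to the common 125 Hz rate with zero-phase FIR anti-aliasing.

    500 Hz input is decimated by 4; 160 Hz input uses polyphase rational
    resampling by 25/32 with a Kaiser-windowed FIR; 125 Hz input is returned
    unchanged.  Other rates are handled by rational polyphase resampling with
    a warning.  Event sample indices are rescaled alongside the data.
    """
    fs_in = rec.fs
    if fs_in == TARGET_FS:
        return rec
    if fs_in == 500:
        out = signal.decimate(rec.data, 4, ftype="fir", axis=1, zero_phase=True)
    else:
        if fs_in != 160:
            warnings.warn(f"unusual input rate {fs_in} Hz; using rational polyphase resampling")
        frac = Fraction(TARGET_FS, int(fs_in)).limit_denominator(10000)
        out = signal.resample_poly(rec.data, frac.numerator, frac.denominator,
                                   axis=1, window=("kaiser", 5.0))
    events = _scale_events(rec.events, fs_in, TARGET_FS, out.shape[1])
    return replace(rec, data=np.ascontiguousarray(out), fs=float(TARGET_FS), events=events)


def segment_windows(rec: Recording) -> list[EpochWindow]:
    """Tile each MI interval with non-overlapping 1 s (125-sample) windows.

    Windows start at the interval onset and advance in steps of 125 samples;
    a trailing partial window is dropped, and baseline intervals produce no
    windows, so no window can straddle an event boundary.  A recording with
    no MI events yields an empty list.
    """
    if rec.fs != TARGET_FS:
        raise ValueError("segment_windows requires a 125 Hz recording")
    windows: list[EpochWindow] = []
    idx = 0
    for ev in rec.events:
        if ev.kind != "MI":
            continue
        start = ev.onset
        while start + TARGET_FS <= ev.offset:
            windows.append(EpochWindow(
                data=rec.data[:, start:start + TARGET_FS].copy(),
                subject_id=rec.subject_id,
                recording_id=rec.recording_id,
                y=rec.y,
                window_index=idx,
            ))
            idx += 1
            start += TARGET_FS
    return windows


def amplitude_qc(
    windows: Sequence[EpochWindow], threshold_uv: float = QC_THRESHOLD_UV
) -> tuple[list[EpochWindow], list[EpochWindow]]:
    """Drop windows containing any sample with |amplitude| strictly above the
    threshold (non-physiological excursion).  Returns (kept, dropped)."""
    kept, dropped = [], []
    for w in windows:
        if np.max(np.abs(w.data)) > threshold_uv:
            dropped.append(w)
        else:
            kept.append(w)
    return kept, dropped


def fit_norm_stats(training_windows: Sequence[EpochWindow], sd_floor: float = 1e-12) -> NormStats:
    """Estimate per-recording, per-channel mean and sd from training windows.

    Statistics pool all training windows of a recording; the per-channel sd
    is floored at ``sd_floor`` (a constant channel then z-scores to zero).
    """
    stats = NormStats(sd_floor=sd_floor)
    by_rec: dict[str, list[np.ndarray]] = {}
    for w in training_windows:
        by_rec.setdefault(w.recording_id, []).append(w.data)
        stats.fitted_on.add(w.uid)
    for rec_id, mats in by_rec.items():
        stacked = np.concatenate(mats, axis=1)
        mean = stacked.mean(axis=1)
        sd = stacked.std(axis=1, ddof=0)
        low = sd < sd_floor
        if np.any(low):
            warnings.warn(f"recording {rec_id}: {int(low.sum())} channel sd(s) floored")
            sd = np.where(low, sd_floor, sd)
        stats.mean[rec_id] = mean
        stats.sd[rec_id] = sd
    return stats


def apply_norm(windows: Sequence[EpochWindow], stats: NormStats) -> list[EpochWindow]:
    """z-score windows with the fitted per-recording statistics.

    A recording absent from the fit (no training windows) falls back to
    statistics computed from the windows being transformed, with a warning.
    """
    fallback: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    missing = sorted({w.recording_id for w in windows} - set(stats.mean))
    for rec_id in missing:
        warnings.warn(
            f"recording {rec_id} has no training windows; z-scoring with its own window statistics"
        )
        mats = np.concatenate([w.data for w in windows if w.recording_id == rec_id], axis=1)
        sd = mats.std(axis=1, ddof=0)
        fallback[rec_id] = (mats.mean(axis=1), np.maximum(sd, stats.sd_floor))
    out = []
    for w in windows:
        if w.recording_id in stats.mean:
            mean, sd = stats.mean[w.recording_id], stats.sd[w.recording_id]
        else:
            mean, sd = fallback[w.recording_id]
        zdata = (w.data - mean[:, None]) / sd[:, None]
        # channels whose sd was floored are (numerically) constant: define
        # their z-score as exactly zero rather than rounding-noise / floor
        zdata = np.where(sd[:, None] <= stats.sd_floor, 0.0, zdata)
        out.append(replace(w, data=zdata))
    return out


def class_weights(n_healthy: int, n_impaired: int) -> ClassWeights:
    """Inverse-frequency weights w_c = N / (2 N_c); both 1 for balanced classes."""
    n = n_healthy + n_impaired
    return ClassWeights(healthy=n / (2.0 * n_healthy), impaired=n / (2.0 * n_impaired))


def _downsample(group: list[EpochWindow], k: int, rng: np.random.Generator) -> list[EpochWindow]:
    """Seeded uniform subsample without replacement, keeping window order."""
    if k >= len(group):
        return list(group)
    ordered = sorted(group, key=lambda w: (w.recording_id, w.window_index))
    pick = np.sort(rng.choice(len(ordered), size=k, replace=False))
    return [ordered[i] for i in pick]


def balance_and_weight(
    windows: Sequence[EpochWindow],
    seed: int = 0,
    imbalance_tol: float = 0.05,
) -> tuple[list[EpochWindow], ClassWeights]:
    """Two-step window balancing across groups.

    (i) Within each class, every subject is undersampled (seeded, uniform,
    without replacement) to the class's minimum per-subject window count.
    (ii) If the residual class imbalance |N0-N1|/N is below ``imbalance_tol``
    the windows are kept and inverse-frequency weights w_c = N/(2 N_c) are
    attached; otherwise the larger class is additionally undersampled to
    equality (per-subject proportional, largest-remainder allocation) and the
    weights are then exactly 1.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[int, dict[str, list[EpochWindow]]] = {0: {}, 1: {}}
    for w in windows:
        by_class[w.y].setdefault(w.subject_id, []).append(w)
    if not by_class[0] or not by_class[1]:
        raise ValueError("balance_and_weight requires at least one window per class")

    balanced: dict[int, dict[str, list[EpochWindow]]] = {}
    for c, subjects in by_class.items():
        min_count = min(len(v) for v in subjects.values())
        balanced[c] = {
            s: _downsample(grp, min_count, rng) for s, grp in sorted(subjects.items())
        }

    n0 = sum(len(v) for v in balanced[0].values())
    n1 = sum(len(v) for v in balanced[1].values())
    if abs(n0 - n1) / (n0 + n1) >= imbalance_tol:
        big, small_n = (0, n1) if n0 > n1 else (1, n0)
        subjects = balanced[big]
        keys = sorted(subjects)
        sizes = np.array([len(subjects[s]) for s in keys], dtype=float)
        quota = sizes * small_n / sizes.sum()
        take = np.floor(quota).astype(int)
        rema = quota - take
        for i in np.argsort(-rema, kind="stable")[: small_n - int(take.sum())]:
            take[i] += 1
        balanced[big] = {
            s: _downsample(subjects[s], int(k), rng) for s, k in zip(keys, take)
        }
        n0 = sum(len(v) for v in balanced[0].values())
        n1 = sum(len(v) for v in balanced[1].values())

    out: list[EpochWindow] = []
    for c in (0, 1):
        for s in sorted(balanced[c]):
            out.extend(balanced[c][s])
    return out, class_weights(n0, n1)
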