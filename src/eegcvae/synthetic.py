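"""Synthetic EEG-like recordings and reference processes with known ground truth.

Two kinds of generators live here.  *Reference processes* (fractional
Gaussian noise, the logistic map, sinusoids, white and pink noise) have
analytically known long-range-dependence, entropy, dimension or Lyapunov
properties and serve as ground truth for the feature estimators.  The
*two-class recording generator* emulates the study's cohort structure --
11-channel motor-imagery EEG at 125/160/500 Hz with alternating MI/rest
blocks, class-dependent band power and Hurst structure, and occasional
high-amplitude artifacts -- so the full pipeline can be exercised without
any data download.

Everything is deterministic given the spec and seed: the same
``SyntheticSpec`` always yields byte-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import CANONICAL_MONTAGE, Event, Recording

_BANDS = {"alpha": (8.0, 13.0), "beta": (13.0, 30.0), "gamma": (30.0, 50.0)}


# ---------------------------------------------------------------------------
# reference processes
# ---------------------------------------------------------------------------

def fgn_autocovariance(H: float, lags: np.ndarray) -> np.ndarray:
    """Autocovariance of unit-variance fractional Gaussian noise,
    gamma(k) = (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}) / 2."""
    k = np.abs(lags).astype(np.float64)
    return 0.5 * (np.abs(k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H))


def gen_fgn(H: float, n: int, seed: int | None = None,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """Exact synthesis of fractional Gaussian noise by circulant embedding.

    The target autocovariance for lags 0..n-1 is embedded in a circulant
    matrix whose eigenvalues are obtained by FFT (Davies-Harte).  Negative
    eigenvalues from an indefinite embedding are clipped to zero, a
    deterministic fallback that perturbs the covariance only marginally.

    Parameters
    ----------
    H : Hurst parameter, strictly inside (0, 1). H = 0.5 gives iid Gaussian
        noise; H > 0.5 persistent, H < 0.5 anti-persistent increments.
    n : number of samples (>= 16).
    """
    if not 0.0 < H < 1.0:
        raise ValueError(f"Hurst parameter must lie in (0, 1), got {H}")
    if n < 16:
        raise ValueError("n must be >= 16")
    if rng is None:
        rng = np.random.default_rng(seed)
    m = 2 * (n - 1)
    gamma = fgn_autocovariance(H, np.arange(n))
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    lam = np.clip(lam, 0.0, None)
    half = m // 2
    re = rng.standard_normal(half + 1)
    im = rng.standard_normal(half + 1)
    w = np.zeros(m, dtype=np.complex128)
    w[0] = np.sqrt(lam[0] / m) * re[0]
    w[half] = np.sqrt(lam[half] / m) * re[half]
    inner = np.arange(1, half)
    w[inner] = np.sqrt(lam[inner] / (2 * m)) * (re[inner] + 1j * im[inner])
    w[m - inner] = np.conj(w[inner])
    return np.fft.fft(w).real[:n]


def gen_logistic_map(r: float, n: int, x0: float | None = None,
                     burn_in: int = 100, seed: int | None = None) -> np.ndarray:
    """Iterate x_{t+1} = r x_t (1 - x_t), discarding ``burn_in`` samples.

    Deterministic given ``x0``; the seed is used only to draw x0 when it is
    omitted.  At r = 4 the map is fully chaotic with Lyapunov exponent ln 2.
    """
    if not 0.0 < r <= 4.0:
        raise ValueError("logistic-map parameter r must lie in (0, 4]")
    if x0 is None:
        x0 = float(np.random.default_rng(seed).uniform(0.05, 0.95))
    if not 0.0 < x0 < 1.0:
        raise ValueError("x0 must lie in (0, 1)")
    out = np.empty(burn_in + n)
    x = x0
    for t in range(burn_in + n):
        x = r * x * (1.0 - x)
        out[t] = x
    return out[burn_in:]


def gen_sine(frequency: float, fs: float, n: int, amplitude: float = 1.0,
             phase: float = 0.0) -> np.ndarray:
    t = np.arange(n) / fs
    return amplitude * np.sin(2 * np.pi * frequency * t + phase)


def gen_white_noise(n: int, seed: int | None = None,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.standard_normal(n)


def gen_pink_noise(n: int, seed: int | None = None,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """1/f noise via spectral shaping of white noise, normalized to unit variance."""
    if rng is None:
        rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_reference(kind: str, length: int, seed: int | None = None, **params) -> np.ndarray:
    """Dispatch for named reference processes (fgn, logistic_map, sine,
    white_noise, pink_noise)."""
    if kind == "fgn":
        return gen_fgn(params["H"], length, seed=seed)
    if kind == "logistic_map":
        return gen_logistic_map(params.get("r", 4.0), length,
                                x0=params.get("x0"), burn_in=params.get("burn_in", 100),
                                seed=seed)
    if kind == "sine":
        return gen_sine(params.get("frequency", 10.0), params.get("fs", 125.0),
                        length, amplitude=params.get("amplitude", 1.0),
                        phase=params.get("phase", 0.0))
    if kind == "white_noise":
        return gen_white_noise(length, seed=seed)
    if kind == "pink_noise":
        return gen_pink_noise(length, seed=seed)
    raise ValueError(f"unknown reference process kind: {kind!r}")


# ---------------------------------------------------------------------------
# two-class EEG-like recordings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassEffect:
    """Class-1 deviations: per-band log-power shifts and a Hurst shift.

    A band shift of +d multiplies the band's amplitude by exp(d/2), i.e.
    shifts the window log band power by about +d; ``hurst`` is added to the
    Hurst parameter of the long-range-dependent signal component.
    """

    alpha: float = -0.4
    beta: float = -0.2
    gamma: float = 0.4
    hurst: float = 0.1

    def scaled(self, factor: float) -> "ClassEffect":
        return ClassEffect(self.alpha * factor, self.beta * factor,
                           self.gamma * factor, self.hurst * factor)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the two-class synthetic cohort.

    Defaults mirror the study conditions: 7 subjects per class, the fixed
    11-channel montage, and runs segmented into alternating 4 s MI / 2 s rest
    blocks.  ``n_runs_per_class`` allows asymmetric cohorts (the source
    cohorts contribute 24 min vs 8 min of MI data per subject).
    ``artifact_rate`` is the fraction of MI windows receiving a >100 uV
    single-channel excursion.
    """

    n_subjects_per_class: int = 7
    n_channels: int = 11
    fs: int = 125
    run_length: float = 120.0
    n_runs: int = 2
    n_runs_per_class: tuple[int, int] | None = None
    class_effect: ClassEffect = field(default_factory=ClassEffect)
    artifact_rate: float = 0.05
    mi_block: float = 4.0
    rest_block: float = 2.0
    base_hurst: float = 0.55
    seed: int = 0
    allow_nonstandard_channels: bool = False

    def __post_init__(self) -> None:
        if self.fs not in (125, 160, 500):
            raise ValueError("fs must be one of 125, 160, 500 Hz")
        if self.run_length <= 0:
            raise ValueError("run_length must be positive")
        if not 0.0 <= self.artifact_rate < 1.0:
            raise ValueError("artifact_rate must lie in [0, 1)")
        if self.n_channels != 11 and not self.allow_nonstandard_channels:
            raise ValueError("n_channels != 11 requires allow_nonstandard_channels=True")
        h1 = self.base_hurst + self.class_effect.hurst
        if not (0.0 < self.base_hurst < 1.0 and 0.0 < h1 < 1.0):
            raise ValueError("base and shifted Hurst parameters must lie in (0, 1)")

    def runs_for_class(self, c: int) -> int:
        if self.n_runs_per_class is not None:
            return self.n_runs_per_class[c]
        return self.n_runs


def _mi_events(n_samples: int, fs: int, mi_block: float, rest_block: float) -> list[Event]:
    """Alternating MI/rest block annotations covering the run. rest_block = 0
    produces a single MI interval spanning the whole run."""
    if rest_block <= 0:
        return [Event(0, n_samples, "MI")]
    mi_n, rest_n = int(round(mi_block * fs)), int(round(rest_block * fs))
    events, pos, is_mi = [], 0, True
    while pos < n_samples:
        span = mi_n if is_mi else rest_n
        end = min(pos + span, n_samples)
        events.append(Event(pos, end, "MI" if is_mi else "baseline"))
        pos, is_mi = end, not is_mi
    return events


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                lo: float, hi: float) -> np.ndarray:
    """Band-limited Gaussian noise (FFT mask), unit variance."""
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < lo) | (freqs >= hi)] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


# base rms amplitudes (uV) of the signal components; total stays well below
# the 100 uV QC threshold so only injected artifacts are rejected
_BAND_RMS = {"alpha": 5.0, "beta": 3.0, "gamma": 2.0}
_PINK_RMS = 3.0
_FGN_RMS = 3.0


def _synth_channel(rng: np.random.Generator, n: int, fs: float, y: int,
                   effect: ClassEffect, base_hurst: float) -> np.ndarray:
    """One channel: band-limited alpha/beta/gamma noise + 1/f background +
    a fractional-Gaussian-noise component carrying the Hurst structure."""
    shifts = {"alpha": effect.alpha, "beta": effect.beta, "gamma": effect.gamma}
    x = np.zeros(n)
    for band, (lo, hi) in _BANDS.items():
        amp = _BAND_RMS[band] * (np.exp(shifts[band] / 2.0) if y == 1 else 1.0)
        x += amp * _band_noise(rng, n, fs, lo, hi)
    x += _PINK_RMS * gen_pink_noise(n, rng=rng)
    H = base_hurst + (effect.hurst if y == 1 else 0.0)
    x += _FGN_RMS * gen_fgn(H, n, rng=rng)
    return x


def _inject_artifacts(rng: np.random.Generator, data: np.ndarray,
                      events: list[Event], fs: int, rate: float) -> None:
    """Give a fraction ``rate`` of MI windows a single-channel 150 uV burst.

    The burst is a 0.4 s square-envelope oscillation at 25 Hz (the passband
    center), centered inside the window so the excursion survives the 8-50 Hz
    band-pass and does not leak into neighboring windows.
    """
    if rate <= 0:
        return
    n_ch = data.shape[0]
    starts = []
    for ev in events:
        if ev.kind != "MI":
            continue
        s = ev.onset
        while s + fs <= ev.offset:
            starts.append(s)
            s += fs
    hit = rng.random(len(starts)) < rate
    dur = int(round(0.4 * fs))
    t = np.arange(dur) / fs
    burst = 150.0 * np.sin(2 * np.pi * 25.0 * t)
    for s, h in zip(starts, hit):
        if not h:
            continue
        ch = int(rng.integers(n_ch))
        off = s + int(round(0.3 * fs))
        data[ch, off:off + dur] += burst


def gen_two_class_recordings(spec: SyntheticSpec) -> list[Recording]:
    """Generate the full two-class synthetic cohort.

    Returns one ``Recording`` per (subject, run), with the canonical montage
    names, MI/rest event annotations, class-1 band-power and Hurst shifts,
    and artifact windows at the configured rate.  Identical specs yield
    byte-identical output.
    """
    root = np.random.SeedSequence(spec.seed)
    n = int(round(spec.run_length * spec.fs))
    names = list(CANONICAL_MONTAGE[: spec.n_channels])
    if spec.n_channels > len(CANONICAL_MONTAGE):
        names += [f"X{i}" for i in range(spec.n_channels - len(CANONICAL_MONTAGE))]
    recordings = []
    total_runs = sum(spec.runs_for_class(c) * spec.n_subjects_per_class for c in (0, 1))
    children = root.spawn(total_runs)
    child_idx = 0
    for c, prefix in ((0, "h"), (1, "i")):
        for subj in range(spec.n_subjects_per_class):
            subject_id = f"{prefix}{subj + 1:02d}"
            for run in range(spec.runs_for_class(c)):
                rng = np.random.default_rng(children[child_idx])
                child_idx += 1
                data = np.stack([
                    _synth_channel(rng, n, spec.fs, c, spec.class_effect, spec.base_hurst)
                    for _ in range(spec.n_channels)
                ])
                events = _mi_events(n, spec.fs, spec.mi_block, spec.rest_block)
                _inject_artifacts(rng, data, events, spec.fs, spec.artifact_rate)
                recordings.append(Recording(
                    data=data, fs=float(spec.fs), channel_names=list(names),
                    events=events, subject_id=subject_id,
                    recording_id=f"{subject_id}_r{run + 1:02d}", y=c,
                ))
    return recordings
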