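"""Per-window, per-channel EEG descriptors and 88-D feature assembly.

Six descriptors are computed on each z-scored 1 s window (125 samples at
125 Hz) for each of the 11 montage channels:

* STFT log band power in the alpha (8-13 Hz), beta (13-30 Hz) and gamma
  (30-50 Hz) rhythms (3 scalars),
* the rescaled-range Hurst exponent,
* the detrended-fluctuation-analysis scaling exponent,
* permutation (ordinal) entropy with m=3, tau=1 -- a finite-sample proxy for
  the Kolmogorov-Sinai entropy rate,
* the Grassberger-Procaccia correlation dimension with delay embedding
  (m, tau) = (6, 1) and Theiler window W = 6,
* the largest Lyapunov exponent by Rosenstein's nearest-neighbor divergence
  method with the same embedding.

Per channel the scalars are ordered (BP_a, BP_b, BP_g, H, a_DFA, KolmEn, CD,
LLE); stacking channel-major over the montage gives the 88-dimensional
feature vector.  Degenerate inputs (constant signals, perfectly linear
trends) yield neutral substitutes (H = a_DFA = 0.5, CD = LLE = 0) with a QC
flag so vectors stay rectangular.

All logarithms are natural.  Parameters are fixed a priori in
``FeatureConfig`` and never adapted to the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window
from scipy.spatial.distance import pdist, squareform

from .preprocess import EpochWindow

#: Descriptor groups in their fixed intra-channel order, with scalar names.
DESCRIPTOR_GROUPS: dict[str, tuple[str, ...]] = {
    "stft": ("bp_alpha", "bp_beta", "bp_gamma"),
    "hurst": ("hurst",),
    "dfa": ("dfa",),
    "kolmen": ("kolmen",),
    "cd": ("cd",),
    "lle": ("lle",),
}

ALL_GROUPS = tuple(DESCRIPTOR_GROUPS)


@dataclass(frozen=True)
class FeatureConfig:
    """Fixed estimator parameters (per 1 s window at 125 Hz).

    ``groups`` selects a descriptor subset for ablation runs; the default is
    the full six-descriptor bank (8 scalars/channel, 88 total).
    """

    fs: float = 125.0
    # STFT band power
    stft_nperseg: int = 64
    stft_hop: int = 16
    stft_nfft: int = 128
    stft_eps: float = 1e-8
    bands: tuple[tuple[str, float, float], ...] = (
        ("alpha", 8.0, 13.0), ("beta", 13.0, 30.0), ("gamma", 30.0, 50.0),
    )
    # rescaled range & DFA
    scales: tuple[int, ...] = (8, 16, 32, 64, 125)
    # permutation entropy
    pe_order: int = 3
    pe_delay: int = 1
    # state-space embedding (correlation dimension & Lyapunov)
    embed_dim: int = 6
    embed_delay: int = 1
    # Theiler window W = m * tau
    cd_n_radii: int = 20
    cd_percentiles: tuple[float, float] = (5.0, 95.0)
    cd_min_span: int = 5
    lle_t1: int = 3
    lle_t2: int = 25
    # separations larger than this fraction of the saturation (plateau)
    # separation are no longer "small" -- the Lyapunov fit stops there
    lle_saturation_frac: float = 0.1
    groups: tuple[str, ...] = ALL_GROUPS

    @property
    def theiler(self) -> int:
        return self.embed_dim * self.embed_delay

    def __post_init__(self) -> None:
        unknown = set(self.groups) - set(DESCRIPTOR_GROUPS)
        if unknown:
            raise ValueError(f"unknown descriptor groups: {sorted(unknown)}")

    @property
    def channel_feature_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for g in ALL_GROUPS:
            if g in self.groups:
                names.extend(DESCRIPTOR_GROUPS[g])
        return tuple(names)


@dataclass
class FeatureVector:
    """Channel-major feature values with per-scalar degeneracy flags."""

    values: np.ndarray
    qc_flags: np.ndarray
    names: list[str]


def _band_bins(cfg: FeatureConfig) -> dict[str, np.ndarray]:
    """DFT bins per band, f_k = k fs / Nfft; alpha/beta half-open, gamma
    closed at the 50 Hz upper edge (applied literally to bin frequencies)."""
    k = np.arange(cfg.stft_nfft // 2 + 1)
    fk = k * cfg.fs / cfg.stft_nfft
    out = {}
    for name, lo, hi in cfg.bands:
        if name == "gamma":
            out[name] = k[(fk >= lo) & (fk <= hi)]
        else:
            out[name] = k[(fk >= lo) & (fk < hi)]
    return out


def stft_band_power(x: np.ndarray, cfg: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Mean log band power over the STFT frames of one window.

    Frames of length 64 advance by the hop of 16 (75% overlap): a 125-sample
    window yields exactly M = floor((125-64)/16)+1 = 4 complete frames
    (incomplete trailing frames are not taken).  Each frame is Hann-tapered
    and zero-padded to a 128-point DFT; the band power is
    (1/M) sum_m sum_{k in B} log(|X(k,m)|^2 + eps) with eps = 1e-8 and no
    1/N spectral normalization (band powers are used comparatively).
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[-1]
    win = get_window("hann", cfg.stft_nperseg, fftbins=True)
    n_frames = (n - cfg.stft_nperseg) // cfg.stft_hop + 1
    offsets = np.arange(n_frames) * cfg.stft_hop
    frames = np.stack([x[o:o + cfg.stft_nperseg] for o in offsets])
    spec = np.fft.rfft(frames * win, n=cfg.stft_nfft, axis=1)
    power = np.abs(spec) ** 2
    bins = _band_bins(cfg)
    return np.array([
        np.log(power[:, bins[name]] + cfg.stft_eps).sum(axis=1).mean()
        for name, _, _ in cfg.bands
    ])


def _dominant_frequency(x: np.ndarray, fs: float) -> float:
    """Frequency of the periodogram maximum (DC excluded)."""
    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    if spec[1:].max() <= 0:
        return 0.0
    return float(freqs[1 + int(np.argmax(spec[1:]))])


def _ols_slope(logx: np.ndarray, logy: np.ndarray) -> float:
    slope, _ = np.polyfit(logx, logy, 1)
    return float(slope)


def hurst_rs(x: np.ndarray, cfg: FeatureConfig = FeatureConfig()) -> tuple[float, bool]:
    """Rescaled-range Hurst exponent over scales {8, 16, 32, 64, 125}.

    Segments of length s are placed at 50% overlap (stride s/2, trailing
    partial segments discarded) and demeaned; R is the range of the
    cumulative deviates and S the segment standard deviation (ddof=1).  The
    exponent is the OLS slope of log mean[R/S] against log s.  The shortest
    scale is omitted when fewer than two cycles of the window's dominant
    rhythm fit inside it.  Fewer than two usable scales flags the estimate
    degenerate and substitutes H = 0.5.
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    f_dom = _dominant_frequency(x, cfg.fs)
    scales = list(cfg.scales)
    if f_dom > 0 and scales and scales[0] < 2.0 * cfg.fs / f_dom:
        scales = scales[1:]
    log_s, log_rs = [], []
    for s in scales:
        if s > n:
            continue
        stride = max(1, s // 2)
        tiny = 1e-12 * max(1.0, float(np.abs(x).max()))
        stats = []
        for start in range(0, n - s + 1, stride):
            seg = x[start:start + s]
            d = seg - seg.mean()
            ssd = np.sqrt((d ** 2).sum() / (s - 1))
            if ssd <= tiny:  # numerically constant segment
                continue
            y = np.cumsum(d)
            stats.append((y.max() - y.min()) / ssd)
        if stats:
            m = float(np.mean(stats))
            if m > 0:
                log_s.append(np.log(s))
                log_rs.append(np.log(m))
    if len(log_s) < 2:
        return 0.5, True
    return _ols_slope(np.array(log_s), np.array(log_rs)), False


def dfa(x: np.ndarray, cfg: FeatureConfig = FeatureConfig()) -> tuple[float, bool]:
    """Detrended-fluctuation-analysis exponent over the same scale set.

    The integrated profile Y(k) = sum(x_t - mean) is cut into floor(N/s)
    non-overlapping forward segments; a least-squares line is removed from
    each, and F(s) is the root mean square residual over the covered samples.
    The exponent is the OLS slope of log F(s) vs log s over scales with
    F(s) > 0 (a perfectly linear signal detrends to zero everywhere and is
    flagged degenerate, substituting 0.5).
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    profile = np.cumsum(x - x.mean())
    log_s, log_f = [], []
    for s in cfg.scales:
        n_seg = n // s
        if n_seg < 1:
            continue
        segs = profile[: n_seg * s].reshape(n_seg, s)
        t = np.arange(s, dtype=np.float64)
        tc = t - t.mean()
        denom = (tc ** 2).sum()
        slopes = (segs * tc).sum(axis=1) / denom
        residues = segs - segs.mean(axis=1, keepdims=True) - slopes[:, None] * tc
        f = np.sqrt((residues ** 2).mean())
        if f > 1e-10:
            log_s.append(np.log(s))
            log_f.append(np.log(f))
    if len(log_s) < 2:
        return 0.5, True
    return _ols_slope(np.array(log_s), np.array(log_f)), False


def perm_entropy(x: np.ndarray, cfg: FeatureConfig = FeatureConfig()) -> float:
    """Permutation entropy, -sum p(pi) ln p(pi), without normalization.

    Ordinal patterns of length m = 3 at delay tau = 1 (123 patterns per
    125-sample window).  Ties are broken by stable ordering: the earlier
    index ranks lower, a deterministic convention that is measure-zero on
    continuous signals.
    """
    x = np.asarray(x, dtype=np.float64)
    m, tau = cfg.pe_order, cfg.pe_delay
    span = (m - 1) * tau
    if len(x) <= span:
        raise ValueError("window too short for the ordinal embedding")
    emb = sliding_window_view(x, span + 1)[:, ::tau]
    patterns = np.argsort(emb, axis=1, kind="stable")
    codes = patterns @ (m ** np.arange(m))
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    span = (m - 1) * tau
    return sliding_window_view(np.asarray(x, dtype=np.float64), span + 1)[:, ::tau]


def correlation_dimension(x: np.ndarray, cfg: FeatureConfig = FeatureConfig()) -> tuple[float, bool]:
    """Grassberger-Procaccia correlation dimension with Theiler exclusion.

    Pairs closer than W = 6 samples in time are excluded both from the
    correlation sum and from the radius percentiles.  20 log-spaced radii
    span the 5th-95th percentile of the retained pairwise distances; CD is
    the OLS slope of ln C(r) vs ln r over the contiguous span of at least 5
    radii maximizing R^2 (ties resolved toward the longer span).
    """
    pts = _embed(x, cfg.embed_dim, cfg.embed_delay)
    k = len(pts)
    d = squareform(pdist(pts))
    i, j = np.triu_indices(k, k=1)
    valid = (j - i) > cfg.theiler
    dists = d[i[valid], j[valid]]
    if dists.size == 0 or dists.max() <= 0:
        return 0.0, True
    r_lo, r_hi = np.percentile(dists, cfg.cd_percentiles)
    pos = dists[dists > 0]
    r_lo = max(r_lo, pos.min())
    if not r_hi > r_lo:
        return 0.0, True
    radii = np.exp(np.linspace(np.log(r_lo), np.log(r_hi), cfg.cd_n_radii))
    c = np.array([(dists < r).mean() for r in radii])
    keep = c > 0
    log_r, log_c = np.log(radii[keep]), np.log(c[keep])
    n = len(log_r)
    if n < cfg.cd_min_span:
        return 0.0, True
    return _best_r2_slope(log_r, log_c, cfg.cd_min_span), False


def lyapunov_rosenstein(x: np.ndarray, cfg: FeatureConfig = FeatureConfig()) -> tuple[float, bool]:
    """Largest Lyapunov exponent (per sample) by Rosenstein's method.

    Each embedded point is paired with its nearest neighbor at temporal
    separation > W; the mean log separation d(t) is tracked for t up to 25
    steps ahead, keeping only reference points whose full horizon fits inside
    the series.  The exponent is the OLS slope of d(t) on t in [3, 25]
    truncated before saturation: exponential divergence only holds while
    separations stay small relative to the attractor extent, so when the
    curve rises past 10% of its plateau separation the fit stops there
    (never fewer than 5 points).  Curves whose total rise is below that
    factor -- noise, limit cycles, typical EEG windows -- have no saturation
    regime to avoid and keep the full range.  Initial zero distances are
    floored at 1e-12; with no valid reference points the estimate is flagged
    degenerate and set to 0.
    """
    pts = _embed(x, cfg.embed_dim, cfg.embed_delay)
    k = len(pts)
    t1, t2 = cfg.lle_t1, cfg.lle_t2
    if k <= t2 + 1:
        return 0.0, True
    d = squareform(pdist(pts))
    if d.max() <= 0:  # constant signal: every embedded point coincides
        return 0.0, True
    ii, jj = np.indices((k, k))
    d[np.abs(ii - jj) <= cfg.theiler] = np.inf
    horizon = k - t2
    cand = d[:horizon, :horizon]
    if not np.isfinite(cand).any():
        return 0.0, True
    nn = np.argmin(cand, axis=1)
    refs = np.where(np.isfinite(cand[np.arange(horizon), nn]))[0]
    if refs.size == 0:
        return 0.0, True
    ts = np.arange(t2 + 1)
    dbar = np.empty(t2 + 1)
    for t in ts:
        sep = np.linalg.norm(pts[refs + t] - pts[nn[refs] + t], axis=1)
        dbar[t] = np.log(np.maximum(sep, 1e-12)).mean()
    fit_t = np.arange(t1, t2 + 1)
    fit_d = dbar[t1:t2 + 1]
    level = fit_d.max() + np.log(cfg.lle_saturation_frac)
    if fit_d[0] <= level:  # the curve spans more than the saturation factor
        above = np.nonzero(fit_d > level)[0]
        cut = int(above[0]) if above.size else len(fit_d)
        cut = max(cut, 5)
        fit_t, fit_d = fit_t[:cut], fit_d[:cut]
    slope, _ = np.polyfit(fit_t, fit_d, 1)
    return float(slope), False


def _best_r2_slope(xs: np.ndarray, ys: np.ndarray, min_span: int) -> float:
    """OLS slope over the contiguous subrange (>= min_span points) with the
    highest R^2; ties go to the longer, then earlier, span.  A perfectly flat
    subrange (zero y-variance) counts as R^2 = 0.

    All spans are scored at once from prefix sums (slope = Sxy/Sxx and
    R^2 = Sxy^2/(Sxx*Syy) on centered moments), so the search stays cheap.
    """
    n = len(xs)
    cx = np.concatenate([[0.0], np.cumsum(xs)])
    cy = np.concatenate([[0.0], np.cumsum(ys)])
    cxx = np.concatenate([[0.0], np.cumsum(xs * xs)])
    cyy = np.concatenate([[0.0], np.cumsum(ys * ys)])
    cxy = np.concatenate([[0.0], np.cumsum(xs * ys)])
    best = None
    for a in range(0, n - min_span + 1):
        b = np.arange(a + min_span, n + 1)
        m = (b - a).astype(float)
        sx, sy = cx[b] - cx[a], cy[b] - cy[a]
        sxx = (cxx[b] - cxx[a]) - sx * sx / m
        syy = (cyy[b] - cyy[a]) - sy * sy / m
        sxy = (cxy[b] - cxy[a]) - sx * sy / m
        slope = sxy / sxx
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(syy > 0, sxy * sxy / (sxx * syy), 0.0)
        for i in range(len(b)):
            key = (round(float(r2[i]), 12), int(b[i]) - a, -a)
            if best is None or key > best[0]:
                best = (key, float(slope[i]))
    return best[1]


def channel_features(x: np.ndarray, cfg: FeatureConfig = FeatureConfig()
                     ) -> tuple[np.ndarray, np.ndarray]:
    """All configured descriptors for a single channel; returns (values, flags)."""
    vals: list[float] = []
    flags: list[bool] = []
    if "stft" in cfg.groups:
        bp = stft_band_power(x, cfg)
        vals.extend(bp.tolist())
        flags.extend([False] * len(bp))
    if "hurst" in cfg.groups:
        v, f = hurst_rs(x, cfg)
        vals.append(v); flags.append(f)
    if "dfa" in cfg.groups:
        v, f = dfa(x, cfg)
        vals.append(v); flags.append(f)
    if "kolmen" in cfg.groups:
        vals.append(perm_entropy(x, cfg)); flags.append(False)
    if "cd" in cfg.groups:
        v, f = correlation_dimension(x, cfg)
        vals.append(v); flags.append(f)
    if "lle" in cfg.groups:
        v, f = lyapunov_rosenstein(x, cfg)
        vals.append(v); flags.append(f)
    return np.array(vals), np.array(flags, dtype=bool)


def assemble_features(window: EpochWindow, cfg: FeatureConfig = FeatureConfig()) -> FeatureVector:
    """Stack the per-channel scalars channel-major into one feature vector.

    With the full descriptor bank this is 11 channels x 8 scalars = 88
    values; configured subsets shrink the vector accordingly.  The window is
    expected to be z-scored already (training-split statistics).
    """
    values, flags, names = [], [], []
    per_ch = cfg.channel_feature_names
    for ci in range(window.data.shape[0]):
        v, f = channel_features(window.data[ci], cfg)
        values.append(v)
        flags.append(f)
        names.extend(f"ch{ci}_{nm}" for nm in per_ch)
    return FeatureVector(np.concatenate(values), np.concatenate(flags), names)


def feature_table(windows: Sequence[EpochWindow],
                  cfg: FeatureConfig = FeatureConfig()) -> pd.DataFrame:
    """Feature matrix with provenance columns; one row per window.

    Columns: subject, recording, label, window_index, the feature scalars in
    channel-major order, and ``qc_flags`` (semicolon-joined names of
    degenerate scalars, usually empty).  Written as CSV this round-trips
    exactly (shortest-repr floats).
    """
    rows = []
    names: list[str] | None = None
    for w in windows:
        fv = assemble_features(w, cfg)
        if names is None:
            names = fv.names
        rows.append({
            "subject": w.subject_id,
            "recording": w.recording_id,
            "label": w.y,
            "window_index": w.window_index,
            **dict(zip(fv.names, fv.values)),
            "qc_flags": ";".join(np.array(fv.names)[fv.qc_flags]),
        })
    return pd.DataFrame(rows)


def feature_columns(df: pd.DataFrame) -> list[str]:
    """Names of the feature scalar columns of a feature table."""
    meta = {"subject", "recording", "label", "window_index", "qc_flags"}
    return [c for c in df.columns if c not in meta]
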