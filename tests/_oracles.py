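"""Independent brute-force reference implementations used only by the tests.

Each oracle is written as plainly as possible (explicit loops, direct
formulas) and shares no code with the library, so agreement between the two
is evidence of correctness rather than of shared bugs.  Slope-based oracles
use the same scale/radius grids as the estimators under test.
"""

import math

import numpy as np


def band_power_oracle(x, fs=125.0, nperseg=64, hop=16, nfft=128, eps=1e-8):
    """Direct-DFT log band power: explicit frame loop, explicit DFT sums."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    n_frames = (n - nperseg) // hop + 1
    win = np.array([0.5 - 0.5 * math.cos(2 * math.pi * i / nperseg)
                    for i in range(nperseg)])
    bands = {"alpha": (8.0, 13.0, False), "beta": (13.0, 30.0, False),
             "gamma": (30.0, 50.0, True)}
    out = []
    for lo, hi, closed in bands.values():
        acc = 0.0
        for m in range(n_frames):
            frame = x[m * hop:m * hop + nperseg] * win
            for k in range(nfft // 2 + 1):
                fk = k * fs / nfft
                inside = (lo <= fk <= hi) if closed else (lo <= fk < hi)
                if not inside:
                    continue
                re = sum(frame[t] * math.cos(-2 * math.pi * k * t / nfft)
                         for t in range(nperseg))
                im = sum(frame[t] * math.sin(-2 * math.pi * k * t / nfft)
                         for t in range(nperseg))
                acc += math.log(re * re + im * im + eps)
        out.append(acc / n_frames)
    return np.array(out)


def rs_oracle(x, scales=(8, 16, 32, 64, 125), fs=125.0):
    """Classical rescaled-range estimate with the estimator's scale grid and
    shortest-scale omission rule, written with explicit loops."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    centered = x - x.mean()
    spec = np.abs(np.fft.rfft(centered)) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    f_dom = freqs[1 + int(np.argmax(spec[1:]))] if spec[1:].max() > 0 else 0.0
    use = list(scales)
    if f_dom > 0 and use[0] < 2.0 * fs / f_dom:
        use = use[1:]
    pts = []
    for s in use:
        if s > n:
            continue
        vals = []
        start = 0
        while start + s <= n:
            seg = x[start:start + s]
            d = seg - seg.mean()
            ssd = math.sqrt(sum(v * v for v in d) / (s - 1))
            if ssd > 0:
                cum, mx, mn = 0.0, -math.inf, math.inf
                for v in d:
                    cum += v
                    mx, mn = max(mx, cum), min(mn, cum)
                vals.append((mx - mn) / ssd)
            start += max(1, s // 2)
        if vals and sum(vals) > 0:
            pts.append((math.log(s), math.log(sum(vals) / len(vals))))
    if len(pts) < 2:
        return 0.5
    lx = [p[0] for p in pts]
    ly = [p[1] for p in pts]
    mx, my = sum(lx) / len(lx), sum(ly) / len(ly)
    return (sum((a - mx) * (b - my) for a, b in pts)
            / sum((a - mx) ** 2 for a in lx))


def dfa_oracle(x, scales=(8, 16, 32, 64, 125)):
    """DFA exponent via per-segment polyfit detrending of the profile."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    profile = np.cumsum(x - x.mean())
    pts = []
    for s in scales:
        n_seg = n // s
        if n_seg < 1:
            continue
        sq = 0.0
        for seg_i in range(n_seg):
            seg = profile[seg_i * s:(seg_i + 1) * s]
            t = np.arange(s)
            coef = np.polyfit(t, seg, 1)
            resid = seg - np.polyval(coef, t)
            sq += float(resid @ resid)
        f = math.sqrt(sq / (n_seg * s))
        if f > 1e-10:
            pts.append((math.log(s), math.log(f)))
    if len(pts) < 2:
        return 0.5
    lx = [p[0] for p in pts]
    ly = [p[1] for p in pts]
    mx, my = sum(lx) / len(lx), sum(ly) / len(ly)
    return (sum((a - mx) * (b - my) for a, b in pts)
            / sum((a - mx) ** 2 for a in lx))


def perm_entropy_oracle(x, m=3, tau=1):
    """Ordinal-pattern entropy by dictionary counting of rank tuples."""
    x = np.asarray(x, dtype=float)
    counts = {}
    for i in range(len(x) - (m - 1) * tau):
        window = [x[i + j * tau] for j in range(m)]
        pattern = tuple(sorted(range(m), key=lambda j: (window[j], j)))
        counts[pattern] = counts.get(pattern, 0) + 1
    total = sum(counts.values())
    return -sum((c / total) * math.log(c / total) for c in counts.values())


def correlation_sum_oracle(x, m=6, tau=1, theiler=6):
    """Theiler-excluded pairwise distances and the correlation sum C(r) on
    the estimator's radius grid; returns (radii, C)."""
    x = np.asarray(x, dtype=float)
    k = len(x) - (m - 1) * tau
    pts = [x[i:i + (m - 1) * tau + 1:tau] for i in range(k)]
    dists = []
    for i in range(k):
        for j in range(i + 1, k):
            if j - i > theiler:
                dists.append(math.dist(pts[i], pts[j]))
    dists = np.array(dists)
    r_lo, r_hi = np.percentile(dists, (5.0, 95.0))
    r_lo = max(r_lo, dists[dists > 0].min())
    radii = np.exp(np.linspace(math.log(r_lo), math.log(r_hi), 20))
    c = np.array([(dists < r).sum() / len(dists) for r in radii])
    return radii, c


def logistic_lyapunov_oracle(x_traj, r=4.0):
    """Analytic Lyapunov exponent of the logistic map as the mean log
    derivative |r(1 - 2x)| along the trajectory."""
    return float(np.mean(np.log(np.abs(r * (1.0 - 2.0 * np.asarray(x_traj))))))


def wilson_oracle(p, n, conf=0.95):
    """Wilson interval through statsmodels (independent of the library path)."""
    from statsmodels.stats.proportion import proportion_confint

    return proportion_confint(p * n, n, alpha=1 - conf, method="wilson")
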