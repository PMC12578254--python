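"""Splits, classification metrics, and analytic statistics.

Covers the evaluation protocol around the model: a stratified window-level
80/20 split preserving class and subject proportions (deliberately *not*
subject-exclusive, matching the study protocol and its documented
limitation), the standard confusion-matrix metrics with macro averaging,
Wilson score confidence intervals for accuracy, conservative unpaired
two-proportion z-tests between classifiers evaluated on identically sized
test sets, and a Pearson redundancy check across the six descriptor groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from .features import ALL_GROUPS, DESCRIPTOR_GROUPS


@dataclass
class SplitResult:
    train_idx: np.ndarray
    test_idx: np.ndarray
    train_frac: float
    seed: int


@dataclass
class MetricsReport:
    confusion: np.ndarray
    accuracy: float
    precision: float
    recall: float
    f1_macro: float
    per_class_f1: np.ndarray
    wilson_ci: tuple[float, float]
    n: int
    flags: list[str] = field(default_factory=list)
    z_tests: list[dict] = field(default_factory=list)

    def to_text(self) -> str:
        lines = [
            f"n = {self.n}",
            f"accuracy  = {self.accuracy:.6f}",
            f"precision = {self.precision:.6f} (macro)",
            f"recall    = {self.recall:.6f} (macro)",
            f"macro_f1  = {self.f1_macro:.6f}",
            f"wilson_95 = [{self.wilson_ci[0]:.3f}, {self.wilson_ci[1]:.3f}]",
            "confusion (rows = true, cols = predicted):",
            f"  {self.confusion[0, 0]:6d} {self.confusion[0, 1]:6d}",
            f"  {self.confusion[1, 0]:6d} {self.confusion[1, 1]:6d}",
        ]
        for zt in self.z_tests:
            lines.append(
                f"z-test vs {zt['comparator']}: p1={zt['p1']:.3f} p2={zt['p2']:.3f} "
                f"z={zt['z']:.3f} p={zt['p']:.3g}")
        if self.flags:
            lines.append("flags: " + "; ".join(self.flags))
        return "\n".join(lines)


def stratified_split(labels, subjects, frac: float = 0.8, seed: int = 0) -> SplitResult:
    """Window-level stratified split preserving class and subject proportions.

    Windows are grouped into (class, subject) cells; train counts are
    allocated proportionally with largest-remainder rounding (ties broken by
    cell label order) so the train total is exactly round(frac * N), and the
    split within each cell is a seeded shuffle.  Cells with fewer than two
    windows are an error (both sides of the split must be representable).
    """
    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    if len(labels) != len(subjects):
        raise ValueError("labels and subjects must have equal length")
    rng = np.random.default_rng(seed)
    cells: dict[tuple, np.ndarray] = {}
    for key in sorted(set(zip(labels.tolist(), subjects.tolist()))):
        idx = np.where((labels == key[0]) & (subjects == key[1]))[0]
        if len(idx) < 2:
            raise ValueError(f"cell (class={key[0]}, subject={key[1]}) has "
                             f"{len(idx)} window(s); need at least 2")
        cells[key] = idx
    n_total = len(labels)
    target_train = int(round(frac * n_total))
    keys = list(cells)
    sizes = np.array([len(cells[k]) for k in keys], dtype=float)
    quota = sizes * frac
    take = np.floor(quota).astype(int)
    remainder = quota - take
    short = target_train - int(take.sum())
    for i in np.argsort(-remainder, kind="stable")[:short]:
        take[i] += 1
    train_parts, test_parts = [], []
    for k, t in zip(keys, take):
        idx = cells[k].copy()
        rng.shuffle(idx)
        train_parts.append(idx[:t])
        test_parts.append(idx[t:])
    return SplitResult(
        train_idx=np.sort(np.concatenate(train_parts)),
        test_idx=np.sort(np.concatenate(test_parts)),
        train_frac=frac, seed=seed,
    )


def wilson_ci(p_hat: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    center = (p + z^2/2n) / (1 + z^2/n), half-width
    z sqrt(p(1-p)/n + z^2/4n^2) / (1 + z^2/n), with z the normal quantile at
    (1 + conf)/2.  Always inside [0, 1] and better behaved than the Wald
    interval near the boundaries.
    """
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError("p_hat must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    z = norm.ppf(0.5 * (1 + conf))
    denom = 1 + z ** 2 / n
    center = (p_hat + z ** 2 / (2 * n)) / denom
    half = z * np.sqrt(p_hat * (1 - p_hat) / n + z ** 2 / (4 * n ** 2)) / denom
    return float(center - half), float(center + half)


def two_proportion_z(p1: float, p2: float, n: int) -> tuple[float, float]:
    """Unpaired two-proportion z-test with identical group sizes.

    Uses the pooled proportion standard error and a two-sided normal
    p-value; returns (z, p) with z = (p1 - p2) / SE so that swapping the
    proportions flips the sign of z and leaves p unchanged.  Degenerate
    pooled proportions (0 or 1) yield p = 1 when the proportions are equal
    and p = 0 otherwise.
    """
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError("proportions must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    pooled = 0.5 * (p1 + p2)
    if pooled in (0.0, 1.0):
        return (0.0, 1.0) if p1 == p2 else (np.inf * np.sign(p1 - p2), 0.0)
    se = np.sqrt(pooled * (1 - pooled) * 2.0 / n)
    z = (p1 - p2) / se
    return float(z), float(2.0 * norm.sf(abs(z)))


def compute_metrics(y_true, y_pred, conf: float = 0.95) -> MetricsReport:
    """Confusion matrix, accuracy, macro precision/recall/F1 and Wilson CI.

    A class absent from the truth makes its per-class metrics undefined;
    they are reported as 0 with an explanatory flag (macro averages still
    include them).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    cm = _sk_confusion(y_true, y_pred, labels=[0, 1])
    acc = float(np.trace(cm) / cm.sum())
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=[0, 1], average=None, zero_division=0)
    flags = [f"class {c} absent from y_true; its metrics reported as 0"
             for c in (0, 1) if not np.any(y_true == c)]
    return MetricsReport(
        confusion=cm, accuracy=acc,
        precision=float(prec.mean()), recall=float(rec.mean()),
        f1_macro=float(f1.mean()), per_class_f1=f1,
        wilson_ci=wilson_ci(acc, len(y_true), conf), n=len(y_true),
        flags=flags,
    )


def feature_redundancy(table: pd.DataFrame) -> tuple[float, pd.DataFrame, list[str]]:
    """Pairwise Pearson correlation between descriptor-group summaries.

    Each descriptor group is summarized per window by the mean of its scalars
    over channels (band powers pooled for the STFT group); the result is the
    max |r| over distinct group pairs plus the full symmetric matrix.
    Zero-variance summaries are flagged and their correlations left NaN.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 windows for a correlation estimate")
    summaries = {}
    for group in ALL_GROUPS:
        cols = [c for c in table.columns
                if any(c.endswith(f"_{nm}") for nm in DESCRIPTOR_GROUPS[group])]
        if cols:
            summaries[group] = table[cols].mean(axis=1)
    summ = pd.DataFrame(summaries)
    flags = [f"descriptor group '{g}' has zero variance; correlations undefined"
             for g in summ.columns if summ[g].std() == 0]
    corr = summ.corr(method="pearson")
    off = corr.where(~np.eye(len(corr), dtype=bool)).abs()
    max_r = float(off.max().max()) if np.isfinite(off.to_numpy()).any() else float("nan")
    return max_r, corr, flags
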