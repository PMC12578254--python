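"""End-to-end orchestration: synthesize/ingest -> preprocess -> featurize ->
train -> evaluate -> generate, with YAML configs, stage manifests and a
deterministic per-stage seed derivation.

A run is reproducible bit-for-bit from its config echo: the single global
seed fans out to one child seed per stochastic stage through
``numpy.random.SeedSequence([global_seed, stage_index])``, so stages can be
re-executed independently without seed collisions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cvae as cvae_mod
from . import io as io_mod
from .evalstats import compute_metrics, stratified_split
from .features import FeatureConfig, feature_columns, feature_table
from .preprocess import (amplitude_qc, apply_norm, balance_and_weight,
                         filter_signal, fit_norm_stats, resample_to_125,
                         restrict_montage, segment_windows)
from .synthetic import ClassEffect, SyntheticSpec, gen_two_class_recordings

#: Stage order for the seed fan-out; indices are part of the contract.
_STAGES = ("synth", "balance", "split", "train", "generate")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic child seed for a named stage (< 2**31)."""
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([global_seed, idx]).generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Full configuration of a pipeline run; serializes to/from YAML."""

    source: str = "synthetic"  # "synthetic" | "edf" | "matrix"
    input_paths: list[str] = field(default_factory=list)
    synthetic: dict = field(default_factory=dict)
    mains: int = 50
    feature: dict = field(default_factory=dict)
    cvae: dict = field(default_factory=dict)
    split_frac: float = 0.8
    balance: bool = True
    generate_n: int = 0
    generate_label: int = 1
    seed: int = 0
    out_dir: str = "run"

    def synthetic_spec(self) -> SyntheticSpec:
        params = dict(self.synthetic)
        if "class_effect" in params:
            params["class_effect"] = ClassEffect(**params["class_effect"])
        if "n_runs_per_class" in params and params["n_runs_per_class"] is not None:
            params["n_runs_per_class"] = tuple(params["n_runs_per_class"])
        params.setdefault("seed", stage_seed(self.seed, "synth"))
        return SyntheticSpec(**params)

    def feature_config(self) -> FeatureConfig:
        params = dict(self.feature)
        if "groups" in params:
            params["groups"] = tuple(params["groups"])
        return FeatureConfig(**params)

    def cvae_config(self, d_feat: int) -> cvae_mod.CVAEConfig:
        params = dict(self.cvae)
        for key in ("encoder_widths", "decoder_widths", "adam_betas",
                    "mmd_kernel_scales"):
            if key in params:
                params[key] = tuple(params[key])
        params.setdefault("seed", stage_seed(self.seed, "train"))
        params["d_feat"] = d_feat
        return cvae_mod.CVAEConfig(**params)


def load_config(path) -> RunConfig:
    payload = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**payload)


def dump_config(cfg: RunConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True))
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_recordings(cfg: RunConfig) -> list:
    if cfg.source == "synthetic":
        return gen_two_class_recordings(cfg.synthetic_spec())
    if cfg.source == "edf":
        return [io_mod.read_edf(p) for p in cfg.input_paths]
    if cfg.source == "matrix":
        return [io_mod.read_raw_matrix(p) for p in cfg.input_paths]
    raise ValueError(f"unknown source {cfg.source!r}")


def preprocess_recordings(recordings, mains: int = 50):
    """Montage restriction, filtering, resampling and epoching for a list of
    recordings; returns (windows, counts-dict)."""
    windows = []
    for rec in recordings:
        rec = restrict_montage(rec)
        rec = filter_signal(rec, mains=mains)
        rec = resample_to_125(rec)
        windows.extend(segment_windows(rec))
    kept, dropped = amplitude_qc(windows)
    counts = {
        "recordings": len(recordings),
        "windows_segmented": len(windows),
        "windows_qc_kept": len(kept),
        "windows_qc_dropped": len(dropped),
    }
    return kept, counts


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict
    metrics: object
    model: cvae_mod.CVAEModel
    features: object


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute every stage and write the artifacts under ``cfg.out_dir``.

    Artifacts: config echo (YAML), window archive, normalization statistics,
    feature table (CSV), model checkpoint, per-epoch traces, metrics report,
    optional generated samples, and a manifest with per-stage counts, stage
    timings and file checksums.  Any stage failure leaves the partial
    artifacts in place next to a ``FAILED`` marker file.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"counts": {}, "timings_s": {}, "checksums": {}}
    t_all = time.perf_counter()
    try:
        dump_config(cfg, out / "config_echo.yaml")

        t0 = time.perf_counter()
        recordings = load_recordings(cfg)
        windows, counts = preprocess_recordings(recordings, mains=cfg.mains)
        manifest["counts"].update(counts)
        manifest["timings_s"]["preprocess"] = time.perf_counter() - t0

        if cfg.balance:
            windows, weights = balance_and_weight(
                windows, seed=stage_seed(cfg.seed, "balance"))
        else:
            from .preprocess import class_weights
            n1 = sum(w.y for w in windows)
            weights = class_weights(len(windows) - n1, n1)
        manifest["counts"]["windows_balanced"] = len(windows)
        manifest["counts"]["class_weights"] = [weights.healthy, weights.impaired]

        labels = np.array([w.y for w in windows])
        subjects = np.array([w.subject_id for w in windows])
        split = stratified_split(labels, subjects, frac=cfg.split_frac,
                                 seed=stage_seed(cfg.seed, "split"))
        manifest["counts"]["windows_train"] = len(split.train_idx)
        manifest["counts"]["windows_test"] = len(split.test_idx)

        stats = fit_norm_stats([windows[i] for i in split.train_idx])
        windows = apply_norm(windows, stats)
        io_mod.write_windows(windows, out / "windows.npz")
        io_mod.write_norm_stats(stats, weights, out / "norm_stats.json")

        t0 = time.perf_counter()
        fcfg = cfg.feature_config()
        table = feature_table(windows, fcfg)
        io_mod.write_feature_table(table, out / "features.csv")
        manifest["timings_s"]["featurize"] = time.perf_counter() - t0

        cols = feature_columns(table)
        x = table[cols].to_numpy(dtype=np.float64)
        y = table["label"].to_numpy(dtype=int)
        # the model assumes z-scored feature inputs (its Gaussian likelihood
        # is homoscedastic across dimensions): standardize feature-wise with
        # training-split statistics
        f_mean = x[split.train_idx].mean(axis=0)
        f_sd = np.maximum(x[split.train_idx].std(axis=0), 1e-12)
        x = (x - f_mean) / f_sd
        (out / "feature_scaler.json").write_text(json.dumps(
            {"mean": f_mean.tolist(), "sd": f_sd.tolist(), "columns": cols}))
        ccfg = cfg.cvae_config(d_feat=len(cols))
        t0 = time.perf_counter()
        model, traces = cvae_mod.train(
            x[split.train_idx], y[split.train_idx], ccfg, weights=weights,
            x_val=x[split.test_idx], y_val=y[split.test_idx])
        manifest["timings_s"]["train"] = time.perf_counter() - t0
        cvae_mod.save_model(model, out / "model.npz")
        traces.to_csv(out / "traces.csv", index=False)
        (out / "split.json").write_text(json.dumps({
            "train": split.train_idx.tolist(), "test": split.test_idx.tolist(),
            "frac": split.train_frac, "seed": split.seed}))

        preds = cvae_mod.predict(model, x[split.test_idx])
        metrics = compute_metrics(y[split.test_idx], preds)
        (out / "metrics.txt").write_text(metrics.to_text() + "\n")
        (out / "metrics.json").write_text(json.dumps({
            "accuracy": metrics.accuracy, "precision": metrics.precision,
            "recall": metrics.recall, "macro_f1": metrics.f1_macro,
            "wilson_ci": list(metrics.wilson_ci), "n": metrics.n,
            "confusion": metrics.confusion.tolist()}, indent=1))

        if cfg.generate_n > 0:
            gen = cvae_mod.generate(model, cfg.generate_label, cfg.generate_n,
                                    seed=stage_seed(cfg.seed, "generate"))
            import pandas as pd
            pd.DataFrame(gen, columns=cols).to_csv(out / "generated.csv", index=False)

        manifest["timings_s"]["total"] = time.perf_counter() - t_all
        for f in sorted(out.iterdir()):
            if f.is_file() and f.name != "manifest.json":
                manifest["checksums"][f.name] = _sha256(f)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return PipelineResult(out_dir=out, manifest=manifest, metrics=metrics,
                              model=model, features=table)
    except Exception:
        (out / "FAILED").write_text("pipeline stage failed; partial artifacts retained\n")
        raise
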