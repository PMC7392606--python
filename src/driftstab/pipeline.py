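"""Configuration-driven orchestration of the analysis stages.

A run is described by a YAML config (strictly validated — unknown keys
are errors) naming an input source (synthetic recipe or dataset path),
a list of stages, per-stage parameters, an output directory and a
global seed.  ``run_pipeline`` executes the stages in order, writes
each stage's tables, and records a manifest (inputs, seeds, output
hashes) from which every reported number can be recomputed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alignment, dataio, decoding, lms, null_model, synthetic
from .data import InvalidParameterError, MultiDayDataset

__all__ = ["RunConfig", "ConfigError", "load_config", "run_pipeline",
           "render_report", "KNOWN_STAGES"]

KNOWN_STAGES = ("simulate", "decode", "nullmodel", "align", "lms")
log = logging.getLogger("driftstab")


class ConfigError(ValueError):
    pass


_SIMULATE_KEYS = {"n_units", "n_sessions", "n_trials", "maze_len_m",
                  "sample_rate_hz", "max_gap_days", "p_gap", "cue_shift",
                  "mode", "rank_k", "step_size", "noise_align_frac",
                  "session_days", "sigma_shared", "sigma_private",
                  "smooth_tau_s"}
_STAGE_KEYS = {
    "simulate": _SIMULATE_KEYS,
    "decode": {"target", "mode", "folds", "ridge_strength", "lambda_grid",
               "subset_sizes", "n_draws", "n_shuffles", "n_perms"},
    "nullmodel": {"target", "n_days", "rank", "n_resamples", "folds"},
    "align": {"mode", "n_location_bins", "condition_on_cue", "n_samples",
              "min_trials"},
    "lms": {"target", "eta", "eta_grid", "init_sessions"},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    stages: list
    out_dir: str
    seed: int = 0
    input_path: str | None = None
    input_format: str = "hdf5"
    simulate: dict = field(default_factory=dict)
    stage_params: dict = field(default_factory=dict)


def load_config(source) -> RunConfig:
    """Parse and strictly validate a YAML config (path, str or dict)."""
    if isinstance(source, dict):
        raw = dict(source)
    else:
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        raw = yaml.safe_load(text) or {}
    known_top = {"stages", "out_dir", "seed", "input_path", "input_format",
                 "simulate"} | set(KNOWN_STAGES)
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    stages = list(raw.get("stages", []))
    for st in stages:
        if st not in KNOWN_STAGES:
            raise ConfigError(f"unknown stage {st!r}; known: {KNOWN_STAGES}")
    stage_params = {}
    for st in KNOWN_STAGES:
        params = dict(raw.get(st, {}))
        bad = set(params) - _STAGE_KEYS[st]
        if bad:
            raise ConfigError(f"unknown keys for stage {st!r}: {sorted(bad)}")
        stage_params[st] = params
    return RunConfig(stages=stages, out_dir=str(raw.get("out_dir", "runs")),
                     seed=int(raw.get("seed", 0)),
                     input_path=raw.get("input_path"),
                     input_format=str(raw.get("input_format", "hdf5")),
                     simulate=stage_params.pop("simulate"),
                     stage_params=stage_params)


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _simulate_config(params: dict, seed: int) -> synthetic.SimulateConfig:
    drift_keys = {"mode", "rank_k", "step_size", "noise_align_frac"}
    noise_keys = {"sigma_shared", "sigma_private", "smooth_tau_s"}
    drift = synthetic.DriftSpec(**{k: params[k] for k in drift_keys
                                   if k in params}, seed=seed)
    noise = synthetic.NoiseParams(**{k: params[k] for k in noise_keys
                                     if k in params})
    rest = {k: v for k, v in params.items()
            if k not in drift_keys | noise_keys}
    return synthetic.SimulateConfig(drift=drift, noise_params=noise,
                                    seed=seed, **rest)


def _load_input(cfg: RunConfig) -> MultiDayDataset:
    if cfg.input_path is not None:
        return dataio.load_dataset(cfg.input_path, cfg.input_format)
    return synthetic.generate_dataset(_simulate_config(cfg.simulate,
                                                       cfg.seed))


# --------------------------------------------------------- stage runners

def _stage_simulate(cfg, dataset, out: Path) -> list[Path]:
    path = out / "dataset.h5"
    dataio.save_dataset(dataset, path, "hdf5")
    return [path]


def _prepared(dataset: MultiDayDataset) -> MultiDayDataset:
    return dataset.map_sessions(dataio.prepare_decoding_series)


def _stage_decode(cfg, dataset, out: Path) -> list[Path]:
    p = cfg.stage_params["decode"]
    target = p.get("target", "position")
    folds = int(p.get("folds", 10))
    prep = _prepared(dataset)
    rows = []
    for s in prep.sessions:
        cv = decoding.evaluate_cv(s, target, folds)
        rows.append({"day_index": s.day_index, "cv_mae": cv["mae"],
                     "cv_mse": cv["mse"]})
    per_day = pd.DataFrame(rows)
    cat = decoding.fit_concatenated(prep, target)
    per_day["concat_mae"] = [decoding.mean_abs_error(
        s.target(target), decoding.predict(cat, s.activity))
        for s in prep.sessions]
    files = [out / "decode_per_day.csv"]
    per_day.to_csv(files[0], index=False)

    lam = p.get("lambda_grid", [0.0, 0.3, 0.6, 0.9, 0.99])
    path_res = decoding.fit_constrained_path(prep, target, lam)
    lam_df = pd.DataFrame({
        "lambda": path_res.lambda_grid,
        "mean_mae": path_res.per_day_error.mean(axis=1),
        "pct_weight_change": path_res.pct_weight_change})
    files.append(out / "decode_lambda_path.csv")
    lam_df.to_csv(files[-1], index=False)

    xmat = decoding.cross_day_matrix(prep, target, folds)
    files.append(out / "decode_cross_day.csv")
    pd.DataFrame(xmat).to_csv(files[-1], index=False)
    curve = decoding.degradation_curve(prep, target)
    files.append(out / "decode_degradation.csv")
    pd.DataFrame({"n_days": np.arange(1, len(curve) + 1),
                  "normalized_r2": curve}).to_csv(files[-1], index=False)
    return files


def _stage_nullmodel(cfg, dataset, out: Path) -> list[Path]:
    p = cfg.stage_params["nullmodel"]
    target = p.get("target", "position")
    prep = _prepared(dataset)
    match = null_model.match_null_to_data(prep, target,
                                          int(p.get("folds", 5)))
    res = null_model.run_null_experiment(
        prep.sessions[0], n_days=int(p.get("n_days", prep.n_sessions)),
        between_day_r2=match["between_day_r2"],
        single_day_mae=match["single_day_mae"], k=p.get("rank"),
        seed=cfg.seed, n_resamples=int(p.get("n_resamples", 20)))
    df = pd.DataFrame({
        "n_days": np.arange(1, res.mean_curve.size + 1),
        "normalized_r2_mean": res.mean_curve,
        "band_lo": res.band[0], "band_hi": res.band[1]})
    files = [out / "null_degradation.csv"]
    df.to_csv(files[0], index=False)
    return files


def _stage_align(cfg, dataset, out: Path) -> list[Path]:
    p = cfg.stage_params["align"]
    mode = p.get("mode", "noise")
    bins = int(p.get("n_location_bins", 50))
    processed = []
    for s in dataset.sessions:
        keep = ~s.kinematics.iti_flag
        sub = s.select_samples(keep)
        act = dataio.bandpass_zscore(sub.activity + 1.0,
                                     sample_rate_hz=sub.sample_rate_hz)
        processed.append(type(sub)(sub.day_index, sub.unit_ids, act,
                                   sub.kinematics, sub.sample_rate_hz))
    res = alignment.pooled_rho(processed, mode, bins,
                               bool(p.get("condition_on_cue", True)),
                               int(p.get("min_trials", 2)))
    files = [out / f"align_{mode}.csv"]
    pd.DataFrame(res["table"]).to_csv(files[0], index=False)
    mom = alignment.conditioned_moments(processed[0], bins,
                                        bool(p.get("condition_on_cue",
                                                   True)),
                                        int(p.get("min_trials", 2)))
    cell = mom.cells()[len(mom.cells()) // 2]
    chance = alignment.chance_alignment_mc(mom, mode,
                                           int(p.get("n_samples", 100)),
                                           cfg.seed, cell=cell)
    files.append(out / f"align_{mode}_chance.csv")
    pd.DataFrame({"rho": chance["rho_samples"]}).to_csv(files[-1],
                                                        index=False)
    return files


def _stage_lms(cfg, dataset, out: Path) -> list[Path]:
    p = cfg.stage_params["lms"]
    target = p.get("target", "position")
    raw = dataset.map_sessions(
        lambda s: dataio.prepare_decoding_series(s, center=False))
    eta = float(p.get("eta", 4e-4))
    res = lms.run_online(raw, target, eta,
                         int(p.get("init_sessions", 2)), cfg.seed)
    stats = lms.weight_change_stats(res["snapshots"], res["day_gaps"])
    df = pd.DataFrame({"session": np.arange(len(res["mae_per_session"])),
                       "mae_lms": res["mae_per_session"],
                       "mae_frozen": res["mae_frozen"]})
    files = [out / "lms_per_session.csv"]
    df.to_csv(files[0], index=False)
    if "eta_grid" in p:
        sweep = lms.sweep_learning_rates(raw, target, p["eta_grid"],
                                         cfg.seed,
                                         int(p.get("init_sessions", 2)))
        files.append(out / "lms_sweep.csv")
        pd.DataFrame({"eta": sweep["eta"], "mae": sweep["mae"],
                      "pct_weight_change_per_day":
                          sweep["pct_weight_change_per_day"]}
                     ).to_csv(files[-1], index=False)
    summary = pd.DataFrame([{"eta": eta,
                             "mean_pct_per_session":
                                 stats["mean_pct_per_session"],
                             "mean_pct_per_day": stats["mean_pct_per_day"],
                             "mean_mae": res["mae_per_session"].mean(),
                             "frozen_mae": res["mae_frozen"].mean()}])
    files.append(out / "lms_summary.csv")
    summary.to_csv(files[-1], index=False)
    return files


_RUNNERS = {"simulate": _stage_simulate, "decode": _stage_decode,
            "nullmodel": _stage_nullmodel, "align": _stage_align,
            "lms": _stage_lms}


def run_pipeline(config) -> dict:
    """Execute the configured stages and write a run manifest.

    Stages run in the configured order; a stage failure stops the run
    but leaves completed-stage outputs (and the manifest) intact.
    """
    cfg = config if isinstance(config, RunConfig) else load_config(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": cfg.seed, "stages": [], "outputs": {},
                "input": cfg.input_path or "synthetic",
                "config": {"simulate": cfg.simulate,
                           "stage_params": cfg.stage_params}}
    dataset = _load_input(cfg) if cfg.stages else None
    for st in cfg.stages:
        t0 = time.time()
        log.info("stage %s: starting (seed=%d)", st, cfg.seed)
        files = _RUNNERS[st](cfg, dataset, out)
        manifest["stages"].append(st)
        for f in files:
            manifest["outputs"][f.name] = _file_hash(f)
        log.info("stage %s: done in %.1fs", st, time.time() - t0)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def render_report(manifest: dict, out_dir=None) -> dict:
    """Render per-stage figures and a summary table from a manifest.

    Only stages whose outputs are present are rendered; missing stages
    are listed as skipped.  Whiskers on distribution panels are 5th and
    95th percentiles, recomputed from the archived tables.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir) if out_dir else Path(".")
    rendered, skipped = [], []
    summary_rows = []

    def have(name):
        return name in manifest["outputs"] and (out / name).exists()

    if have("decode_per_day.csv"):
        df = pd.read_csv(out / "decode_per_day.csv")
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(df["day_index"], df["cv_mae"], "o-", label="same-day CV")
        ax.plot(df["day_index"], df["concat_mae"], "s-",
                label="concatenated")
        ax.set(xlabel="day", ylabel="MAE", title="Decoding error by day")
        ax.legend()
        fig.savefig(out / "report_decode.png", dpi=120,
                    bbox_inches="tight")
        plt.close(fig)
        rendered.append("decode")
        summary_rows.append({"stage": "decode",
                             "mean_cv_mae": df["cv_mae"].mean(),
                             "mean_concat_mae": df["concat_mae"].mean()})
    else:
        skipped.append("decode")

    if have("null_degradation.csv"):
        df = pd.read_csv(out / "null_degradation.csv")
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.fill_between(df["n_days"], df["band_lo"], df["band_hi"],
                        alpha=0.3, label="null inner 95%")
        ax.plot(df["n_days"], df["normalized_r2_mean"], "k-", label="null")
        ax.set(xlabel="days in span", ylabel="normalized $R^2$",
               title="Null-model degradation")
        ax.legend()
        fig.savefig(out / "report_null.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        rendered.append("nullmodel")
        summary_rows.append({"stage": "nullmodel",
                             "final_norm_r2":
                                 df["normalized_r2_mean"].iloc[-1]})
    else:
        skipped.append("nullmodel")

    for mode in ("noise", "coding"):
        name = f"align_{mode}.csv"
        if have(name):
            df = pd.read_csv(out / name)
            fig, ax = plt.subplots(figsize=(4, 3.5))
            r = df["rho"].to_numpy()
            ax.boxplot([r], whis=(5, 95), tick_labels=[mode])
            ax.axhline(0, color="grey", lw=0.8)
            ax.set(ylabel=r"$\rho$", title=f"Drift alignment ({mode})")
            fig.savefig(out / f"report_align_{mode}.png", dpi=120,
                        bbox_inches="tight")
            plt.close(fig)
            rendered.append(f"align_{mode}")
            summary_rows.append({"stage": f"align_{mode}",
                                 "mean_rho": float(np.mean(r)),
                                 "p5": float(np.percentile(r, 5)),
                                 "p95": float(np.percentile(r, 95))})
        else:
            skipped.append(f"align_{mode}")

    if have("lms_per_session.csv"):
        df = pd.read_csv(out / "lms_per_session.csv")
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(df["session"], df["mae_lms"], "o-", label="LMS")
        ax.plot(df["session"], df["mae_frozen"], "s--", label="frozen")
        ax.set(xlabel="streamed session", ylabel="MAE",
               title="Online LMS tracking")
        ax.legend()
        fig.savefig(out / "report_lms.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        rendered.append("lms")
        summary_rows.append({"stage": "lms",
                             "mean_mae_lms": df["mae_lms"].mean(),
                             "mean_mae_frozen": df["mae_frozen"].mean()})
    else:
        skipped.append("lms")

    if not manifest.get("stages"):
        raise InvalidParameterError("manifest has no completed stages")
    pd.DataFrame(summary_rows).to_csv(out / "report_summary.csv",
                                      index=False)
    return {"rendered": rendered, "skipped": skipped,
            "summary": str(out / "report_summary.csv")}
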