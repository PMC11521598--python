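"""End-to-end orchestration: simulate -> preprocess -> synchrony -> indices -> model.

The pipeline is configured by a YAML file (unknown keys rejected), runs
the enabled stages in order, logs structured JSON-lines events, and
writes a run manifest with SHA-256 digests of every output so that
re-running with an identical configuration and seed is verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import indices as indices_mod
from . import io as io_mod
from . import models as models_mod
from . import preprocess as pp
from . import synchrony as sync_mod
from .simulate import DyadSimConfig, simulate_study
from .types import DyadSession

logger = logging.getLogger("dyadsync")

STAGES = ("simulate", "preprocess", "synchrony", "indices", "model")
_ALLOWED_KEYS = {"out_dir", "seed", "n_dyads", "stages", "sim", "wtc", "synchrony",
                 "model", "rpeak_threshold_sd", "log_level", "channels"}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (round-trips through YAML)."""

    out_dir: str = "dyadsync_run"
    seed: int = 0
    n_dyads: int = 6
    stages: list = field(default_factory=lambda: list(STAGES))
    channels: list = field(default_factory=lambda: ["ecg", "rsp", "sc"])
    sim: dict = field(default_factory=dict)
    wtc: dict = field(default_factory=dict)
    synchrony: dict = field(default_factory=lambda: {"channel": "ibi", "band": "lf"})
    model: dict = field(default_factory=dict)
    rpeak_threshold_sd: float = 0.6
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; expected subset of {STAGES}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    """Digest record of one pipeline run."""

    config_hash: str
    seed: int
    started: float
    finished: float = 0.0
    stages_run: list = field(default_factory=list)
    file_digests: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _log_event(out_dir: Path, **event) -> None:
    event.setdefault("ts", time.time())
    with open(out_dir / "run.log.jsonl", "a", encoding="utf-8") as fh:
        fh.write(json.dumps(event) + "\n")
    logger.info("%s", event)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in order and write a manifest.

    Any stage failure raises with the stage name attached; partial
    outputs remain on disk for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = RunManifest(config_hash=hashlib.sha256(cfg_json.encode()).hexdigest(),
                           seed=config.seed, started=time.time())

    sessions: list[DyadSession] = []
    try:
        for stage in config.stages:
            _log_event(out, stage=stage, status="start")
            if stage == "simulate":
                sessions = _stage_simulate(config, out)
            else:
                if not sessions:
                    sessions = _load_sessions(out)
                if stage == "preprocess":
                    _stage_preprocess(config, out, sessions)
                elif stage == "synchrony":
                    _stage_synchrony(config, out, sessions)
                elif stage == "indices":
                    _stage_indices(config, out, sessions)
                elif stage == "model":
                    _stage_model(config, out)
            manifest.stages_run.append(stage)
            _log_event(out, stage=stage, status="done")
    except Exception as exc:
        _log_event(out, stage="pipeline", status="error", error=str(exc))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest.file_digests[str(path.relative_to(out))] = _sha256(path)
    manifest.finished = time.time()
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest.to_dict(), fh, indent=1)
    return manifest


def _stage_simulate(config: PipelineConfig, out: Path) -> list:
    sim_cfg = DyadSimConfig(**{"seed": config.seed, **config.sim})
    sessions = simulate_study(config.n_dyads, sim_cfg, channels=tuple(config.channels),
                              seed=config.seed)
    for session in sessions:
        io_mod.write_session(session, out / "sessions" / session.dyad_id)
    return sessions


def _load_sessions(out: Path) -> list:
    root = out / "sessions"
    if not root.is_dir():
        raise FileNotFoundError("no sessions directory; enable the simulate stage "
                                "or point out_dir at an existing run")
    return [io_mod.read_session(d) for d in sorted(root.iterdir()) if d.is_dir()]


def _stage_preprocess(config: PipelineConfig, out: Path, sessions: list) -> None:
    pdir = out / "preproc"
    pdir.mkdir(exist_ok=True)
    rsp_recs, sc_recs = {}, {}
    for session in sessions:
        for m in range(2):
            pid = f"{session.dyad_id}_m{m + 1}"
            rsp_list, sc_list = [], []
            for v in range(session.n_videos):
                mv = session.data.get((m, v))
                if mv is None:
                    raise FileNotFoundError(f"missing channel files for dyad "
                                            f"{session.dyad_id} member {m + 1} video {v + 1}")
                if "ecg" in mv.recordings:
                    series = pp.ecg_to_ibi(mv.recordings["ecg"],
                                           threshold_sd=config.rpeak_threshold_sd)
                else:
                    peaks = mv.truth.get("ibi_peak_times_s", mv.truth.get("r_peak_times_s"))
                    series = pp.build_ibi(np.asarray(peaks))
                ibi_df = pd.DataFrame({"peak_time_s": series.peak_times,
                                       "ibi_ms": np.concatenate(([np.nan], series.ibis_ms))})
                ibi_df.to_csv(pdir / f"{pid}_video{v + 1}_ibi.csv", index=False)
                if "rsp" in mv.recordings:
                    rsp_list.append(mv.recordings["rsp"])
                if "sc" in mv.recordings:
                    sc_list.append(mv.recordings["sc"])
                    phasic = pp.extract_phasic_sc(mv.recordings["sc"])
                    pd.DataFrame({"time_s": phasic.times,
                                  "phasic_us": phasic.samples}).to_csv(
                        pdir / f"{pid}_video{v + 1}_sc_phasic.csv", index=False)
            if rsp_list:
                rsp_recs[pid] = rsp_list
            if sc_list:
                sc_recs[pid] = sc_list

    artifacts = {}
    if len(rsp_recs) >= 2:
        for pid, rep in pp.flag_rsp_artifacts(rsp_recs).items():
            artifacts.setdefault(pid, {})["rsp"] = {
                "rules_fired": rep.rules_fired, "excluded": rep.excluded}
    if sc_recs:
        for pid, rep in pp.flag_sc_artifacts(sc_recs).items():
            artifacts.setdefault(pid, {})["sc"] = {
                "rules_fired": rep.rules_fired, "excluded": rep.excluded}
    with open(out / "artifacts.json", "w", encoding="utf-8") as fh:
        json.dump(artifacts, fh, indent=1)


def _stage_synchrony(config: PipelineConfig, out: Path, sessions: list) -> None:
    channel = config.synchrony.get("channel", "ibi")
    bands = config.synchrony.get("bands", [config.synchrony.get("band", "lf")])
    cfg = sync_mod.WtcConfig(**config.wtc) if config.wtc else None
    rows = []
    for session in sessions:
        for v in range(session.n_videos):
            x, fs = sync_mod.member_trace(session, 0, v, channel)
            y, _ = sync_mod.member_trace(session, 1, v, channel)
            n = min(x.size, y.size)
            wtc_map = sync_mod.wavelet_coherence(x[:n], y[:n], fs, cfg)
            for band in bands:
                scalar = sync_mod.average_synchrony(wtc_map, band=band)
                rows.append({"dyad": session.dyad_id, "channel": channel,
                             "video": v, "condition": session.video_conditions[v],
                             "band": band, "method": "wtc", "value": scalar.value})
    pd.DataFrame(rows).to_csv(out / "synchrony.csv", index=False)


def _stage_indices(config: PipelineConfig, out: Path, sessions: list) -> None:
    sync_path = out / "synchrony.csv"
    sync_df = pd.read_csv(sync_path) if sync_path.exists() else None
    table = indices_mod.build_index_table(sessions, synchrony_table=sync_df)
    table.to_csv(out / "dyad_indices.csv", index=False)
    corrected = indices_mod.neutral_baseline_correct(table)
    corrected.to_csv(out / "dyad_indices_corrected.csv", index=False)


def _stage_model(config: PipelineConfig, out: Path) -> None:
    table = pd.read_csv(out / "dyad_indices_corrected.csv")
    model_cfg = dict(config.model)
    response = model_cfg.pop("response", "mutual_connectedness")
    fixed = model_cfg.pop("fixed", None)
    if fixed is None:
        fixed = []
        for col in ("dyadic_mean_ibi_ms", "dyadic_mean_rsp_rate", "dyadic_mean_sc_level",
                    "dyadic_mean_arousal"):
            if col in table.columns and table[col].notna().all():
                fixed.append(col)
                fixed.append(f"{col}:attention")
        fixed.append("attention")
    std_cols = model_cfg.pop("standardize", None)
    if std_cols is None:
        std_cols = [t for t in fixed
                    if ":" not in t and t in table.columns
                    and pd.api.types.is_numeric_dtype(table[t])]
    if std_cols:
        table = models_mod.standardize_predictors(table, std_cols)
    spec = models_mod.ModelSpec(response=response, fixed=fixed,
                                random_intercepts=model_cfg.pop("random_intercepts", ["dyad"]),
                                estimation="ML")
    trace = models_mod.backward_stepwise(spec, table,
                                         alpha_keep=model_cfg.pop("alpha_keep", 0.05))
    fit = trace.final_fit
    fit_out = {
        "coefficients": {k: {"estimate": float(fit.params[k]), "se": float(fit.bse[k]),
                             "ci_lower": float(fit.conf_int.loc[k, "lower"]),
                             "ci_upper": float(fit.conf_int.loc[k, "upper"]),
                             "p": float(fit.pvalues[k])}
                         for k in fit.params.index},
        "sigma2": fit.sigma2, "tau00": fit.tau00, "icc": fit.icc,
        "r2_marginal": fit.r2_marginal, "r2_conditional": fit.r2_conditional,
        "n_obs": fit.nobs, "converged": fit.converged,
    }
    with open(out / "model_fit.json", "w", encoding="utf-8") as fh:
        json.dump(fit_out, fh, indent=1)
    with open(out / "selection_trace.json", "w", encoding="utf-8") as fh:
        json.dump(trace.to_dict(), fh, indent=1)


def validate_session_dir(path) -> dict:
    """Schema check of one session directory; returns a violation report."""
    path = Path(path)
    report = {"path": str(path), "violations": []}
    meta_path = path / "session.json"
    if not meta_path.exists():
        report["violations"].append("missing session.json")
        return report
    with open(meta_path, encoding="utf-8") as fh:
        meta = json.load(fh)
    n_videos = len(meta.get("video_conditions", []))
    channels = [c for c in ("ecg", "rsp", "sc")
                if any(path.glob(f"member*_video*_{c}.csv"))]
    for m in range(1, 3):
        for v in range(1, n_videos + 1):
            for channel in channels:
                fpath = path / f"member{m}_video{v}_{channel}.csv"
                if not fpath.exists():
                    report["violations"].append(
                        f"missing {channel} file for member {m} video {v}")
                    continue
                with open(fpath, encoding="utf-8") as fh:
                    header = fh.readline()
                if not (header.startswith("#") and "fs=" in header):
                    report["violations"].append(f"{fpath.name}: missing fs header")
                    continue
                df = pd.read_csv(fpath, comment="#")
                dt = np.diff(df["time_s"].to_numpy())
                bad = np.flatnonzero(dt <= 0)
                if bad.size:
                    report["violations"].append(
                        f"{fpath.name}: non-monotone time column at row {int(bad[0]) + 2}")
    report["ok"] = not report["violations"]
    return report
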