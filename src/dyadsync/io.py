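"""Session-directory serialization.

One directory per dyad:

    member{1,2}_video{1,2,3}_{ecg|rsp|sc}.csv   # '# fs=<Hz> units=<u>' header,
                                                # then time_s,value rows
    ratings.csv                                 # per member x video Likert data
    attitudes.csv                               # t0/t1 social attitudes
    session.json                                # metadata + scalar ground truth

The CSV dialect is UTF-8, comma-separated, '.' decimal, with comment
lines prefixed '#'.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import DyadSimConfig
from .types import DyadSession, MemberVideoData, SignalRecording


def _channel_path(directory: Path, member: int, video: int, channel: str) -> Path:
    return directory / f"member{member + 1}_video{video + 1}_{channel}.csv"


def write_recording(path: Path, rec: SignalRecording) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fs={rec.fs:g} units={rec.units}\n")
        fh.write("time_s,value\n")
        t = rec.times
        for ti, vi in zip(t, rec.samples):
            fh.write(f"{ti:.6f},{vi:.6f}\n")


def read_recording(path: Path, channel: str) -> SignalRecording:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
    if not header.startswith("#"):
        raise ValueError(f"{path}: missing '# fs=... units=...' header line")
    meta = dict(tok.split("=", 1) for tok in header.lstrip("# ").split())
    fs = float(meta["fs"])
    df = pd.read_csv(path, comment="#")
    return SignalRecording(channel=channel, fs=fs, samples=df["value"].to_numpy(),
                           t0=float(df["time_s"].iloc[0]), units=meta.get("units", ""))


def write_session(session: DyadSession, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for (m, v), mv in session.data.items():
        for channel, rec in mv.recordings.items():
            write_recording(_channel_path(directory, m, v, channel), rec)
    if session.ratings is not None:
        session.ratings.to_csv(directory / "ratings.csv", index=False)
    if session.attitudes is not None:
        session.attitudes.to_csv(directory / "attitudes.csv", index=False)

    truth = {}
    for (m, v), mv in session.data.items():
        entry = {}
        for key in ("r_peak_times_s", "expiration_onsets_s", "scr_times_s"):
            if key in mv.truth:
                entry[key] = np.asarray(mv.truth[key]).round(6).tolist()
        if "ibi" in mv.truth:
            entry["ibi_peak_times_s"] = np.asarray(mv.truth["ibi"].peak_times).round(6).tolist()
        if "mean_ibi_ms" in mv.truth:
            entry["mean_ibi_ms"] = mv.truth["mean_ibi_ms"]
        truth[f"member{m + 1}_video{v + 1}"] = entry
    meta = {
        "dyad_id": session.dyad_id,
        "attention": session.attention,
        "video_conditions": list(session.video_conditions),
        "config": session.config.to_dict() if session.config else None,
        "ground_truth": truth,
    }
    with open(directory / "session.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)
    return directory


def read_session(directory) -> DyadSession:
    directory = Path(directory)
    with open(directory / "session.json", encoding="utf-8") as fh:
        meta = json.load(fh)
    config = DyadSimConfig(**meta["config"]) if meta.get("config") else None
    session = DyadSession(dyad_id=meta["dyad_id"], attention=meta["attention"],
                          video_conditions=meta["video_conditions"], config=config)
    n_videos = len(session.video_conditions)
    for m in range(2):
        for v in range(n_videos):
            mv = MemberVideoData(driver=None)
            for channel in ("ecg", "rsp", "sc"):
                path = _channel_path(directory, m, v, channel)
                if path.exists():
                    mv.recordings[channel] = read_recording(path, channel)
            truth = meta.get("ground_truth", {}).get(f"member{m + 1}_video{v + 1}", {})
            for key, val in truth.items():
                mv.truth[key] = np.asarray(val) if isinstance(val, list) else val
            if mv.recordings or mv.truth:
                session.data[(m, v)] = mv
    ratings_path = directory / "ratings.csv"
    if ratings_path.exists():
        session.ratings = pd.read_csv(ratings_path)
    attitudes_path = directory / "attitudes.csv"
    if attitudes_path.exists():
        session.attitudes = pd.read_csv(attitudes_path)
    return session
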