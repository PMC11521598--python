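"""Shared data containers for dyadic physiological recordings.

The containers mirror the stages of the analysis: raw single-channel
recordings (:class:`SignalRecording`), the cardiac inter-beat-interval
series derived from ECG (:class:`IbiSeries`), per-participant artifact
screening results (:class:`ArtifactReport`), and the simulated dyad
session bundle (:class:`DyadSession`) produced by :mod:`dyadsync.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

CHANNELS = ("ecg", "rsp", "sc")
CHANNEL_UNITS = {"ecg": "mV", "rsp": "mcV", "sc": "uS"}
CONDITIONS = ("negative", "neutral", "positive")
ATTENTION_LEVELS = ("joint", "disjoint")


@dataclass
class SignalRecording:
    """One uniformly sampled physiological channel.

    Parameters
    ----------
    channel : {"ecg", "rsp", "sc"}
        Physiological modality; ECG in mV, respiration-belt output in
        mcV, skin conductance in μS.
    fs : float
        Sampling rate in Hz, strictly positive.
    samples : ndarray
        Finite sample vector.
    t0 : float
        Time of the first sample in seconds.
    """

    channel: str
    fs: float
    samples: np.ndarray
    t0: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D vector")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.units:
            self.units = CHANNEL_UNITS[self.channel]

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class IbiSeries:
    """Cardiac inter-beat intervals with the 20 Hz interpolated trace.

    ``ibis_ms[i]`` is the interval between ``peak_times[i]`` and
    ``peak_times[i+1]`` in milliseconds.  ``interp_trace`` is the
    cubic-spline interpolated IBI series resampled at ``interp_fs``
    and band-passed to the heart-rate-variability range (0.04–0.4 Hz);
    ``mean_ibi_ms`` is computed before band-passing, as an inverse
    index of heart rate.
    """

    peak_times: np.ndarray
    ibis_ms: np.ndarray
    interp_fs: float = 20.0
    interp_trace: Optional[np.ndarray] = None
    interp_times: Optional[np.ndarray] = None
    mean_ibi_ms: float = float("nan")

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.ibis_ms = np.asarray(self.ibis_ms, dtype=float)
        if np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak_times must be strictly increasing")
        if np.any(self.ibis_ms <= 0):
            raise ValueError("all inter-beat intervals must be positive")
        if self.ibis_ms.size != self.peak_times.size - 1:
            raise ValueError("ibis_ms must have length len(peak_times) - 1")


@dataclass
class ArtifactReport:
    """Outcome of the artifact screening rules for one participant/channel.

    ``rules_fired`` maps rule name -> list of video indices (0-based) on
    which it fired; ``excluded`` follows each channel's criterion: the
    respiration and slope rules exclude on >=1 flagged video, the
    electrodermal unresponsiveness rule only when all three videos are
    response-free.
    """

    participant: str
    channel: str
    rules_fired: dict = field(default_factory=dict)
    excluded: bool = False

    @property
    def rule(self) -> str:
        """Name of the first rule that fired, or ``"none"``."""
        for name, videos in self.rules_fired.items():
            if videos:
                return name
        return "none"


@dataclass
class LatentArousalTrace:
    """Latent arousal driver shared by, or idiosyncratic to, dyad members.

    Member drivers are formed as ``coupling * common +
    (1 - coupling) * idiosyncratic`` with both components standardized
    to unit variance before mixing.
    """

    t: np.ndarray
    values: np.ndarray
    fs: float

    def interp(self, t_query: np.ndarray) -> np.ndarray:
        return np.interp(t_query, self.t, self.values)


@dataclass
class MemberVideoData:
    """Ground-truth bundle for one member watching one video."""

    driver: LatentArousalTrace
    recordings: dict = field(default_factory=dict)   # channel -> SignalRecording
    truth: dict = field(default_factory=dict)        # r_peak_times_s, expiration_onsets_s, scr_times_s


@dataclass
class DyadSession:
    """One simulated dyad: two members × three videos plus ratings.

    ``video_conditions`` lists the valence condition of each presented
    video in order.  ``data[(member, video)]`` holds the member-level
    recordings and ground truth; ``ratings`` has one row per member ×
    video; ``attitudes`` one row per member with t0/t1 social-attitude
    scores.  ``latent`` retains the generating rating coefficients for
    parameter-recovery tests.
    """

    dyad_id: str
    attention: str
    video_conditions: list
    data: dict = field(default_factory=dict)
    ratings: Optional[pd.DataFrame] = None
    attitudes: Optional[pd.DataFrame] = None
    latent: dict = field(default_factory=dict)
    config: Optional[object] = None

    @property
    def n_videos(self) -> int:
        return len(self.video_conditions)
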