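"""Synthetic dyadic physiology and rating generator.

Emulates two co-seated participants watching three 5-minute videos
(negative / neutral / positive) while ECG, respiration-belt and skin
conductance are recorded.  Each member's autonomic fluctuations are
driven by a latent arousal trace that mixes a video-locked *common*
component with an *idiosyncratic* component; the mixing weight
(``coupling``) controls how much of the two members' physiology is
shared, which is what the wavelet-coherence synchrony stage measures
downstream.

Channel means are calibrated to typical resting values for young
adults: mean inter-beat interval near 790–810 ms, respiratory rate
near 20–22 breaths/min, skin-conductance level near 5–8 μS, with
per-condition offsets so that emotional videos raise arousal the way
such stimuli do (longer IBI, faster breathing, higher SC level).

All randomness flows from a single master seed through
``numpy.random.SeedSequence`` spawning, so an identical configuration
reproduces a bit-identical session.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    ATTENTION_LEVELS,
    CONDITIONS,
    DyadSession,
    IbiSeries,
    LatentArousalTrace,
    MemberVideoData,
    SignalRecording,
)

# Per-condition offsets applied to the neutral-ish base levels below.
# Calibrated so default sessions land on typical printed summaries:
# IBI 808/788/805 ms, RSP 20.9/19.9/22.0 per min, SC 6.7/4.8/8.5 uS
# for negative/neutral/positive.
IBI_CONDITION_OFFSET_MS = {"negative": 8.0, "neutral": -12.0, "positive": 5.0}
RSP_CONDITION_OFFSET_BPM = {"negative": -0.1, "neutral": -1.1, "positive": 1.0}
SC_CONDITION_OFFSET_US = {"negative": 0.0, "neutral": -1.9, "positive": 1.8}

DRIVER_FS = 4.0            # Hz; latent traces only need to cover <0.5 Hz content
DRIVER_BAND = (0.01, 0.4)  # Hz; overlaps the analysed HRV band so coupling is detectable
QRS_SIGMA_S = 0.013        # Mexican-hat width parameter; ~80 ms total QRS footprint


@dataclass
class DyadSimConfig:
    """Configuration of one simulated dyad session.

    ``coupling`` in [0, 1] sets the share of the common arousal driver
    in each member's latent trace; 0 yields independent members, 1
    identical drivers.  ``valence_condition`` selects the per-condition
    physiological offsets when a single channel is simulated outside a
    full session.
    """

    duration_s: float = 300.0
    fs_ecg: float = 1000.0
    fs_rsp: float = 1000.0
    fs_sc: float = 1000.0
    mean_ibi_ms: float = 800.0
    ibi_sd_ms: float = 15.0
    rsp_rate_bpm: float = 21.0
    sc_tonic_level_us: float = 6.7
    scr_rate_per_min: float = 4.0
    coupling: float = 0.0
    valence_condition: str = "neutral"
    attention: str = "joint"
    seed: int = 0
    # generator gains (free parameters; the analysed literature does not
    # quantify stimulus-locked response amplitudes)
    arousal_ibi_gain_ms: float = 80.0
    rsp_rate_jitter: float = 0.05
    arousal_rsp_gain_bpm: float = 1.0
    scr_arousal_gain: float = 0.5
    scr_amp_us: float = 0.4
    sc_drift_us: float = 0.3
    sc_noise_us: float = 0.01
    rsp_amplitude_mcv: float = 300.0
    rsp_noise_mcv: float = 5.0
    ecg_noise_mv: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        for name in ("fs_ecg", "fs_rsp", "fs_sc", "mean_ibi_ms", "rsp_rate_bpm",
                     "sc_tonic_level_us"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.ibi_sd_ms < 0 or self.scr_rate_per_min < 0:
            raise ValueError("ibi_sd_ms and scr_rate_per_min must be non-negative")
        if self.valence_condition not in CONDITIONS:
            raise ValueError(f"valence_condition must be one of {CONDITIONS}")
        if self.attention not in ATTENTION_LEVELS:
            raise ValueError(f"attention must be one of {ATTENTION_LEVELS}")

    def for_condition(self, condition: str) -> "DyadSimConfig":
        """Copy of the config with ``valence_condition`` replaced."""
        return replace(self, valence_condition=condition)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RatingEffectParams:
    """Latent rating model: per-condition means, noise, and effect slopes.

    A per-video dyad-level arousal deviation ``d_v ~ N(0, 1)`` shifts
    both members' arousal reports (gain ``arousal_coupling``) and, under
    joint attention, the latent connectedness
    (``connect_arousal_slope``), emulating the link between
    physiological arousal and social bonding that the mixed models are
    meant to recover.  Latent Gaussians are rounded and clipped to the
    Likert bounds (9-point valence/arousal, 7-point connectedness and
    attitude items).
    """

    valence_means: dict = field(default_factory=lambda: {"negative": 2.2, "neutral": 5.2, "positive": 7.9})
    arousal_means: dict = field(default_factory=lambda: {"negative": 6.1, "neutral": 3.0, "positive": 7.3})
    connect_means: dict = field(default_factory=lambda: {"negative": 3.9, "neutral": 3.0, "positive": 3.9})
    valence_noise_sd: float = 0.9
    arousal_noise_sd: float = 1.0
    arousal_coupling: float = 1.0
    connect_arousal_slope: dict = field(default_factory=lambda: {"joint": 0.8, "disjoint": 0.0})
    connect_noise_sd: float = 0.5
    connect_item_sd: float = 0.5
    dyad_sd: float = 0.4
    attitude_t0_mean: float = 3.0
    attitude_noise_sd: float = 0.8
    attitude_item_sd: float = 0.5
    bonding_gain: float = 0.3


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def band_limited_noise(n: int, fs: float, f_lo: float, f_hi: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise confined to [f_lo, f_hi] Hz.

    Built by masking the rFFT of white noise; used as the latent
    arousal driver and as the intrinsic heart-rate-variability process.
    """
    if n < 8:
        raise ValueError("need at least 8 samples for band-limited noise")
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    if not mask.any():
        raise ValueError(f"band [{f_lo}, {f_hi}] Hz empty at n={n}, fs={fs}")
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate band-limited noise (zero variance)")
    return (x - x.mean()) / sd


def make_driver(duration_s: float, rng: np.random.Generator,
                fs: float = DRIVER_FS, band=DRIVER_BAND) -> LatentArousalTrace:
    """One standardized band-limited arousal trace."""
    n = max(int(round(duration_s * fs)), 16)
    values = band_limited_noise(n, fs, band[0], band[1], rng)
    t = np.arange(n) / fs
    return LatentArousalTrace(t=t, values=values, fs=fs)


def mix_drivers(common: LatentArousalTrace, idio: LatentArousalTrace,
                coupling: float) -> LatentArousalTrace:
    """coupling * common + (1 - coupling) * idiosyncratic (both unit variance)."""
    values = coupling * common.values + (1.0 - coupling) * idio.values
    return LatentArousalTrace(t=common.t.copy(), values=values, fs=common.fs)


# ---------------------------------------------------------------------------
# per-channel generators
# ---------------------------------------------------------------------------

def simulate_ibi_process(config: DyadSimConfig,
                         driver: Optional[LatentArousalTrace] = None,
                         rng=None) -> IbiSeries:
    """Generate beat times whose interval fluctuations live in 0.04–0.4 Hz.

    The inter-beat interval at time ``t`` is the condition-adjusted mean
    plus an intrinsic band-limited fluctuation (SD ``ibi_sd_ms``) minus
    ``arousal_ibi_gain_ms`` times the arousal driver — higher arousal
    shortens the interval (faster heart rate).
    """
    rng = _rng(config.seed if rng is None else rng)
    mean_eff = config.mean_ibi_ms + IBI_CONDITION_OFFSET_MS[config.valence_condition]
    if mean_eff <= 0:
        raise ValueError("effective mean IBI must be positive")

    fs_mod = DRIVER_FS
    n_mod = max(int(round(config.duration_s * fs_mod)), 16)
    t_mod = np.arange(n_mod) / fs_mod
    if config.ibi_sd_ms > 0:
        hrv = band_limited_noise(n_mod, fs_mod, 0.04, 0.4, rng) * config.ibi_sd_ms
    else:
        hrv = np.zeros(n_mod)
    if driver is not None:
        hrv = hrv - config.arousal_ibi_gain_ms * driver.interp(t_mod)

    ibis = []
    peaks = [0.0]
    t = 0.0
    floor = 0.3 * mean_eff
    while t < config.duration_s:
        ibi_ms = mean_eff + np.interp(t, t_mod, hrv)
        ibi_ms = max(ibi_ms, floor)
        ibis.append(ibi_ms)
        t += ibi_ms / 1000.0
        peaks.append(t)
    return IbiSeries(peak_times=np.array(peaks), ibis_ms=np.array(ibis))


def qrs_pulse(fs: float, sigma_s: float = QRS_SIGMA_S) -> np.ndarray:
    """Mexican-hat (biphasic) QRS-like pulse, peak amplitude 1, ~80 ms wide."""
    half = int(round(3.0 * sigma_s * fs))
    if half < 2:
        raise ValueError(f"sampling rate {fs} Hz too low to represent an 80 ms QRS pulse")
    t = np.arange(-half, half + 1) / fs
    u = (t / sigma_s) ** 2
    return (1.0 - u) * np.exp(-u / 2.0)


def simulate_ecg(ibi: IbiSeries, fs: float, noise_sd: float = 0.0,
                 seed=None) -> tuple[SignalRecording, np.ndarray]:
    """Synthesize an ECG-like waveform with known R-peak times.

    Each beat is a Mexican-hat pulse placed at the nearest sample to the
    generating beat time; the returned ground-truth times are the
    sample-aligned placements, so the waveform argmax of each beat sits
    exactly on the truth in the noiseless case.
    """
    if fs < 100:
        raise ValueError("ECG synthesis requires fs >= 100 Hz")
    rng = _rng(seed)
    pulse = qrs_pulse(fs)
    half = (pulse.size - 1) // 2
    n = int(round((ibi.peak_times[-1]) * fs)) + half + int(0.3 * fs)
    x = np.zeros(n)
    truth = []
    for pt in ibi.peak_times:
        idx = int(round(pt * fs))
        lo, hi = idx - half, idx + half + 1
        if lo < 0 or hi > n:
            continue
        x[lo:hi] += pulse
        truth.append(idx / fs)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=n)
    rec = SignalRecording(channel="ecg", fs=fs, samples=x)
    return rec, np.array(truth)


def noise_sd_for_snr(signal: np.ndarray, snr_db: float) -> float:
    """Noise SD giving the requested signal-to-noise ratio in dB."""
    p_signal = float(np.mean(np.square(signal - signal.mean())))
    return float(np.sqrt(p_signal / (10.0 ** (snr_db / 10.0))))


def simulate_respiration(config: DyadSimConfig,
                         driver: Optional[LatentArousalTrace] = None,
                         rng=None) -> tuple[SignalRecording, np.ndarray]:
    """Slow tidal-volume-like oscillation with known expiration onsets.

    The chest trace is a phase oscillator whose instantaneous rate
    wanders around the configured breaths-per-minute (multiplicative
    jitter plus an additive arousal term).  Expiration onsets are the
    signal's local maxima (maximal chest circumference); their times are
    returned as ground truth.
    """
    rng = _rng(config.seed if rng is None else rng)
    rate_eff = config.rsp_rate_bpm + RSP_CONDITION_OFFSET_BPM[config.valence_condition]
    if not 5.0 < rate_eff < 60.0:
        raise ValueError(f"respiratory rate {rate_eff}/min outside plausible range (5, 60)")
    fs = config.fs_rsp
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs

    fs_mod = DRIVER_FS
    n_mod = max(int(round(config.duration_s * fs_mod)), 16)
    t_mod = np.arange(n_mod) / fs_mod
    rate_mod = np.full(n_mod, rate_eff)
    if config.rsp_rate_jitter > 0:
        rate_mod = rate_mod * (1.0 + config.rsp_rate_jitter
                               * band_limited_noise(n_mod, fs_mod, 0.005, 0.05, rng))
    if driver is not None:
        rate_mod = rate_mod + config.arousal_rsp_gain_bpm * driver.interp(t_mod)
    rate_inst = np.clip(np.interp(t, t_mod, rate_mod), 1.0, 80.0)

    phase = 2.0 * np.pi * np.cumsum(rate_inst / 60.0) / fs
    x = config.rsp_amplitude_mcv * np.sin(phase)
    if config.rsp_noise_mcv > 0:
        x = x + rng.normal(0.0, config.rsp_noise_mcv, size=n)

    # ground-truth onsets: phase crossings of pi/2 + 2*pi*k (sin maxima)
    k = np.floor((phase - np.pi / 2.0) / (2.0 * np.pi))
    crossings = np.flatnonzero(np.diff(k) > 0) + 1
    onsets = t[crossings]
    if phase[0] >= np.pi / 2.0:  # pragma: no cover - phase starts at ~0
        onsets = np.insert(onsets, 0, 0.0)
    rec = SignalRecording(channel="rsp", fs=fs, samples=x)
    return rec, onsets


def scr_kernel(fs: float, rise_s: float = 0.75, decay_s: float = 2.0,
               length_s: float = 10.0) -> np.ndarray:
    """Skin-conductance-response shape: difference of exponentials, peak 1."""
    t = np.arange(int(length_s * fs)) / fs
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    return k / k.max()


def simulate_sc(config: DyadSimConfig,
                driver: Optional[LatentArousalTrace] = None,
                rng=None) -> tuple[SignalRecording, np.ndarray]:
    """Skin conductance: tonic level + drift + discrete SCR events.

    SCR events arrive as an inhomogeneous Poisson process whose rate
    increases with the arousal driver; each event adds a two-exponential
    kernel (0.75 s rise, 2 s decay) with lognormal amplitude.  Event
    times are returned as ground truth.
    """
    rng = _rng(config.seed if rng is None else rng)
    level_eff = config.sc_tonic_level_us + SC_CONDITION_OFFSET_US[config.valence_condition]
    fs = config.fs_sc
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs

    x = np.full(n, level_eff)
    # slow tonic drift; recordings shorter than one drift cycle skip it
    if config.sc_drift_us > 0 and n >= 64 and config.duration_s >= 120.0:
        fs_mod = DRIVER_FS
        n_mod = max(int(round(config.duration_s * fs_mod)), 64)
        f_lo = max(0.002, 1.0 / config.duration_s)
        f_hi = max(0.01, 2.5 / config.duration_s)
        drift = band_limited_noise(n_mod, fs_mod, f_lo, f_hi, rng) * config.sc_drift_us
        x = x + np.interp(t, np.arange(n_mod) / fs_mod, drift)

    # event times by per-second Poisson thinning against the driver-modulated rate
    events = []
    base = config.scr_rate_per_min / 60.0
    if base > 0:
        n_bins = int(np.ceil(config.duration_s))
        for b in range(n_bins):
            tb = min(b + 0.5, config.duration_s)
            lam = base
            if driver is not None:
                lam = max(0.0, base * (1.0 + config.scr_arousal_gain
                                       * float(driver.interp(np.array([tb]))[0])))
            width = min(1.0, config.duration_s - b)
            count = rng.poisson(lam * width)
            events.extend(b + rng.uniform(0.0, width, size=count))
    events = np.sort(np.array(events))

    if events.size:
        kernel = scr_kernel(fs)
        amps = config.scr_amp_us * rng.lognormal(mean=0.0, sigma=0.4, size=events.size)
        for et, amp in zip(events, amps):
            idx = int(round(et * fs))
            hi = min(idx + kernel.size, n)
            if idx < n:
                x[idx:hi] += amp * kernel[: hi - idx]
    if config.sc_noise_us > 0:
        x = x + rng.normal(0.0, config.sc_noise_us, size=n)
    rec = SignalRecording(channel="sc", fs=fs, samples=x)
    return rec, events


# ---------------------------------------------------------------------------
# session-level generation
# ---------------------------------------------------------------------------

def simulate_dyad_session(config: DyadSimConfig,
                          channels: Sequence[str] = ("ecg", "rsp", "sc"),
                          effect_params: Optional[RatingEffectParams] = None,
                          dyad_id: str = "dyad000") -> DyadSession:
    """Simulate one dyad: two members × three videos plus ratings.

    The three valence conditions are presented in a seeded random order.
    Per video, one common arousal driver is mixed into each member's
    driver by ``config.coupling``.  ``channels`` selects which waveforms
    to synthesize (the beat-time / IBI ground truth is always produced;
    pass an empty tuple for a fast ratings-and-IBI-only session).
    """
    params = effect_params or RatingEffectParams()
    ss = np.random.SeedSequence(config.seed)
    rng_order, rng_ratings, rng_videos = (np.random.default_rng(s) for s in ss.spawn(3))
    conditions = [str(c) for c in rng_order.permutation(CONDITIONS)]

    session = DyadSession(dyad_id=dyad_id, attention=config.attention,
                          video_conditions=conditions, config=config)
    for v, cond in enumerate(conditions):
        cfg_v = config.for_condition(cond)
        rng_common = np.random.default_rng(rng_videos.integers(2 ** 31))
        member_rngs = [np.random.default_rng(rng_videos.integers(2 ** 31)) for _ in range(2)]
        common = make_driver(config.duration_s, rng_common)
        for m, rng_m in enumerate(member_rngs):
            idio = make_driver(config.duration_s, rng_m)
            drv = mix_drivers(common, idio, config.coupling)
            ibi = simulate_ibi_process(cfg_v, driver=drv, rng=rng_m)
            mv = MemberVideoData(driver=drv)
            mv.truth["ibi"] = ibi
            mv.truth["mean_ibi_ms"] = float(ibi.ibis_ms.mean())
            if "ecg" in channels:
                ecg, r_truth = simulate_ecg(ibi, cfg_v.fs_ecg, noise_sd=cfg_v.ecg_noise_mv,
                                            seed=rng_m)
                mv.recordings["ecg"] = ecg
                mv.truth["r_peak_times_s"] = r_truth
            if "rsp" in channels:
                rsp, onsets = simulate_respiration(cfg_v, driver=drv, rng=rng_m)
                mv.recordings["rsp"] = rsp
                mv.truth["expiration_onsets_s"] = onsets
            if "sc" in channels:
                sc, scr_times = simulate_sc(cfg_v, driver=drv, rng=rng_m)
                mv.recordings["sc"] = sc
                mv.truth["scr_times_s"] = scr_times
            session.data[(m, v)] = mv

    simulate_ratings(session, params, rng_ratings)
    return session


def simulate_ratings(session: DyadSession, params: RatingEffectParams,
                     seed=None) -> DyadSession:
    """Attach Likert ratings and t0/t1 social attitudes to a session.

    Stores the generating latents (per-video dyad arousal deviation,
    slopes, condition bases) in ``session.latent`` for recovery tests.
    """
    rng = _rng(seed)
    attention = session.attention
    rating_rows = []
    d_video = {}
    conn_latents = []
    dyad_re = rng.normal(0.0, params.dyad_sd)
    for v, cond in enumerate(session.video_conditions):
        d_v = rng.standard_normal()
        d_video[v] = d_v
        for m in range(2):
            val = params.valence_means[cond] + rng.normal(0.0, params.valence_noise_sd)
            aro = (params.arousal_means[cond] + params.arousal_coupling * d_v
                   + rng.normal(0.0, params.arousal_noise_sd))
            conn = (params.connect_means[cond]
                    + params.connect_arousal_slope[attention] * d_v
                    + dyad_re + rng.normal(0.0, params.connect_noise_sd))
            conn_latents.append(conn)
            items = [_likert(conn + rng.normal(0.0, params.connect_item_sd), 7)
                     for _ in range(4)]
            rating_rows.append({
                "member": m, "video": v, "condition": cond,
                "valence": _likert(val, 9), "arousal": _likert(aro, 9),
                **{f"connect_{i + 1}": it for i, it in enumerate(items)},
                "connectedness": float(np.mean(items)),
            })
    attitude_rows = []
    for m in range(2):
        ident_t0 = params.attitude_t0_mean + rng.normal(0.0, params.attitude_noise_sd)
        desire_t0 = params.attitude_t0_mean + rng.normal(0.0, params.attitude_noise_sd)
        bond = params.bonding_gain * (np.mean(conn_latents) - params.connect_means["neutral"])
        ident_t1 = ident_t0 + bond + rng.normal(0.0, 0.3)
        desire_t1 = desire_t0 + bond + rng.normal(0.0, 0.3)
        desire_items_t0 = [_likert(desire_t0 + rng.normal(0.0, params.attitude_item_sd), 7)
                           for _ in range(7)]
        desire_items_t1 = [_likert(desire_t1 + rng.normal(0.0, params.attitude_item_sd), 7)
                           for _ in range(7)]
        attitude_rows.append({
            "member": m,
            "identification_t0": _likert(ident_t0, 7),
            "identification_t1": _likert(ident_t1, 7),
            "desire_t0": float(np.mean(desire_items_t0)),
            "desire_t1": float(np.mean(desire_items_t1)),
        })
    session.ratings = pd.DataFrame(rating_rows)
    session.attitudes = pd.DataFrame(attitude_rows)
    session.latent = {
        "d_video": d_video,
        "dyad_re": dyad_re,
        "connect_arousal_slope": dict(params.connect_arousal_slope),
        "connect_means": dict(params.connect_means),
        "params": params,
    }
    return session


def _likert(latent: float, top: int) -> int:
    """Round a latent Gaussian to the integer Likert scale [1, top]."""
    return int(np.clip(np.rint(latent), 1, top))


def simulate_study(n_dyads: int, base_config: DyadSimConfig,
                   channels: Sequence[str] = ("ecg", "rsp", "sc"),
                   effect_params: Optional[RatingEffectParams] = None,
                   seed: Optional[int] = None) -> list[DyadSession]:
    """Simulate ``n_dyads`` sessions, alternating joint/disjoint attention.

    Per-dyad seeds are spawned from ``seed`` (default: the base config's
    seed), so the study is reproducible as a whole.
    """
    master = base_config.seed if seed is None else seed
    child_seeds = np.random.SeedSequence(master).generate_state(n_dyads) % (2 ** 31)
    sessions = []
    for d in range(n_dyads):
        cfg = replace(base_config, seed=int(child_seeds[d]),
                      attention=ATTENTION_LEVELS[d % 2])
        sessions.append(simulate_dyad_session(cfg, channels=channels,
                                              effect_params=effect_params,
                                              dyad_id=f"dyad{d:03d}"))
    return sessions
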