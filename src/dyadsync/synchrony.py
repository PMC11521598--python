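"""Interpersonal physiological synchrony by wavelet transform coherence.

The coherence follows the classic smoothed-cross-spectrum construction:
continuous Morlet wavelet transforms over logarithmically spaced scales,
a Gaussian smoothing in time (SD = scale/sqrt(2)) and a boxcar smoothing
over 0.6 octaves in scale, then

    R^2(s, t) = |S(W_xy / s)|^2 / ( S(|W_x|^2 / s) * S(|W_y|^2 / s) )

which is bounded in [0, 1] by the Cauchy–Schwarz inequality.  Cells
closer to either edge than the e-folding distance sqrt(2)*scale lie in
the cone of influence (COI) and are excluded from every average.

A :class:`WtcEngine` caches the per-signal transforms so that the
surrogate-dyad bootstrap — which pairs every individual with every
individual from other dyads — only pays the cross-spectrum smoothing
per pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import fft as sfft
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .types import DyadSession

LF_BAND_HZ = (0.05, 0.15)
HF_BAND_HZ = (0.15, 0.4)
BAND_RANGES = {"lf": LF_BAND_HZ, "hf": HF_BAND_HZ}
CHANNEL_TRACE_FS = {"ibi": 20.0, "rsp": 10.0, "sc": 10.0}


@dataclass
class WtcConfig:
    """Morlet / smoothing configuration for wavelet coherence.

    ``wavelet_omega0`` is the Morlet centre frequency (6 gives the usual
    time/frequency trade-off), ``voices_per_octave`` the scale
    resolution; ``min_scale_s`` defaults to 2/fs and ``max_scale_s`` to
    a quarter of the record length.  ``squared=False`` averages the
    square root of the magnitude-squared coherence instead.
    """

    wavelet_omega0: float = 6.0
    voices_per_octave: int = 12
    min_scale_s: Optional[float] = None
    max_scale_s: Optional[float] = None
    time_smooth_sd_scale: float = 1.0 / np.sqrt(2.0)
    scale_smooth_octaves: float = 0.6
    coi_efold: float = np.sqrt(2.0)
    squared: bool = True

    def __post_init__(self) -> None:
        if self.voices_per_octave < 4:
            raise ValueError("voices_per_octave must be >= 4")

    @property
    def fourier_factor(self) -> float:
        """Equivalent Fourier period per unit scale for the Morlet wavelet."""
        w0 = self.wavelet_omega0
        return 4.0 * np.pi / (w0 + np.sqrt(2.0 + w0 ** 2))


@dataclass
class WtcMap:
    """Time × frequency magnitude-squared coherence with COI mask.

    ``coi_mask`` is True where the cell is *usable* (inside the cone of
    valid data, i.e. far enough from the edges).
    """

    times: np.ndarray
    freqs: np.ndarray
    scales: np.ndarray
    coherence: np.ndarray
    coi_mask: np.ndarray


@dataclass
class SynchronyScalar:
    """One dyad-level synchrony value."""

    value: float
    band: str
    method: str = "wtc"
    channel: str = ""
    dyad_id: str = ""
    video: int = -1
    n_cells: int = 0


class WtcEngine:
    """Precomputed Morlet transform + smoothing machinery for fixed (n, fs).

    ``freq_band`` optionally restricts the scale axis to the band of
    interest (plus a margin covering the scale-smoothing window), which
    makes large surrogate-pair sweeps tractable.
    """

    def __init__(self, n: int, fs: float, cfg: Optional[WtcConfig] = None,
                 freq_band: Optional[tuple] = None, decimate: object = 1):
        if n < 64:
            raise ValueError("wavelet coherence requires at least 64 samples")
        self.cfg = cfg or WtcConfig()
        self.n = int(n)
        self.fs = float(fs)
        dt = 1.0 / fs
        c = self.cfg

        s0 = c.min_scale_s if c.min_scale_s is not None else 2.0 * dt
        smax = c.max_scale_s if c.max_scale_s is not None else (n * dt) / 4.0
        if smax <= s0:
            raise ValueError("max scale must exceed min scale; record too short")
        dj = 1.0 / c.voices_per_octave
        n_scales = int(np.floor(np.log2(smax / s0) / dj)) + 1
        scales = s0 * 2.0 ** (dj * np.arange(n_scales))
        freqs = 1.0 / (c.fourier_factor * scales)

        self._band_rows = np.ones(n_scales, dtype=bool)
        if freq_band is not None:
            f_lo, f_hi = freq_band
            margin = 2.0 ** (c.scale_smooth_octaves / 2.0 + 2.0 * dj)
            keep = (freqs >= f_lo / margin) & (freqs <= f_hi * margin)
            if not keep.any():
                raise ValueError(f"no scales inside band {freq_band} Hz")
            scales, freqs = scales[keep], freqs[keep]
            self._band_rows = np.ones(scales.size, dtype=bool)
        self.scales = scales
        self.freqs = freqs

        # Morlet daughters in the Fourier domain (analytic: positive freqs only)
        self.nfft = sfft.next_fast_len(2 * n)
        omega = 2.0 * np.pi * np.fft.fftfreq(self.nfft, d=dt)
        w0 = c.wavelet_omega0
        norm = (np.pi ** -0.25) * np.sqrt(2.0 * np.pi * scales[:, None] / dt)
        arg = scales[:, None] * omega[None, :]
        self._daughters = np.where(omega[None, :] > 0,
                                   norm * np.exp(-0.5 * (arg - w0) ** 2), 0.0)

        # Optional spectral-fold decimation of the time axis.  The wavelet
        # coefficients at the retained scales are band-limited (analytic
        # Morlet content sits near each scale's centre frequency), so
        # evaluating the inverse transform on a coarser grid is exact as
        # long as the decimated Nyquist clears the highest represented
        # frequency with margin.  Used by the surrogate bootstrap where
        # thousands of low-frequency pairs must be smoothed.
        if decimate == "auto":
            f_top = float(freqs.max()) * (1.0 + 6.0 / c.wavelet_omega0)
            q = 1
            for cand in range(int(self.fs / (4.0 * f_top)), 1, -1):
                if self.nfft % cand == 0:
                    q = cand
                    break
        else:
            q = int(decimate)
            if q > 1 and self.nfft % q != 0:
                raise ValueError(f"decimation {q} must divide the FFT length {self.nfft}")
        self.q = q
        self.m = self.nfft // q                       # decimated padded length
        self.n_dec = (n - 1) // q + 1                 # retained time samples
        self.dt_dec = dt * q
        self.times = np.arange(self.n_dec) * self.dt_dec

        # Gaussian time-smoothing kernels in the (decimated) Fourier domain
        self.nfft_s = sfft.next_fast_len(2 * self.n_dec)
        omega_s = 2.0 * np.pi * np.fft.fftfreq(self.nfft_s, d=self.dt_dec)
        sd = c.time_smooth_sd_scale * scales[:, None]
        self._smooth_kernels = np.exp(-0.5 * (sd * omega_s[None, :]) ** 2)
        self._scale_win = max(1, int(round(c.scale_smooth_octaves * c.voices_per_octave)))

        # usable-cell mask: at least coi_efold * scale away from both edges
        t_end = (n - 1) * dt
        edge = np.minimum(self.times[None, :], t_end - self.times[None, :])
        self.coi_mask = edge >= (c.coi_efold * scales[:, None])

    # -- building blocks -------------------------------------------------

    def cwt(self, x: np.ndarray) -> np.ndarray:
        """Morlet CWT coefficients, shape (n_scales, n_dec)."""
        x = np.asarray(x, dtype=float)
        if x.size != self.n:
            raise ValueError(f"expected {self.n} samples, got {x.size}")
        if not np.all(np.isfinite(x)):
            raise ValueError("input contains non-finite values")
        xf = sfft.fft(x - x.mean(), self.nfft)
        prod = xf[None, :] * self._daughters
        if self.q > 1:
            # spectral folding == exact time decimation for band-limited fields
            prod = prod.reshape(prod.shape[0], self.q, self.m).sum(axis=1) / self.q
        return sfft.ifft(prod, axis=1)[:, : self.n_dec]

    def _smooth(self, field2d: np.ndarray) -> np.ndarray:
        """Gaussian-in-time then boxcar-in-scale smoothing."""
        f = sfft.fft(field2d, self.nfft_s, axis=1)
        out = sfft.ifft(f * self._smooth_kernels, axis=1)[:, : self.n_dec]
        if not np.iscomplexobj(field2d):
            out = out.real
        if self._scale_win > 1:
            if np.iscomplexobj(out):
                out = (uniform_filter1d(out.real, self._scale_win, axis=0, mode="nearest")
                       + 1j * uniform_filter1d(out.imag, self._scale_win, axis=0,
                                               mode="nearest"))
            else:
                out = uniform_filter1d(out, self._scale_win, axis=0, mode="nearest")
        return out

    def spectrum(self, x: np.ndarray):
        """Per-signal cache: (W, smoothed |W|^2 / s)."""
        if np.std(x) == 0:
            raise ValueError("undefined coherence: constant input has zero auto-spectrum")
        W = self.cwt(x)
        S = self._smooth(np.abs(W) ** 2 / self.scales[:, None])
        return W, np.maximum(S, 0.0)

    def coherence_from(self, Wx: np.ndarray, Sx: np.ndarray,
                       Wy: np.ndarray, Sy: np.ndarray) -> np.ndarray:
        Sxy = self._smooth(Wx * np.conj(Wy) / self.scales[:, None])
        den = Sx * Sy
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.abs(Sxy) ** 2 / den
        r2 = np.where(den > 0, r2, np.nan)
        return np.clip(r2, 0.0, 1.0)

    def band_mean(self, coherence: np.ndarray, band_hz: Optional[tuple]) -> tuple:
        """Mean coherence over usable (COI) cells inside a band."""
        rows = np.ones(self.freqs.size, dtype=bool)
        if band_hz is not None:
            rows = (self.freqs >= band_hz[0]) & (self.freqs <= band_hz[1])
            if not rows.any():
                raise ValueError(f"band {band_hz} Hz entirely outside the map range")
        use = self.coi_mask[rows] & np.isfinite(coherence[rows])
        vals = coherence[rows][use]
        if vals.size == 0:
            raise ValueError("no usable cells: cone of influence covers the band")
        if not self.cfg.squared:
            vals = np.sqrt(vals)
        return float(vals.mean()), int(vals.size)

    def pair_band_mean(self, spec_x, spec_y, band_hz: Optional[tuple]) -> float:
        r2 = self.coherence_from(spec_x[0], spec_x[1], spec_y[0], spec_y[1])
        return self.band_mean(r2, band_hz)[0]


def cwt_morlet(x: np.ndarray, fs: float, cfg: Optional[WtcConfig] = None):
    """Morlet CWT over logarithmic scales.

    Returns ``(coefficients, scales, freqs)`` with coefficients of shape
    (n_scales, len(x)).
    """
    x = np.asarray(x, dtype=float)
    engine = WtcEngine(x.size, fs, cfg)
    return engine.cwt(x), engine.scales, engine.freqs


def wavelet_coherence(x: np.ndarray, y: np.ndarray, fs: float,
                      cfg: Optional[WtcConfig] = None) -> WtcMap:
    """Magnitude-squared wavelet coherence map of two equal-length signals.

    Symmetric in (x, y) — the inputs are ordered canonically before the
    computation so swapped arguments give a bit-identical map — and
    invariant to separate affine rescaling of either signal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.tobytes() > y.tobytes():
        x, y = y, x
    engine = WtcEngine(x.size, fs, cfg)
    spec_x = engine.spectrum(x)
    spec_y = engine.spectrum(y)
    r2 = engine.coherence_from(spec_x[0], spec_x[1], spec_y[0], spec_y[1])
    return WtcMap(times=engine.times, freqs=engine.freqs, scales=engine.scales,
                  coherence=r2, coi_mask=engine.coi_mask)


def average_synchrony(wtc_map: WtcMap, band: str = "full",
                      band_hz: Optional[tuple] = None,
                      squared: bool = True) -> SynchronyScalar:
    """Time-frequency average of a coherence map, COI cells excluded.

    ``band`` is ``"full"``, ``"lf"`` (0.05–0.15 Hz), ``"hf"``
    (0.15–0.4 Hz) or ``"custom"`` with an explicit ``band_hz`` range.
    """
    if band_hz is None:
        band_hz = BAND_RANGES.get(band)
        if band_hz is None and band != "full":
            raise ValueError(f"unknown band {band!r}")
    rows = np.ones(wtc_map.freqs.size, dtype=bool)
    if band_hz is not None:
        rows = (wtc_map.freqs >= band_hz[0]) & (wtc_map.freqs <= band_hz[1])
        if not rows.any():
            raise ValueError(f"band {band_hz} Hz entirely outside the map range")
    use = wtc_map.coi_mask[rows] & np.isfinite(wtc_map.coherence[rows])
    vals = wtc_map.coherence[rows][use]
    if vals.size == 0:
        raise ValueError("no usable cells inside the cone of influence for this band")
    if not squared:
        vals = np.sqrt(vals)
    return SynchronyScalar(value=float(vals.mean()), band=band, method="wtc",
                           n_cells=int(vals.size))


def correlation_synchrony(x: np.ndarray, y: np.ndarray,
                          method: str = "global_pearson",
                          window_s: float = 30.0,
                          fs: float = 1.0) -> SynchronyScalar:
    """Correlational synchrony: |Pearson r|, global or windowed.

    ``windowed_abs_r`` averages |r| over non-overlapping windows;
    zero-variance windows are skipped (and counted in ``n_cells`` as
    the number of contributing windows).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if method == "global_pearson":
        if x.std() == 0 or y.std() == 0:
            raise ValueError("zero-variance input: correlation undefined")
        r = float(np.corrcoef(x, y)[0, 1])
        return SynchronyScalar(value=abs(r), band="full", method=method, n_cells=x.size)
    if method != "windowed_abs_r":
        raise ValueError(f"unknown method {method!r}")
    win = max(2, int(round(window_s * fs)))
    rs = []
    for start in range(0, x.size - win + 1, win):
        xs, ys = x[start:start + win], y[start:start + win]
        if xs.std() == 0 or ys.std() == 0:
            continue
        rs.append(abs(float(np.corrcoef(xs, ys)[0, 1])))
    if not rs:
        raise ValueError("all windows degenerate: correlation undefined")
    return SynchronyScalar(value=float(np.mean(rs)), band="full",
                           method=method, n_cells=len(rs))


# ---------------------------------------------------------------------------
# session traces and the surrogate-dyad null
# ---------------------------------------------------------------------------

def member_trace(session: DyadSession, member: int, video: int,
                 channel: str = "ibi") -> tuple:
    """Analysis-ready trace for one member and video.

    ``ibi`` uses the 20 Hz interpolated band-passed inter-beat-interval
    trace (built from the session's beat times); ``rsp`` and ``sc`` are
    mean-removed recordings decimated to 10 Hz (``sc`` phasic-filtered
    first).  Returns ``(trace, fs)``.
    """
    from . import preprocess

    mv = session.data[(member, video)]
    if channel == "ibi":
        ibi = mv.truth.get("ibi")
        if ibi is not None:
            peaks = ibi.peak_times
        else:
            peaks = mv.truth.get("ibi_peak_times_s", mv.truth.get("r_peak_times_s"))
            peaks = np.asarray(peaks, dtype=float)
        series = preprocess.build_ibi(peaks)
        return series.interp_trace, series.interp_fs
    rec = mv.recordings[channel]
    target_fs = CHANNEL_TRACE_FS[channel]
    if channel == "sc":
        rec = preprocess.extract_phasic_sc(rec)
    q = int(round(rec.fs / target_fs))
    if q > 1:
        x = sps.decimate(rec.samples, q, ftype="fir", zero_phase=True)
    else:
        x = rec.samples
    return x - x.mean(), rec.fs / max(q, 1)


@dataclass
class SurrogateNullResult:
    """Real-vs-surrogate synchrony comparison with a bootstrap null."""

    statistic: float
    p_value: float
    real_values: np.ndarray
    surrogate_values: np.ndarray
    null_distribution: np.ndarray
    n_real: int
    n_surrogate_pairs: int
    seed: Optional[int] = None


def surrogate_null(sessions: Sequence[DyadSession], channel: str = "ibi",
                   band: str = "lf", n_boot: int = 1000, seed=None,
                   cfg: Optional[WtcConfig] = None,
                   band_hz: Optional[tuple] = None) -> SurrogateNullResult:
    """Surrogate-dyad bootstrap test of real synchrony.

    Surrogate pairs are all cross-dyad pairings of individuals matched
    on attention condition and video identity (valence condition).  The
    statistic is mean(real synchrony) − mean(surrogate synchrony).  The
    null distribution resamples the surrogate pairings ``n_boot`` times
    as random vertex-disjoint cross-dyad matchings of the individuals —
    the same dependence structure as the real pairing — and the
    two-sided p-value is the fraction of resampled statistics at least
    as extreme as the observed one.
    """
    if len(sessions) < 3:
        raise ValueError("surrogate null requires at least 3 dyads")
    rng = np.random.default_rng(seed)
    if band_hz is None:
        band_hz = BAND_RANGES.get(band)

    # group individuals by (attention, condition); note each session
    # presents each condition exactly once, at a session-specific position
    groups: dict = {}
    for session in sessions:
        for v, cond in enumerate(session.video_conditions):
            for m in range(2):
                trace, fs = member_trace(session, m, v, channel)
                groups.setdefault((session.attention, cond), []).append(
                    (session.dyad_id, trace, fs))

    real_vals, surr_vals = [], []
    n_surr_pairs = 0
    group_data = []  # (pair-value matrix, dyad ids) per group, for the matchings
    for key, members in groups.items():
        dyads = {d for d, _, _ in members}
        if len(dyads) < 3:
            raise ValueError(
                f"group {key} has {len(dyads)} dyads; the surrogate null needs >= 3")
        n_min = min(t.size for _, t, _ in members)
        fs = members[0][2]
        engine = WtcEngine(n_min, fs, cfg, freq_band=band_hz,
                           decimate="auto" if band_hz is not None else 1)
        specs = [(d, engine.spectrum(t[:n_min])) for d, t, _ in members]
        k = len(specs)
        values = np.full((k, k), np.nan)
        for i in range(k):
            for j in range(i + 1, k):
                v = engine.pair_band_mean(specs[i][1], specs[j][1], band_hz)
                values[i, j] = values[j, i] = v
                if specs[i][0] == specs[j][0]:
                    real_vals.append(v)
                else:
                    surr_vals.append(v)
                    n_surr_pairs += 1
        group_data.append((values, [d for d, _ in specs]))

    real_vals = np.asarray(real_vals)
    surr_vals = np.asarray(surr_vals)
    surr_mean = surr_vals.mean()
    stat = float(real_vals.mean() - surr_mean)

    boots = np.empty(n_boot)
    for b in range(n_boot):
        acc, count = 0.0, 0
        for values, dyad_ids in group_data:
            k = values.shape[0]
            perm = rng.permutation(k)
            for a, bb in zip(perm[0::2], perm[1::2]):
                acc += values[a, bb]
                count += 1
        boots[b] = acc / count - surr_mean
    p = float((1 + np.sum(np.abs(boots) >= abs(stat))) / (n_boot + 1))
    return SurrogateNullResult(statistic=stat, p_value=p, real_values=real_vals,
                               surrogate_values=surr_vals, null_distribution=boots,
                               n_real=real_vals.size, n_surrogate_pairs=n_surr_pairs,
                               seed=seed)
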