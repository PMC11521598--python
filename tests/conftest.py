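"""Shared fixtures: small synthetic recordings and sessions."""

import numpy as np
import pytest

from dyadsync import preprocess as pp
from dyadsync import simulate
from dyadsync.types import DyadSession, MemberVideoData


@pytest.fixture(scope="session")
def short_config():
    """60 s dyad config at modest sampling rates (fast unit tests)."""
    return simulate.DyadSimConfig(duration_s=60.0, fs_ecg=500.0, fs_rsp=50.0,
                                  fs_sc=50.0, seed=12345)


@pytest.fixture(scope="session")
def small_session(short_config):
    return simulate.simulate_dyad_session(short_config)


def one_video_ibi_sessions(n_dyads: int, coupling: float, seed: int,
                           duration_s: float = 300.0,
                           attention: str = "joint",
                           condition: str = "neutral") -> list:
    """Minimal sessions (one video, IBI ground truth only) for synchrony tests.

    Builds the latent-driver mixing and the beat-time generation through
    the public generator API, skipping waveform synthesis and ratings.
    """
    sessions = []
    ss = np.random.SeedSequence(seed)
    for d, child in enumerate(ss.spawn(n_dyads)):
        rng_c, rng_0, rng_1 = (np.random.default_rng(s) for s in child.spawn(3))
        cfg = simulate.DyadSimConfig(duration_s=duration_s, coupling=coupling,
                                     attention=attention, valence_condition=condition,
                                     seed=0)
        common = simulate.make_driver(duration_s, rng_c)
        session = DyadSession(dyad_id=f"dyad{d:03d}", attention=attention,
                              video_conditions=[condition], config=cfg)
        for m, rng_m in enumerate((rng_0, rng_1)):
            drv = simulate.mix_drivers(common, simulate.make_driver(duration_s, rng_m),
                                       coupling)
            ibi = simulate.simulate_ibi_process(cfg, driver=drv, rng=rng_m)
            mv = MemberVideoData(driver=drv)
            mv.truth["ibi"] = ibi
            session.data[(m, 0)] = mv
        sessions.append(session)
    return sessions


def detection_metrics(detected: np.ndarray, truth: np.ndarray, tol_s: float):
    """Sensitivity and precision of event detection with a time tolerance."""
    if detected.size == 0 or truth.size == 0:
        return 0.0, 0.0
    d = np.abs(detected[:, None] - truth[None, :])
    tp_det = np.sum(d.min(axis=1) <= tol_s)
    tp_truth = np.sum(d.min(axis=0) <= tol_s)
    return tp_truth / truth.size, tp_det / detected.size


@pytest.fixture(scope="session")
def noiseless_ecg_truth():
    cfg = simulate.DyadSimConfig(duration_s=60.0, seed=3)
    ibi = simulate.simulate_ibi_process(cfg)
    ecg, truth = simulate.simulate_ecg(ibi, 1000.0)
    filtered = pp.bandpass(ecg, 1.0, 100.0, order=4)
    return ibi, ecg, filtered, truth
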