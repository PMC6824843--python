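"""EMG and hand-kinematics preprocessing for the behavioral controls.

EMG: 6th-order Butterworth band-pass 20-200 Hz, full-wave rectification,
6th-order low-pass at 100 Hz; all stages zero-phase (forward-backward).
Epoch statistics use the last 200 ms before the load (baseline) and the first
300 ms after (perturbation), with a two-way ANOVA (epoch x load combination)
per muscle.

Kinematics: positions low-passed with a 3rd-order 10 Hz Butterworth filter;
hand speed integrated (trapezoid) over 0-300 ms after the perturbation; the
perturbed:unperturbed ratio quantifies how much more the loaded limb moves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "EmgEnvelope",
    "process_emg",
    "EmgEpochStats",
    "emg_epoch_stats",
    "integrated_hand_speed",
]

ALPHA = 0.05


@dataclass
class EmgEnvelope:
    muscle: str
    envelope: np.ndarray  # (n_trials, T) or (T,), non-negative
    rate_hz: float


def _band_sos(fs: float):
    # butter order 3 band-pass = 6th-order filter overall
    return butter(3, [20.0, 200.0], btype="bandpass", fs=fs, output="sos")


def _low_sos(fs: float):
    return butter(6, 100.0, btype="lowpass", fs=fs, output="sos")


def process_emg(raw: np.ndarray, fs: float = 1000.0, muscle: str = "") -> EmgEnvelope:
    """Filter chain: band-pass 20-200 Hz, rectify, low-pass 100 Hz.

    ``raw`` is (T,) or (n_trials, T) at sampling rate ``fs`` (> 400 Hz so the
    200 Hz band edge is below Nyquist).  Filtering is zero-phase.
    """
    raw = np.atleast_2d(np.asarray(raw, float))
    if fs <= 400:
        raise ValueError("sampling rate must exceed 400 Hz")
    min_len = 3 * 3 * (2 * 6 + 1)  # ~3 filter lengths for stable filtfilt padding
    if raw.shape[1] < min_len:
        raise ValueError(
            f"series length {raw.shape[1]} too short for zero-phase filtering "
            f"(need >= {min_len} samples)"
        )
    band = sosfiltfilt(_band_sos(fs), raw, axis=1)
    rect = np.abs(band)
    env = sosfiltfilt(_low_sos(fs), rect, axis=1)
    return EmgEnvelope(muscle=muscle, envelope=np.squeeze(env), rate_hz=fs)


@dataclass
class EmgEpochStats:
    muscle: str
    baseline_rms: float
    perturbation_rms: float
    p_epoch: float
    p_interaction: float
    significant: bool
    per_trial_means: pd.DataFrame  # columns: trial, load, epoch, mean


def emg_epoch_stats(
    envelope: np.ndarray,
    load_indices: np.ndarray,
    perturb_index: int,
    fs: float = 1000.0,
    muscle: str = "",
) -> EmgEpochStats:
    """Epoch RMS and the two-way epoch x load ANOVA for one muscle.

    ``envelope``: (n_trials, T) trial-aligned envelopes; ``load_indices``:
    per-trial load combination (0-7); ``perturb_index``: sample of load
    onset.  Significant if the epoch main effect or the interaction has
    p < 0.05.
    """
    env = np.asarray(envelope, float)
    loads = np.asarray(load_indices, int)
    if env.ndim != 2 or env.shape[0] != loads.size:
        raise ValueError("envelope must be (n_trials, T) matching load_indices")
    b = int(round(0.2 * fs))
    p = int(round(0.3 * fs))
    if perturb_index - b < 0 or perturb_index + p > env.shape[1]:
        raise ValueError("epoch windows fall outside the recorded span")
    base = env[:, perturb_index - b : perturb_index]
    pert = env[:, perturb_index : perturb_index + p]
    for li in range(8):
        if not np.any(loads == li):
            raise ValueError(f"empty cell: no trials for load {li}")
    recs = []
    for i in range(env.shape[0]):
        recs.append((i, loads[i], "baseline", base[i].mean()))
        recs.append((i, loads[i], "perturbation", pert[i].mean()))
    df = pd.DataFrame(recs, columns=["trial", "load", "epoch", "mean"])
    model = smf.ols("mean ~ C(epoch) * C(load)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    p_epoch = float(table["PR(>F)"]["C(epoch)"])
    p_inter = float(table["PR(>F)"]["C(epoch):C(load)"])
    return EmgEpochStats(
        muscle=muscle,
        baseline_rms=float(np.sqrt(np.mean(base**2))),
        perturbation_rms=float(np.sqrt(np.mean(pert**2))),
        p_epoch=p_epoch,
        p_interaction=p_inter,
        significant=bool(p_epoch < ALPHA or p_inter < ALPHA),
        per_trial_means=df,
    )


def integrated_hand_speed(
    positions: np.ndarray,
    perturb_index: int,
    fs: float = 1000.0,
    window_ms: tuple[float, float] = (0.0, 300.0),
) -> float:
    """Integral of filtered hand speed over a post-perturbation window.

    ``positions``: (T, 2) hand coordinates (m) at rate ``fs``.  Positions are
    low-passed (3rd-order Butterworth, 10 Hz, zero-phase), differentiated to
    velocity, and the speed magnitude is integrated (trapezoid) over
    ``window_ms`` relative to ``perturb_index``.  Returns metres.
    """
    pos = np.asarray(positions, float)
    if pos.ndim != 2 or pos.shape[1] < 1:
        raise ValueError("positions must be (T, n_coords)")
    i0 = perturb_index + int(round(window_ms[0] * fs / 1000.0))
    i1 = perturb_index + int(round(window_ms[1] * fs / 1000.0))
    if i0 < 0 or i1 + 1 > pos.shape[0] or i1 <= i0:
        raise ValueError("integration window falls outside the recording")
    sos = butter(3, 10.0, btype="lowpass", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, pos, axis=0)
    vel = np.gradient(filtered, axis=0) * fs
    speed = np.linalg.norm(vel, axis=1)
    # endpoint included so the trapezoid spans the full window duration
    return float(np.trapezoid(speed[i0 : i1 + 1], dx=1.0 / fs))
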