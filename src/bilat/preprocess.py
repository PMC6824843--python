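"""Spike-train smoothing, epoch alignment, and the context matrices C and I.

Spike trains are convolved at 1 ms resolution with either a causal post-spike
kernel (difference of exponentials, 1 ms rise / 20 ms fall) or a Gaussian
kernel (sd 20 ms).  Rates are realigned to the perturbation onset, yielding a
perturbation-aligned segment covering [-200, +300) ms and a steady-state
segment covering the last 1000 ms of each trial.

The population analyses consume a per-context matrix of shape
``neurons x (8 conditions * 30 time bins)``: trial-averaged perturbation-epoch
rates point-sampled every 10 ms, soft-normalized per neuron by its maximum
trial-averaged rate across both contexts plus 5 spikes/s, then mean-subtracted
across the eight load conditions at each time bin.  All recorded neurons enter
these matrices, whether or not they are load-sensitive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .core import CONTEXTS, EpochWindows, Session, canonical_load_set

logger = logging.getLogger(__name__)

__all__ = [
    "postspike_kernel",
    "gaussian_kernel",
    "RateSeries",
    "smooth_spike_trains",
    "EpochMeans",
    "epoch_means",
    "ContextMatrix",
    "build_context_matrices",
]

#: soft-normalization constant, spikes/s
SOFT_NORM_HZ = 5.0
#: downsampling step for the context matrices, ms
BIN_MS = 10
#: samples of the perturbation-aligned segment and index of load onset
ALIGNED_SPAN = (-200, 300)


def postspike_kernel(
    rise_ms: float = 1.0, fall_ms: float = 20.0, dt_ms: float = 1.0
) -> np.ndarray:
    """Causal post-spike smoothing kernel, unit area at resolution ``dt_ms``.

    ``k(t) = (1 - exp(-t/rise)) * exp(-t/fall)`` for t >= 0 and 0 before the
    spike; support truncated where k drops below 1e-6 of its peak.  The
    returned array starts at t = 0 (index i is t = i*dt_ms).
    """
    if rise_ms <= 0 or fall_ms <= 0:
        raise ValueError("time constants must be positive")
    if rise_ms >= fall_ms:
        raise ValueError("rise time must be shorter than fall time")
    # peak at t = rise * ln(1 + fall/rise); decay sets the support length
    t_max = fall_ms * np.log(1e6) + rise_ms * np.log(1 + fall_ms / rise_ms)
    t = np.arange(0.0, t_max + dt_ms, dt_ms)
    k = (1.0 - np.exp(-t / rise_ms)) * np.exp(-t / fall_ms)
    # truncate the tail only (keep the zero at t=0)
    last = int(np.max(np.nonzero(k >= 1e-6 * k.max()))) + 1
    k = k[:last]
    return k / (k.sum() * dt_ms)


def gaussian_kernel(sd_ms: float = 20.0, dt_ms: float = 1.0) -> np.ndarray:
    """Symmetric Gaussian kernel, unit area; support truncated at 4 sd."""
    if sd_ms <= 0:
        raise ValueError("sd must be positive")
    half = int(np.ceil(4 * sd_ms / dt_ms))
    t = np.arange(-half, half + 1) * dt_ms
    k = np.exp(-0.5 * (t / sd_ms) ** 2)
    return k / (k.sum() * dt_ms)


@dataclass
class RateSeries:
    """Perturbation-aligned firing-rate traces (Hz) at 1 ms resolution.

    ``perturb[(context, load_index)]`` has shape (n_neurons, n_trials, 500)
    covering [-200, +300) ms around load onset; ``steady`` has shape
    (n_neurons, n_trials, 1000) covering the last 1000 ms of each trial.
    """

    neuron_ids: list[int]
    perturb: dict[tuple[str, int], np.ndarray]
    steady: dict[tuple[str, int], np.ndarray]
    trial_ids: dict[tuple[str, int], list[int]]
    kernel: str = "postspike"

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    @property
    def perturb_time_axis(self) -> np.ndarray:
        """ms relative to load onset for the perturbation-aligned segment."""
        return np.arange(*ALIGNED_SPAN)

    def trial_average(self, context: str, load_index: int, which: str = "perturb") -> np.ndarray:
        data = self.perturb if which == "perturb" else self.steady
        return data[(context, load_index)].mean(axis=1)

    def averaged_tensor(self, context: str, which: str = "perturb") -> np.ndarray:
        """Trial-averaged traces stacked over loads: (n_neurons, 8, T)."""
        return np.stack(
            [self.trial_average(context, i, which) for i in range(8)], axis=1
        )

    def n_trials(self, context: str, load_index: int) -> int:
        return self.perturb[(context, load_index)].shape[1]


def _smooth_trains(
    trains: list[np.ndarray], n_ms: int, kernel: np.ndarray, causal: bool
) -> np.ndarray:
    """Convolve many 1 ms spike trains of one trial at once -> (n, n_ms) Hz."""
    mat = np.zeros((len(trains), n_ms))
    for i, st in enumerate(trains):
        if len(st):
            np.add.at(mat[i], np.asarray(st, dtype=np.int64), 1.0)
    full = fftconvolve(mat, kernel[None, :], axes=1)
    if causal:
        return 1000.0 * full[:, :n_ms]
    half = (len(kernel) - 1) // 2
    return 1000.0 * full[:, half : half + n_ms]


def smooth_spike_trains(
    session: Session,
    kernel: str = "postspike",
    gaussian_sd_ms: float = 20.0,
    windows: EpochWindows | None = None,
) -> RateSeries:
    """Convolve every spike train and realign to the perturbation onset.

    ``kernel`` selects the causal post-spike kernel (default) or the
    ``"gaussian"`` alternative.  Trials too short for the requested windows
    are excluded with a logged warning.
    """
    windows = windows or EpochWindows()
    if kernel == "postspike":
        k, causal = postspike_kernel(), True
    elif kernel == "gaussian":
        k, causal = gaussian_kernel(gaussian_sd_ms), False
    else:
        raise ValueError(f"unknown kernel {kernel!r}")

    neuron_ids = session.neuron_ids
    lo, hi = ALIGNED_SPAN
    ss = windows.steady_state_ms
    perturb: dict[tuple[str, int], np.ndarray] = {}
    steady: dict[tuple[str, int], np.ndarray] = {}
    trial_ids: dict[tuple[str, int], list[int]] = {}
    for ctx in CONTEXTS:
        for load in canonical_load_set():
            cell_trials = []
            for t in session.trials_for(ctx, load.index):
                if t.perturb_time_ms + lo < 0 or t.trial_end_ms < ss:
                    logger.warning(
                        "trial %d too short for analysis windows; excluded",
                        t.trial_id,
                    )
                    continue
                cell_trials.append(t)
            p = np.zeros((len(neuron_ids), len(cell_trials), hi - lo))
            s = np.zeros((len(neuron_ids), len(cell_trials), ss))
            empty = np.empty(0, dtype=np.int64)
            for j, t in enumerate(cell_trials):
                n_ms = t.trial_end_ms
                trains = [
                    session.spikes.get(nid, {}).get(t.trial_id, empty)
                    for nid in neuron_ids
                ]
                traces = _smooth_trains(trains, n_ms, k, causal)
                pt = t.perturb_time_ms
                p[:, j] = traces[:, pt + lo : pt + hi]
                s[:, j] = traces[:, n_ms - ss : n_ms]
            key = (ctx, load.index)
            perturb[key], steady[key] = p, s
            trial_ids[key] = [t.trial_id for t in cell_trials]
    return RateSeries(
        neuron_ids=neuron_ids, perturb=perturb, steady=steady,
        trial_ids=trial_ids, kernel=kernel,
    )


@dataclass
class EpochMeans:
    """Per-trial and trial-averaged epoch-mean rates (Hz).

    ``per_trial[context][epoch]`` has shape (n_neurons, 8, n_trials);
    epochs are ``baseline``, ``perturbation``, ``steady_state``.
    """

    neuron_ids: list[int]
    per_trial: dict[str, dict[str, np.ndarray]]

    def averaged(self, context: str, epoch: str) -> np.ndarray:
        return self.per_trial[context][epoch].mean(axis=2)


def epoch_means(rates: RateSeries, windows: EpochWindows | None = None) -> EpochMeans:
    """Arithmetic mean rate within each analysis epoch, per trial."""
    windows = windows or EpochWindows()
    lo, _ = ALIGNED_SPAN
    b0, b1 = (windows.baseline[0] - lo, windows.baseline[1] - lo)
    p0, p1 = (windows.perturbation[0] - lo, windows.perturbation[1] - lo)
    if b1 <= b0 or p1 <= p0:
        raise ValueError("empty epoch window")
    out: dict[str, dict[str, np.ndarray]] = {}
    for ctx in CONTEXTS:
        pt = np.stack([rates.perturb[(ctx, i)] for i in range(8)], axis=1)
        st = np.stack([rates.steady[(ctx, i)] for i in range(8)], axis=1)
        out[ctx] = {
            "baseline": pt[..., b0:b1].mean(axis=-1),
            "perturbation": pt[..., p0:p1].mean(axis=-1),
            "steady_state": st.mean(axis=-1),
        }
    return EpochMeans(neuron_ids=rates.neuron_ids, per_trial=out)


@dataclass
class ContextMatrix:
    """Soft-normalized, mean-subtracted ``neurons x (8*30)`` activity matrix.

    Columns are condition-major: column ``c*30 + t`` is load condition ``c``
    at perturbation-epoch sample ``t`` (10 ms grid).  ``divisors`` holds the
    per-neuron soft-normalization denominators (max rate + 5 spikes/s, taken
    across both contexts); ``condition_mean`` the per-time-bin cross-condition
    mean that was subtracted.
    """

    context: str
    matrix: np.ndarray  # (n_neurons, 240)
    neuron_ids: list[int]
    divisors: np.ndarray  # (n_neurons,)
    condition_mean: np.ndarray  # (n_neurons, n_time)
    n_conditions: int = 8
    n_time: int = 30

    def column(self, condition: int, time_bin: int) -> int:
        return condition * self.n_time + time_bin

    def covariance(self) -> np.ndarray:
        """Neuron-by-neuron covariance over the condition-time columns.

        Rows sum to zero exactly (cross-condition mean removal), so no
        further centering is needed.
        """
        n = self.matrix.shape[1]
        return (self.matrix @ self.matrix.T) / (n - 1)


def sampled_perturbation_rates(
    rates: RateSeries, context: str, bin_ms: int = BIN_MS
) -> np.ndarray:
    """Per-trial perturbation-epoch rates on the 10 ms grid.

    Point-samples (not bin-averages) the 1 ms traces at t = 0, 10, ..., 290 ms
    after load onset.  Shape (n_neurons, 8, n_trials, 30); requires equal
    trial counts across the 8 conditions.
    """
    lo, hi = ALIGNED_SPAN
    idx = np.arange(0, hi, bin_ms) - lo
    per_load = [rates.perturb[(context, i)][..., idx] for i in range(8)]
    if len({p.shape[1] for p in per_load}) != 1:
        raise ValueError(
            "conditions have unequal trial counts; per-trial sampling "
            "requires a rectangular trial structure"
        )
    return np.stack(per_load, axis=1)


def _sampled_average(rates: RateSeries, context: str, bin_ms: int) -> np.ndarray:
    """Trial-averaged perturbation-epoch rates on the 10 ms grid: (N, 8, T)."""
    lo, hi = ALIGNED_SPAN
    idx = np.arange(0, hi, bin_ms) - lo
    avg = rates.averaged_tensor(context, "perturb")  # (N, 8, 500)
    return avg[..., idx]


def soft_norm_divisors(rates: RateSeries) -> np.ndarray:
    """Per-neuron divisor: max trial-averaged rate across both contexts + 5."""
    peak = np.maximum(
        rates.averaged_tensor("contra", "perturb").max(axis=(1, 2)),
        rates.averaged_tensor("ipsi", "perturb").max(axis=(1, 2)),
    )
    return peak + SOFT_NORM_HZ


def _assemble(sampled: np.ndarray, divisors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Soft-normalize, subtract the cross-condition mean, flatten to (N, C*T)."""
    norm = sampled / divisors[:, None, None]
    cond_mean = norm.mean(axis=1)  # (N, T)
    centered = norm - cond_mean[:, None, :]
    n, c, t = centered.shape
    return centered.reshape(n, c * t), cond_mean


def build_context_matrices(
    rates: RateSeries, bin_ms: int = BIN_MS
) -> tuple[ContextMatrix, ContextMatrix]:
    """Build the contralateral (C) and ipsilateral (I) context matrices."""
    for ctx in CONTEXTS:
        for i in range(8):
            if (ctx, i) not in rates.perturb or rates.perturb[(ctx, i)].shape[1] == 0:
                raise ValueError(f"missing trials for (context={ctx}, load={i})")
    divisors = soft_norm_divisors(rates)
    out = []
    for ctx in CONTEXTS:
        sampled = _sampled_average(rates, ctx, bin_ms)
        matrix, cond_mean = _assemble(sampled, divisors)
        out.append(
            ContextMatrix(
                context=ctx, matrix=matrix, neuron_ids=rates.neuron_ids,
                divisors=divisors, condition_mean=cond_mean,
                n_conditions=8, n_time=sampled.shape[2],
            )
        )
    return out[0], out[1]
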