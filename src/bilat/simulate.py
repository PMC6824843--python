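"""Synthetic two-context sessions with known ground truth.

The generator emulates the phenomenology of perturbation responses in primary
motor cortex recorded from one hemisphere while step loads are applied to the
contralateral or ipsilateral limb:

* planar torque tuning with an axially bimodal preferred-load distribution
  (major axis in the shoulder-flexion/elbow-extension quadrants),
* contralateral responses about twice the ipsilateral magnitude,
* ipsilateral response onset lagging the contralateral onset by ~10 ms,
* population activity per context confined to a low-dimensional neuron
  subspace, with the two subspaces at a configurable mutual alignment,
* inhomogeneous-Poisson spiking at 1 ms resolution.

Construction.  Contralateral neuron loadings are built directly from sampled
preferred axes: ``W = [g*cos(theta), g*sin(theta), r, ...]`` with lognormal
gains ``g``.  The ipsilateral basis is ``cos(a)*U_contra + sin(a)*V_perp``
where ``cos^2(a)`` equals the requested alignment and ``V_perp`` is the
orthogonalized loading frame of an independently sampled axis set, so the
principal angles between the two ground-truth subspaces are all exactly ``a``
while ipsilateral tuning stays bimodal.  Latent channels beyond the two planar
ones carry a second-harmonic (cos 2*phi) condition profile with a decaying
temporal profile, so each context is genuinely ``d_latent``-dimensional even
after the cross-condition mean subtraction used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    LoadCombination,
    Session,
    SINGLE_JOINT_NM,
    TrialRecord,
    canonical_load_set,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "sample_preferred_axes",
    "simulate_session",
    "alignment_of_bases",
    "bell_displacement",
]

#: length (ms) of simulated activity after the perturbation
POST_MS = 1300


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters of a simulated session.

    Defaults are the study conditions the generator emulates: ~110 neurons,
    10 trials per condition per context, near-orthogonal 3-D context
    subspaces, a 2:1 contra:ipsi response-magnitude ratio, and a 10 ms
    ipsilateral onset lag.
    """

    n_neurons: int = 110
    n_trials_per_condition: int = 10
    d_latent: int = 3
    alignment: float = 0.15  # 0 = orthogonal subspaces, 1 = identical
    contra_gain_ratio: float = 2.0
    onset_contra_ms: float = 25.0
    onset_ipsi_ms: float = 35.0
    bimodal_axis_deg: float = 135.0
    concentration: float = 2.0
    baseline_rate_hz: float = 10.0
    response_gain_hz: float = 8.0  # median rate change at a preferred single-joint load
    gain_sigma: float = 0.4  # lognormal spread of per-neuron gains
    harmonic_gain: float = 0.6  # loading scale of latent channels beyond the planar pair
    rise_ms: float = 10.0  # initial rise of the phasic-tonic response
    peak_factor: float = 2.5  # transient peak relative to the sustained plateau
    transient_tau_ms: float = 60.0  # decay of the transient toward the plateau
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.alignment <= 1.0:
            raise ValueError(f"alignment must lie in [0, 1], got {self.alignment}")
        if not 2 <= self.d_latent <= 4:
            raise ValueError("d_latent must be 2, 3 or 4")
        if 2 * self.d_latent > self.n_neurons:
            raise ValueError("need n_neurons >= 2 * d_latent")
        if self.n_trials_per_condition < 1:
            raise ValueError("need at least one trial per condition")
        if self.baseline_rate_hz < 0 or self.response_gain_hz < 0:
            raise ValueError("rates must be non-negative")
        if self.contra_gain_ratio <= 0:
            raise ValueError("contra_gain_ratio must be positive")


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery tests."""

    config: SimConfig
    U_contra: np.ndarray  # (n_neurons, d_latent), orthonormal columns
    U_ipsi: np.ndarray
    preferred_angle_deg: dict[str, np.ndarray]  # per context, per neuron
    gain_hz_per_nm: dict[str, np.ndarray]
    onset_ms: dict[str, float]
    baseline_hz: np.ndarray


def sample_preferred_axes(
    n: int,
    axis_deg: float = 135.0,
    concentration: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw ``n`` preferred-load angles from an axial von Mises distribution.

    The distribution is 180-degree symmetric (bimodal on the circle) with
    modes at ``axis_deg`` and ``axis_deg + 180``; ``concentration`` is the
    von Mises kappa of the doubled angles (0 = uniform).  Returns degrees in
    [0, 360).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # doubled-angle von Mises, halved back onto the axial circle
    phi = rng.vonmises(0.0, concentration, size=n)
    flip = rng.integers(0, 2, size=n) * 180.0
    return (axis_deg + np.degrees(phi) / 2.0 + flip) % 360.0


def alignment_of_bases(U_a: np.ndarray, U_b: np.ndarray) -> float:
    """Mean squared cosine of the principal angles between two column spans.

    1 for identical spans, 0 for orthogonal spans.  Both inputs must have
    orthonormal columns over the same neurons.
    """
    U_a = np.asarray(U_a, float)
    U_b = np.asarray(U_b, float)
    if U_a.shape[0] != U_b.shape[0]:
        raise ValueError("bases must have the same neuron count")
    for name, U in (("first", U_a), ("second", U_b)):
        gram = U.T @ U
        if not np.allclose(gram, np.eye(U.shape[1]), atol=1e-8):
            raise ValueError(f"{name} basis does not have orthonormal columns")
    s = np.linalg.svd(U_a.T @ U_b, compute_uv=False)
    return float(np.mean(s**2))


def _signed_qr(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reduced QR with the sign convention diag(R) >= 0."""
    Q, R = np.linalg.qr(M)
    sign = np.sign(np.diag(R))
    sign[sign == 0] = 1.0
    return Q * sign, R * sign[:, None]


def _loading_matrix(
    angles_deg: np.ndarray, gains: np.ndarray, d: int, rng: np.random.Generator,
    harmonic_gain: float,
) -> np.ndarray:
    """Neuron-by-channel loadings: planar pair then random harmonic channels."""
    th = np.radians(angles_deg)
    cols = [gains * np.cos(th), gains * np.sin(th)]
    planar_scale = np.linalg.norm(gains)
    for _ in range(d - 2):
        r = rng.standard_normal(angles_deg.size)
        cols.append(r * (harmonic_gain * planar_scale / np.linalg.norm(r)))
    return np.column_stack(cols)


def _latent_courses(
    loads: list[LoadCombination],
    onset_ms: float,
    rise_ms: float,
    peak_factor: float,
    transient_tau_ms: float,
    d: int,
) -> np.ndarray:
    """Latent time courses, shape (d, n_loads, POST_MS).

    Channels 0/1 carry the planar (shoulder, elbow) torque components with a
    phasic-tonic profile: a sharp rise (``rise_ms``) to a transient peak
    ``peak_factor`` times the sustained plateau, decaying to the plateau
    with time constant ``transient_tau_ms`` and held through the trial end.
    Channels >= 2 carry second-harmonic condition patterns with a
    rise-then-decay profile.
    """
    t = np.arange(POST_MS, dtype=float)
    rise = np.clip((t - onset_ms) / rise_ms, 0.0, 1.0)
    after = np.maximum(t - onset_ms - rise_ms, 0.0)
    phasic = rise * (1.0 + (peak_factor - 1.0) * np.exp(-after / transient_tau_ms))
    decay = rise * (0.3 + 0.7 * np.exp(-after / 150.0))

    phis = np.radians([ld.angle for ld in loads])
    mags = np.array([np.hypot(ld.shoulder_torque, ld.elbow_torque) for ld in loads])
    mags = mags / SINGLE_JOINT_NM

    L = np.zeros((d, len(loads), POST_MS))
    L[0] = np.outer(mags * np.cos(phis), phasic)
    L[1] = np.outer(mags * np.sin(phis), phasic)
    for j in range(2, d):
        phase = np.radians(90.0 * (j - 2))
        L[j] = np.outer(np.cos(2 * phis - phase), decay)
    return L


def simulate_session(config: SimConfig) -> tuple[Session, GroundTruth]:
    """Simulate one two-context session and return it with its ground truth.

    Deterministic given ``config`` (including its seed): the same config
    reproduces the same session byte-for-byte.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    N, d = config.n_neurons, config.d_latent
    loads = canonical_load_set()

    # --- neuron loadings and ground-truth bases -----------------------------
    theta_c = sample_preferred_axes(
        N, config.bimodal_axis_deg, config.concentration, rng
    )
    gains_c = np.exp(rng.normal(0.0, config.gain_sigma, N))
    W_c = _loading_matrix(theta_c, gains_c, d, rng, config.harmonic_gain)
    U_c, K_c = _signed_qr(W_c)

    theta_raw = sample_preferred_axes(
        N, config.bimodal_axis_deg, config.concentration, rng
    )
    gains_raw = np.exp(rng.normal(0.0, config.gain_sigma, N))
    W_raw = _loading_matrix(theta_raw, gains_raw, d, rng, config.harmonic_gain)
    V_perp, _ = _signed_qr(W_raw - U_c @ (U_c.T @ W_raw))

    angle = np.arccos(np.sqrt(config.alignment))
    U_i = np.cos(angle) * U_c + np.sin(angle) * V_perp
    W_i = U_i @ K_c

    amp = {
        "contra": config.response_gain_hz,
        "ipsi": config.response_gain_hz / config.contra_gain_ratio,
    }
    onset = {"contra": config.onset_contra_ms, "ipsi": config.onset_ipsi_ms}
    W = {"contra": W_c, "ipsi": W_i}

    baseline = rng.gamma(4.0, config.baseline_rate_hz / 4.0, N)

    # response templates: (context, load) -> (N, POST_MS) expected rate change
    templates: dict[tuple[str, int], np.ndarray] = {}
    for ctx in ("contra", "ipsi"):
        L = _latent_courses(
            loads, onset[ctx], config.rise_ms, config.peak_factor,
            config.transient_tau_ms, d,
        )
        for ld in loads:
            templates[(ctx, ld.index)] = amp[ctx] * np.einsum(
                "nj,jt->nt", W[ctx], L[:, ld.index, :]
            )

    # --- trials and Poisson spikes ------------------------------------------
    trials: list[TrialRecord] = []
    spikes: dict[int, dict[int, list]] = {nid: {} for nid in range(N)}
    trial_id = 0
    for _block in range(config.n_trials_per_condition):
        for ctx in ("contra", "ipsi"):
            for ld in loads:
                pt = int(rng.integers(500, 1001))
                end = pt + POST_MS
                trials.append(
                    TrialRecord(
                        trial_id=trial_id, context=ctx, load=ld,
                        perturb_time_ms=pt, trial_end_ms=end,
                    )
                )
                rate = np.tile(baseline[:, None], (1, end))
                rate[:, pt:] += templates[(ctx, ld.index)]
                np.clip(rate, 0.0, None, out=rate)
                fired = rng.random((N, end)) < rate * 1e-3
                for nid in range(N):
                    spikes[nid][trial_id] = np.flatnonzero(fired[nid]).astype(np.int64)
                trial_id += 1

    session = Session(
        trials=trials,
        spikes={nid: dict(per) for nid, per in spikes.items()},
    )
    truth = GroundTruth(
        config=config,
        U_contra=U_c,
        U_ipsi=U_i,
        preferred_angle_deg={
            "contra": np.degrees(np.arctan2(W_c[:, 1], W_c[:, 0])) % 360.0,
            "ipsi": np.degrees(np.arctan2(W_i[:, 1], W_i[:, 0])) % 360.0,
        },
        gain_hz_per_nm={
            ctx: amp[ctx] * np.linalg.norm(W[ctx][:, :2], axis=1) / SINGLE_JOINT_NM
            for ctx in ("contra", "ipsi")
        },
        onset_ms=onset,
        baseline_hz=baseline,
    )
    return session, truth


def bell_displacement(
    n_ms: int,
    perturb_ms: int,
    displacement: float = 0.02,
    onset_ms: float = 30.0,
    duration_ms: float = 250.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """A minimal hand-position trace (T, 2): a bell-speed displacement.

    Returns positions in metres sampled at 1 kHz; the hand moves
    ``displacement`` metres along x with a raised-cosine speed profile
    starting ``onset_ms`` after the perturbation.  Used for kinematic-module
    smoke tests; the generator does not model real limb mechanics.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_ms, dtype=float)
    start = perturb_ms + onset_ms
    u = np.clip((t - start) / duration_ms, 0.0, 1.0)
    x = displacement * (u - np.sin(2 * np.pi * u) / (2 * np.pi))
    pos = np.column_stack([x, np.zeros_like(x)])
    if noise_sd > 0:
        pos += rng.normal(0.0, noise_sd, pos.shape)
    return pos
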