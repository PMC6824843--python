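"""Per-neuron load tuning: sensitivity ANOVA, planar fits, circular statistics.

A neuron is *load-sensitive* if a fully crossed three-way ANOVA
(epoch 2 x context 2 x load 8) on its per-trial epoch-mean rates shows a
significant main effect of epoch or any interaction involving epoch
(p < 0.05).  Preferred loads come from a least-squares planar fit
``rate = offset + b_s * tau_shoulder + b_e * tau_elbow`` on per-trial
perturbation- (or steady-state-) epoch means; the preferred angle is
``atan2(b_e, b_s)`` and the magnitude ``sqrt(b_s^2 + b_e^2)`` in Hz/Nm.
Population distributions of preferred angles are summarized with Rayleigh
unimodal/bimodal R statistics against a uniform-resampling bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .core import CONTEXTS, canonical_load_set
from .preprocess import EpochMeans

__all__ = [
    "SensitivityResult",
    "load_sensitivity_anova",
    "PlanarFit",
    "fit_plane",
    "fit_planes",
    "RayleighResult",
    "rayleigh_stats",
    "rayleigh_bootstrap_p",
    "TuningDifference",
    "tuning_difference",
    "MagnitudeContrast",
    "magnitude_contrast",
]

ALPHA = 0.05


@dataclass
class SensitivityResult:
    neuron_id: int
    load_sensitive: bool
    p_epoch: float
    p_interactions: dict[str, float]


def _neuron_anova(rates_long: pd.DataFrame) -> tuple[float, dict[str, float]]:
    model = smf.ols(
        "rate ~ C(epoch) * C(context) * C(load)", data=rates_long
    ).fit()
    table = sm.stats.anova_lm(model, typ=2)
    p = table["PR(>F)"]
    p_epoch = float(p["C(epoch)"])
    inter = {
        name: float(p[name])
        for name in p.index
        if "C(epoch)" in name and ":" in name
    }
    return p_epoch, inter


def load_sensitivity_anova(means: EpochMeans) -> list[SensitivityResult]:
    """Three-way ANOVA per neuron on baseline/perturbation per-trial means.

    Uses Type-II sums of squares on the fully crossed factorial model; any
    empty factor cell raises with the cell named.
    """
    results = []
    frames = []
    for ctx in CONTEXTS:
        for epoch in ("baseline", "perturbation"):
            arr = means.per_trial[ctx][epoch]  # (N, 8, n_trials)
            if arr.shape[2] == 0:
                raise ValueError(f"empty factor cell: context={ctx}, epoch={epoch}")
            n, c, t = arr.shape
            frames.append((ctx, epoch, arr))
    loads = np.arange(8)
    for i, nid in enumerate(means.neuron_ids):
        recs = []
        for ctx, epoch, arr in frames:
            vals = arr[i]  # (8, n_trials)
            for c in loads:
                for v in vals[c]:
                    recs.append((epoch, ctx, c, v))
        df = pd.DataFrame(recs, columns=["epoch", "context", "load", "rate"])
        p_epoch, inter = _neuron_anova(df)
        ps = [p_epoch] + list(inter.values())
        results.append(
            SensitivityResult(
                neuron_id=nid,
                load_sensitive=bool(np.any(np.asarray(ps) < ALPHA)),
                p_epoch=p_epoch,
                p_interactions=inter,
            )
        )
    return results


@dataclass
class PlanarFit:
    """Planar load-tuning fit for one neuron in one context and epoch."""

    neuron_id: int
    context: str
    epoch: str
    offset_hz: float
    b_shoulder: float  # Hz/Nm
    b_elbow: float  # Hz/Nm
    p_value: float

    @property
    def preferred_angle_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.b_elbow, self.b_shoulder)) % 360.0)

    @property
    def magnitude_hz_per_nm(self) -> float:
        return float(np.hypot(self.b_shoulder, self.b_elbow))

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def fit_plane(
    rates: np.ndarray,
    torques: np.ndarray,
    neuron_id: int = -1,
    context: str = "contra",
    epoch: str = "perturbation",
) -> PlanarFit:
    """Least-squares plane through per-trial epoch-mean rates.

    ``rates``: (n_obs,) mean rates; ``torques``: (n_obs, 2) shoulder/elbow
    torques (Nm).  The mean rate is removed before fitting (the plane's
    significance is the overall F-test of the two-slope regression).
    """
    rates = np.asarray(rates, float)
    torques = np.asarray(torques, float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(torques)), torques])) < 3:
        raise ValueError("rank-deficient torque design")
    y = rates - rates.mean()
    X = sm.add_constant(torques)
    res = sm.OLS(y, X).fit()
    p = float(res.f_pvalue) if np.isfinite(res.f_pvalue) else 1.0
    return PlanarFit(
        neuron_id=neuron_id, context=context, epoch=epoch,
        offset_hz=float(rates.mean() + res.params[0]),
        b_shoulder=float(res.params[1]), b_elbow=float(res.params[2]),
        p_value=p,
    )


def fit_planes(
    means: EpochMeans, context: str, epoch: str = "perturbation"
) -> list[PlanarFit]:
    """Planar fits for every neuron in one context/epoch."""
    arr = means.per_trial[context][epoch]  # (N, 8, n_trials)
    taus = np.array([ld.torque_vector for ld in canonical_load_set()])
    n, c, t = arr.shape
    torques = np.repeat(taus, t, axis=0)
    return [
        fit_plane(arr[i].reshape(-1), torques, means.neuron_ids[i], context, epoch)
        for i in range(n)
    ]


@dataclass
class RayleighResult:
    R: float
    axis_deg: float
    mode: str


def rayleigh_stats(angles_deg: np.ndarray, mode: str = "unimodal") -> RayleighResult:
    """Mean resultant length R of unit vectors at the given angles.

    ``bimodal`` doubles the angles first, detecting axial (180-degree
    symmetric) structure; its major axis is reported in [0, 180).
    """
    angles = np.asarray(angles_deg, float)
    if angles.size < 1:
        raise ValueError("need at least one angle")
    if mode not in ("unimodal", "bimodal"):
        raise ValueError(f"unknown mode {mode!r}")
    mult = 2.0 if mode == "bimodal" else 1.0
    z = np.exp(1j * np.radians(angles * mult)).mean()
    axis = np.degrees(np.angle(z)) / mult
    axis = axis % (360.0 / mult)
    return RayleighResult(R=float(np.abs(z)), axis_deg=float(axis), mode=mode)


def _rayleigh_R_rows(angles_rad: np.ndarray, mult: float) -> np.ndarray:
    return np.abs(np.exp(1j * angles_rad * mult).mean(axis=-1))


def rayleigh_bootstrap_p(
    angles_deg: np.ndarray,
    mode: str = "unimodal",
    n_boot: int = 1000,
    seed: int = 0,
) -> float:
    """Probability that uniform angles produce an R at least as large.

    Resamples ``n_boot`` sets of the same size from Uniform(0, 360) and
    counts the fraction whose Rayleigh R reaches the observed R.
    """
    angles = np.asarray(angles_deg, float)
    if angles.size < 2:
        raise ValueError("need at least two angles")
    observed = rayleigh_stats(angles, mode).R
    rng = np.random.default_rng(seed)
    mult = 2.0 if mode == "bimodal" else 1.0
    null = _rayleigh_R_rows(
        rng.uniform(0, 2 * np.pi, size=(n_boot, angles.size)), mult
    )
    return float(np.mean(null >= observed))


def circular_difference_deg(a_deg: np.ndarray, b_deg: np.ndarray) -> np.ndarray:
    """Signed circular difference a - b, wrapped into (-180, 180]."""
    d = (np.asarray(a_deg, float) - np.asarray(b_deg, float)) % 360.0
    d[d > 180.0] -= 360.0
    return d


@dataclass
class TuningDifference:
    neuron_ids: list[int]
    differences_deg: np.ndarray
    R: float
    axis_deg: float
    p: float
    n_boot: int
    seed: int


def tuning_difference(
    fits_a: list[PlanarFit],
    fits_b: list[PlanarFit],
    n_boot: int = 1000,
    seed: int = 0,
) -> TuningDifference:
    """Per-neuron preferred-angle change between two fit sets.

    Matches neurons by id, computes signed circular differences in
    (-180, 180], and summarizes them with the unimodal Rayleigh statistic
    and its uniform bootstrap p.  A difference distribution concentrated at
    0 means tuning is preserved between the two conditions.
    """
    by_a = {f.neuron_id: f for f in fits_a}
    by_b = {f.neuron_id: f for f in fits_b}
    common = sorted(set(by_a) & set(by_b))
    if not common:
        raise ValueError("no common neurons between fit sets")
    diffs = circular_difference_deg(
        np.array([by_a[n].preferred_angle_deg for n in common]),
        np.array([by_b[n].preferred_angle_deg for n in common]),
    )
    stat = rayleigh_stats(diffs, "unimodal")
    p = rayleigh_bootstrap_p(diffs, "unimodal", n_boot=n_boot, seed=seed)
    return TuningDifference(
        neuron_ids=common, differences_deg=diffs,
        R=stat.R, axis_deg=stat.axis_deg, p=p, n_boot=n_boot, seed=seed,
    )


@dataclass
class MagnitudeContrast:
    neuron_ids: list[int]
    median_contra: float
    median_ipsi: float
    differences: np.ndarray  # contra - ipsi, Hz/Nm
    wilcoxon_z: float
    wilcoxon_p: float
    fraction_contra_larger: float


def magnitude_contrast(
    fits_contra: list[PlanarFit], fits_ipsi: list[PlanarFit]
) -> MagnitudeContrast:
    """Contra-vs-ipsi planar-fit magnitudes with a paired signed-rank test.

    Callers apply their inclusion rule first (e.g. neurons with a significant
    fit in at least one context); fewer than five paired neurons is an error
    because the signed-rank z is meaningless at tiny n.
    """
    by_c = {f.neuron_id: f for f in fits_contra}
    by_i = {f.neuron_id: f for f in fits_ipsi}
    common = sorted(set(by_c) & set(by_i))
    if len(common) < 5:
        raise ValueError("need at least 5 paired neurons")
    mc = np.array([by_c[n].magnitude_hz_per_nm for n in common])
    mi = np.array([by_i[n].magnitude_hz_per_nm for n in common])
    diffs = mc - mi
    if np.allclose(diffs, 0.0):
        z, p = 0.0, 1.0
    else:
        res = stats.wilcoxon(diffs, method="approx")
        z, p = float(res.zstatistic), float(res.pvalue)
    return MagnitudeContrast(
        neuron_ids=common,
        median_contra=float(np.median(mc)),
        median_ipsi=float(np.median(mi)),
        differences=diffs,
        wilcoxon_z=z,
        wilcoxon_p=p,
        fraction_contra_larger=float(np.mean(diffs > 0) + 0.5 * np.mean(diffs == 0)),
    )
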