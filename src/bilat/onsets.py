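"""Response-onset detection after load application.

A neuron's onset is estimated on its *best-load average*: the trial average
over the load combination evoking the largest absolute change from baseline
plus its two 45-degree neighbours.  The onset is the first post-load sample
whose deviation from the baseline mean exceeds three baseline standard
deviations and stays above that threshold for 20 consecutive milliseconds.
The criterion is two-sided by default (|deviation|), so inhibited neurons are
detected too.  A population onset applies the same rule to the across-neuron
average of sign-rectified best-load changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import ALIGNED_SPAN, RateSeries

logger = logging.getLogger(__name__)

__all__ = [
    "OnsetResult",
    "best_load_average",
    "detect_onset",
    "population_onset",
    "OnsetContrast",
    "onset_contrast",
]


@dataclass
class OnsetResult:
    neuron_id: int | str
    context: str
    onset_ms: float | None  # relative to load onset; None if never detected
    best_load_index: int | None
    baseline_mean_hz: float
    baseline_sd_hz: float
    degenerate: bool = False  # baseline SD was zero


def best_load_average(
    rates: RateSeries, neuron_index: int, context: str
) -> tuple[np.ndarray, int]:
    """Average trace over the strongest load and its two 45-deg neighbours.

    The strongest load maximizes |perturbation-epoch mean - baseline mean|
    of the trial-averaged trace; ties go to the lower load index (logged).
    Returns the averaged perturbation-aligned trace (500 samples,
    [-200, +300) ms) and the selected centre load index.
    """
    lo, _ = ALIGNED_SPAN
    avg = rates.averaged_tensor(context, "perturb")[neuron_index]  # (8, 500)
    base = avg[:, : -lo].mean(axis=1)
    pert = avg[:, -lo :].mean(axis=1)
    score = np.abs(pert - base)
    best = int(np.argmax(score))
    if np.sum(np.isclose(score, score[best])) > 1:
        logger.info(
            "neuron %s context %s: tied best loads, keeping lowest index %d",
            rates.neuron_ids[neuron_index], context, best,
        )
    picked = [(best - 1) % 8, best, (best + 1) % 8]
    stacked = np.concatenate(
        [rates.perturb[(context, i)][neuron_index] for i in picked], axis=0
    )
    return stacked.mean(axis=0), best


def detect_onset(
    trace: np.ndarray,
    k_sd: float = 3.0,
    dwell_ms: int = 20,
    two_sided: bool = True,
    neuron_id: int | str = -1,
    context: str = "",
    best_load_index: int | None = None,
    baseline_window: tuple[int, int] | None = None,
) -> OnsetResult:
    """Threshold-crossing onset on a perturbation-aligned 1 ms trace.

    ``trace`` covers [-200, +300) ms; baseline statistics come from the
    200 pre-load samples (or the sample range ``baseline_window`` within the
    trace, when given).  The onset is the first post-load time where the
    (absolute, if ``two_sided``) deviation from the baseline mean exceeds
    ``k_sd`` baseline SDs for ``dwell_ms`` consecutive samples; ``None`` if
    the threshold never holds that long.
    """
    lo, hi = ALIGNED_SPAN
    trace = np.asarray(trace, float)
    if trace.size != hi - lo:
        raise ValueError(f"trace must cover [{lo}, {hi}) ms at 1 ms resolution")
    post = trace[-lo:]
    if post.size < dwell_ms:
        raise ValueError("post-load trace shorter than the dwell window")
    b0, b1 = (0, -lo) if baseline_window is None else baseline_window
    mean = trace[b0:b1].mean()
    sd = trace[b0:b1].std(ddof=0)
    if sd == 0.0:
        logger.warning("degenerate baseline (SD=0); onset undefined")
        return OnsetResult(neuron_id, context, None, best_load_index, mean, 0.0, True)
    dev = post - mean
    if two_sided:
        dev = np.abs(dev)
    above = dev > k_sd * sd
    onset = None
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= dwell_ms:
            onset = float(i - dwell_ms + 1)
            break
    return OnsetResult(neuron_id, context, onset, best_load_index, float(mean), float(sd))


def neuron_onsets(
    rates: RateSeries,
    context: str,
    neuron_indices: list[int] | None = None,
    k_sd: float = 3.0,
    dwell_ms: int = 20,
) -> list[OnsetResult]:
    """Best-load-average onset for each requested neuron."""
    idx = range(rates.n_neurons) if neuron_indices is None else neuron_indices
    out = []
    for i in idx:
        trace, best = best_load_average(rates, i, context)
        out.append(
            detect_onset(
                trace, k_sd=k_sd, dwell_ms=dwell_ms,
                neuron_id=rates.neuron_ids[i], context=context,
                best_load_index=best,
            )
        )
    return out


def population_onset(
    rates: RateSeries,
    context: str,
    neuron_indices: list[int],
    k_sd: float = 3.0,
    dwell_ms: int = 20,
) -> tuple[OnsetResult, np.ndarray]:
    """Onset of the average population rate change.

    Each included neuron contributes its best-load-average change from its
    baseline mean, signed so the dominant deflection is positive (excitatory
    and inhibited neurons then add rather than cancel).  The best load and
    the sign are chosen on half of each condition's trials and the trace is
    averaged over the *other* half: selecting and averaging the same trials
    would rectify selection noise into a spurious post-load pedestal, which
    matters at population scale because the averaged trace's baseline SD
    shrinks with the neuron count while the pedestal does not.  The
    3-SD / 20 ms rule is applied to the across-neuron average trace, whose
    own pre-load samples supply the baseline statistics.
    """
    if len(neuron_indices) < 2:
        raise ValueError("population onset needs at least 2 neurons")
    lo, _ = ALIGNED_SPAN
    changes = []
    for i in neuron_indices:
        # two-fold cross-fitting on a deterministic alternating trial split:
        # each fold's best load and sign are chosen on the other fold, so
        # every trial contributes to the trace but never to its own selection
        folds = [
            {c: rates.perturb[(context, c)][i, 0::2] for c in range(8)},
            {c: rates.perturb[(context, c)][i, 1::2] for c in range(8)},
        ]
        per_fold = []
        for select, held in (folds, folds[::-1]):
            base = {c: select[c].mean(axis=0)[: -lo].mean() for c in range(8)}
            pert = {c: select[c].mean(axis=0)[-lo:].mean() for c in range(8)}
            best = max(range(8), key=lambda c: abs(pert[c] - base[c]))
            sign = np.sign(pert[best] - base[best]) or 1.0
            picked = [(best - 1) % 8, best, (best + 1) % 8]
            trace = np.concatenate([held[c] for c in picked], axis=0).mean(axis=0)
            per_fold.append(sign * (trace - trace[: -lo].mean()))
        changes.append(np.mean(per_fold, axis=0))
    pop = np.mean(changes, axis=0)
    result = detect_onset(
        pop, k_sd=k_sd, dwell_ms=dwell_ms,
        neuron_id="population", context=context,
    )
    return result, pop


@dataclass
class OnsetContrast:
    neuron_ids: list[int]
    median_contra_ms: float
    median_ipsi_ms: float
    differences_ms: np.ndarray  # contra - ipsi
    wilcoxon_z: float
    wilcoxon_p: float
    r_difference_vs_log_ratio: float
    r_magnitude_onset_contra: float
    r_magnitude_onset_ipsi: float


def onset_contrast(
    onsets_contra: list[OnsetResult],
    onsets_ipsi: list[OnsetResult],
    magnitudes: dict[str, dict[int, float]],
) -> OnsetContrast:
    """Paired contra-vs-ipsi onset statistics.

    ``magnitudes[context][neuron_id]`` supplies the response magnitudes
    (Hz/Nm) used for the onset-difference vs log-magnitude-ratio correlation
    and the within-context magnitude/onset correlations.  Only neurons with
    defined onsets in both contexts enter; fewer than five is an error.
    """
    by_c = {o.neuron_id: o for o in onsets_contra if o.onset_ms is not None}
    by_i = {o.neuron_id: o for o in onsets_ipsi if o.onset_ms is not None}
    common = sorted(set(by_c) & set(by_i))
    if len(common) < 5:
        raise ValueError("need at least 5 neurons with onsets in both contexts")
    oc = np.array([by_c[n].onset_ms for n in common])
    oi = np.array([by_i[n].onset_ms for n in common])
    diffs = oc - oi
    if np.allclose(diffs, 0.0):
        z, p = 0.0, 1.0
    else:
        res = stats.wilcoxon(diffs, method="approx")
        z, p = float(res.zstatistic), float(res.pvalue)
    mc = np.array([magnitudes["contra"][n] for n in common])
    mi = np.array([magnitudes["ipsi"][n] for n in common])
    log_ratio = np.log(mc / mi)

    def _safe_r(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return float("nan")
        return float(stats.pearsonr(x, y)[0])

    return OnsetContrast(
        neuron_ids=common,
        median_contra_ms=float(np.median(oc)),
        median_ipsi_ms=float(np.median(oi)),
        differences_ms=diffs,
        wilcoxon_z=z,
        wilcoxon_p=p,
        r_difference_vs_log_ratio=_safe_r(diffs, log_ratio),
        r_magnitude_onset_contra=_safe_r(mc, oc),
        r_magnitude_onset_ipsi=_safe_r(mi, oi),
    )
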