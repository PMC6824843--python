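"""Pairwise-correlation restructuring between contexts.

For every unordered neuron pair, Pearson correlation is computed between the
pair's context-matrix row vectors (8 conditions x 30 time bins), once per
context; the statistic of interest is the median absolute change in r between
contexts.  Its null distribution comes from a trial-split bootstrap *within*
one context: trials of every condition are randomly halved, two trial-averaged
matrices are built with the full-data soft-normalization divisors, and the
median absolute correlation change between the halves measures how much
restructuring finite trial counts alone produce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import ContextMatrix, RateSeries, _assemble, sampled_perturbation_rates

logger = logging.getLogger(__name__)

__all__ = [
    "pairwise_correlations",
    "CorrelationChange",
    "correlation_change",
    "TrialSplitNull",
    "split_trial_null",
]


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def pairwise_correlations(cm: ContextMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pearson r for every unordered neuron pair's row vectors.

    Returns ``(i, j, r)`` arrays over the upper triangle.  Pairs involving a
    constant row are skipped with a warning (r undefined there).
    """
    m = cm.matrix
    if m.shape[0] < 2:
        raise ValueError("need at least 2 neurons")
    sd = m.std(axis=1)
    const = sd == 0
    if const.any():
        logger.warning(
            "%d constant rows; their pairs are skipped", int(const.sum())
        )
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(m)
    i, j = _pair_indices(m.shape[0])
    keep = ~(const[i] | const[j])
    return i[keep], j[keep], r[i[keep], j[keep]]


@dataclass
class CorrelationChange:
    neuron_ids: list[int]
    pair_i: np.ndarray
    pair_j: np.ndarray
    r_contra: np.ndarray
    r_ipsi: np.ndarray
    abs_delta: np.ndarray
    median_abs_delta: float


def correlation_change(C: ContextMatrix, I: ContextMatrix) -> CorrelationChange:
    """Observed per-pair |r_contra - r_ipsi| and its median."""
    if C.neuron_ids != I.neuron_ids:
        raise ValueError("context matrices cover different neuron sets")
    ic, jc, rc = pairwise_correlations(C)
    ii, ji, ri = pairwise_correlations(I)
    # intersect pairs surviving the constant-row rule in both contexts
    keys_c = {(a, b): k for k, (a, b) in enumerate(zip(ic, jc))}
    keys_i = {(a, b): k for k, (a, b) in enumerate(zip(ii, ji))}
    common = sorted(set(keys_c) & set(keys_i))
    if not common:
        raise ValueError("no neuron pairs with defined correlations in both contexts")
    idx_c = np.array([keys_c[p] for p in common])
    idx_i = np.array([keys_i[p] for p in common])
    pi = np.array([p[0] for p in common])
    pj = np.array([p[1] for p in common])
    delta = np.abs(rc[idx_c] - ri[idx_i])
    return CorrelationChange(
        neuron_ids=C.neuron_ids, pair_i=pi, pair_j=pj,
        r_contra=rc[idx_c], r_ipsi=ri[idx_i],
        abs_delta=delta, median_abs_delta=float(np.median(delta)),
    )


@dataclass
class TrialSplitNull:
    context: str
    samples: np.ndarray  # (n_boot,) median |delta r| under trial-split
    n_boot: int
    seed: int

    def p_value(self, observed: float) -> float:
        """Fraction of null medians at least as large as the observed one."""
        return float(np.mean(self.samples >= observed))


def _median_abs_delta(a: np.ndarray, b: np.ndarray) -> float:
    sd_a = a.std(axis=1)
    sd_b = b.std(axis=1)
    keep = (sd_a > 0) & (sd_b > 0)
    ra = np.corrcoef(a[keep])
    rb = np.corrcoef(b[keep])
    i, j = _pair_indices(int(keep.sum()))
    return float(np.median(np.abs(ra[i, j] - rb[i, j])))


def split_trial_null(
    rates: RateSeries,
    context: str,
    divisors: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> TrialSplitNull:
    """Trial-split null for the median absolute correlation change.

    Each replicate randomly halves the trials of every condition within
    ``context`` (the larger half takes the extra trial when counts are odd),
    trial-averages each half, applies the *full-data* soft-normalization
    divisors and the within-half cross-condition mean subtraction, and
    records the median |delta r| between the halves.
    """
    per_trial = sampled_perturbation_rates(rates, context)  # (N, 8, n_trials, T)
    n_trials = per_trial.shape[2]
    if n_trials < 2:
        raise ValueError(
            f"context {context!r} has a condition with fewer than 2 trials"
        )
    rng = np.random.default_rng(seed)
    samples = np.empty(n_boot)
    half = (n_trials + 1) // 2
    n, c, _, t = per_trial.shape
    for b in range(n_boot):
        # independent permutation per condition
        avg_a = np.empty((n, c, t))
        avg_b = np.empty((n, c, t))
        for cond in range(c):
            order = rng.permutation(n_trials)
            avg_a[:, cond] = per_trial[:, cond, order[:half]].mean(axis=1)
            avg_b[:, cond] = per_trial[:, cond, order[half:]].mean(axis=1)
        mat_a, _ = _assemble(avg_a, divisors)
        mat_b, _ = _assemble(avg_b, divisors)
        samples[b] = _median_abs_delta(mat_a, mat_b)
    return TrialSplitNull(context=context, samples=samples, n_boot=n_boot, seed=seed)
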