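"""Population subspaces: PCA, alignment index, joint orthogonalization.

The alignment index of a k-dimensional basis B against a covariance Cov is

    A = Tr(B' Cov B) / sum of the top-k eigenvalues of Cov,

i.e. the variance of that context's activity captured by B, normalized by the
most any k orthonormal directions could capture.  It is 1 when B spans the
covariance's top-k eigenspace and 0 when B is orthogonal to its support.
Significance comes from a variance-weighted random-subspace null: PCA on the
column-concatenation of the two context matrices, then repeated draws of two
disjoint k-subsets of those components with selection probability
proportional to the variance each captures.

Joint orthogonalization finds, over jointly orthonormal [Q_c | Q_i] (a point
on the Stiefel manifold of 2d-frames), the maximum of

    1/2 * [ Tr(Q_c' Cov_c Q_c) / (top-d eigensum of Cov_c)
          + Tr(Q_i' Cov_i Q_i) / (top-d eigensum of Cov_i) ],

by projected-gradient ascent with QR retraction, multi-start.  The maximum is
1 exactly when each context can claim its own top-d eigenspace without
conflicting with the other's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import ContextMatrix, RateSeries, _assemble, sampled_perturbation_rates

__all__ = [
    "SubspaceSet",
    "context_pca",
    "alignment_index",
    "AlignmentResult",
    "alignment_null",
    "OrthogonalPair",
    "joint_orthogonal_subspaces",
    "relative_difference",
    "ProjectionDifference",
    "relative_projection_difference",
    "WeightBalance",
    "weight_balance_index",
]


def _check_cov(cov: np.ndarray, name: str = "covariance") -> np.ndarray:
    cov = np.asarray(cov, float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(cov, cov.T, atol=1e-10 * max(1.0, np.abs(cov).max())):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(cov)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError(f"{name} is not positive semidefinite")
    return cov


def _check_orthonormal(B: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    B = np.asarray(B, float)
    if not np.allclose(B.T @ B, np.eye(B.shape[1]), atol=tol):
        raise ValueError("basis columns are not orthonormal")
    return B


def _top_eigensum(cov: np.ndarray, k: int) -> float:
    w = np.linalg.eigvalsh(cov)
    return float(np.sum(w[::-1][:k]))


@dataclass
class SubspaceSet:
    """Top-k principal components of one context with variance bookkeeping."""

    context: str
    components: np.ndarray  # (n_neurons, k), orthonormal columns
    eigenvalues: np.ndarray  # full spectrum of the source covariance
    var_captured_own: np.ndarray  # per-component fraction of own variance
    var_captured_other: np.ndarray  # per-component fraction of other-context variance

    @property
    def cumulative_own(self) -> np.ndarray:
        return np.cumsum(self.var_captured_own)

    @property
    def cumulative_other(self) -> np.ndarray:
        return np.cumsum(self.var_captured_other)


def context_pca(
    cm: ContextMatrix, other: ContextMatrix | None = None, k: int = 10
) -> SubspaceSet:
    """Top-k principal components of a context matrix (via SVD).

    ``other`` supplies the second context for cross-context variance
    bookkeeping; without it the other-context fractions are NaN.
    """
    m = cm.matrix
    if k > min(m.shape):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(m.shape)}")
    # rows already have zero mean by construction; center defensively
    m = m - m.mean(axis=1, keepdims=True)
    U, s, _ = np.linalg.svd(m, full_matrices=False)
    eig = s**2 / (m.shape[1] - 1)
    comps = U[:, :k]
    own_cov = cm.covariance()
    own = np.einsum("nk,nm,mk->k", comps, own_cov, comps) / np.trace(own_cov)
    if other is not None:
        o_cov = other.covariance()
        oth = np.einsum("nk,nm,mk->k", comps, o_cov, comps) / np.trace(o_cov)
    else:
        oth = np.full(k, np.nan)
    return SubspaceSet(
        context=cm.context, components=comps, eigenvalues=eig,
        var_captured_own=own, var_captured_other=oth,
    )


def alignment_index(basis: np.ndarray, other_cov: np.ndarray, k: int | None = None) -> float:
    """Variance of ``other_cov`` captured by ``basis``, normalized to [0, 1].

    Numerator: Tr(basis' Cov basis).  Denominator: sum of the covariance's
    top-k eigenvalues (the most any k orthonormal directions could capture),
    with k the basis width by default.
    """
    basis = _check_orthonormal(basis, tol=1e-8)
    cov = _check_cov(other_cov)
    k = basis.shape[1] if k is None else k
    denom = _top_eigensum(cov, k)
    if denom <= 0:
        raise ValueError("covariance has no variance in its top-k eigenvalues")
    return float(np.trace(basis.T @ cov @ basis) / denom)


@dataclass
class AlignmentResult:
    a_contra_on_ipsi: float
    a_ipsi_on_contra: float
    mean_index: float
    null_samples: np.ndarray  # (n_boot,) null mean indices
    null_mean: float
    null_sd: float
    p_mean: float  # fraction of null means <= observed mean (orthogonality is small)
    p_contra_on_ipsi: float
    p_ipsi_on_contra: float
    k: int
    n_boot: int
    seed: int


def alignment_null(
    C: ContextMatrix,
    I: ContextMatrix,
    k: int = 10,
    n_boot: int = 1000,
    seed: int = 0,
    disjoint: bool = False,
    method: str = "components",
) -> AlignmentResult:
    """Observed alignment indices and their variance-weighted random null.

    The null PCA runs on the column-concatenation [C I]; each replicate
    draws two random k-dimensional bases that respect the data's variance
    structure and scores them against the two context covariances exactly as
    the observed indices are scored.  Two constructions are available:

    ``method="components"`` (default)
        each basis is k principal components of the concatenated data,
        sampled without replacement with probability proportional to the
        variance each captures.  The two sets are drawn independently of
        each other; ``disjoint=True`` instead forces them to share no
        component (a stricter reading that cannot reproduce genuinely
        aligned data, since shared structure then cannot appear in both
        sets).
    ``method="rotation"``
        each basis is a random k-frame drawn by orthonormalizing
        ``Cov^(1/2) @ G`` for Gaussian ``G`` (a random rotation weighted by
        the concatenated-data covariance).

    Significant orthogonality shows up as an observed index *below* the
    null, so p is the fraction of null values at or below the observed.
    """
    cov_c = C.covariance()
    cov_i = I.covariance()
    pcs_c = context_pca(C, k=k).components
    pcs_i = context_pca(I, k=k).components
    a_c_on_i = alignment_index(pcs_c, cov_i, k)
    a_i_on_c = alignment_index(pcs_i, cov_c, k)
    observed_mean = 0.5 * (a_c_on_i + a_i_on_c)

    joint = np.concatenate([C.matrix, I.matrix], axis=1)
    joint = joint - joint.mean(axis=1, keepdims=True)
    U, s, _ = np.linalg.svd(joint, full_matrices=False)
    var = s**2
    usable = var > var[0] * 1e-12 if var.size else var
    U, var = U[:, usable], var[usable]
    n_avail = U.shape[1]
    need = 2 * k if disjoint else k
    if n_avail < need:
        raise ValueError(
            f"only {n_avail} components available; need at least {need}"
        )
    w = var / var.sum()
    rng = np.random.default_rng(seed)
    null_on_i = np.empty(n_boot)
    null_on_c = np.empty(n_boot)
    denom_i = _top_eigensum(cov_i, k)
    denom_c = _top_eigensum(cov_c, k)
    if method == "rotation":
        scale = U * np.sqrt(var)  # Cov^(1/2) up to the discarded null space
    elif method != "components":
        raise ValueError(f"unknown null method {method!r}")
    for b in range(n_boot):
        if method == "rotation":
            A = np.linalg.qr(scale @ rng.standard_normal((n_avail, k)))[0]
            B = np.linalg.qr(scale @ rng.standard_normal((n_avail, k)))[0]
        elif disjoint:
            pick = rng.choice(n_avail, size=2 * k, replace=False, p=w)
            # sequential weighted sampling biases early picks toward high
            # variance; shuffle so the two sets are exchangeable
            rng.shuffle(pick)
            A = U[:, pick[:k]]
            B = U[:, pick[k:]]
        else:
            A = U[:, rng.choice(n_avail, size=k, replace=False, p=w)]
            B = U[:, rng.choice(n_avail, size=k, replace=False, p=w)]
        null_on_i[b] = np.trace(A.T @ cov_i @ A) / denom_i
        null_on_c[b] = np.trace(B.T @ cov_c @ B) / denom_c
    null_mean_samples = 0.5 * (null_on_i + null_on_c)
    return AlignmentResult(
        a_contra_on_ipsi=a_c_on_i,
        a_ipsi_on_contra=a_i_on_c,
        mean_index=observed_mean,
        null_samples=null_mean_samples,
        null_mean=float(null_mean_samples.mean()),
        null_sd=float(null_mean_samples.std(ddof=1)),
        p_mean=float(np.mean(null_mean_samples <= observed_mean)),
        p_contra_on_ipsi=float(np.mean(null_on_i <= a_c_on_i)),
        p_ipsi_on_contra=float(np.mean(null_on_c <= a_i_on_c)),
        k=k, n_boot=n_boot, seed=seed,
    )


# ---------------------------------------------------------------------------
# joint orthogonalization on the Stiefel manifold


@dataclass
class OrthogonalPair:
    Q_contra: np.ndarray  # (n_neurons, d)
    Q_ipsi: np.ndarray
    objective: float
    var_captured: dict[str, dict[str, float]]  # basis -> context -> fraction
    grad_norm: float
    converged: bool
    restarts: int
    d: int


def _objective_and_grad(
    Q: np.ndarray, cov_c: np.ndarray, cov_i: np.ndarray, sa: float, sb: float, d: int
) -> tuple[float, np.ndarray]:
    Qc, Qi = Q[:, :d], Q[:, d:]
    Gc = cov_c @ Qc / sa
    Gi = cov_i @ Qi / sb
    f = 0.5 * (np.sum(Qc * Gc) + np.sum(Qi * Gi))
    return f, np.concatenate([Gc, Gi], axis=1)


def _retract(Q: np.ndarray) -> np.ndarray:
    R, T = np.linalg.qr(Q)
    sign = np.sign(np.diag(T))
    sign[sign == 0] = 1.0
    return R * sign


def _riemannian_grad(Q: np.ndarray, G: np.ndarray) -> np.ndarray:
    QtG = Q.T @ G
    return G - Q @ ((QtG + QtG.T) / 2.0)


def joint_orthogonal_subspaces(
    cov_contra: np.ndarray,
    cov_ipsi: np.ndarray,
    d: int = 3,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 2000,
    gtol: float = 1e-6,
) -> OrthogonalPair:
    """Jointly orthonormal per-context bases maximizing captured variance.

    Projected-gradient ascent with QR retraction and backtracking line
    search; ``n_restarts`` random starts plus one feasible start built from
    the two contexts' top-d eigenvectors (orthonormalized jointly), best
    objective kept.  Fails if no restart reaches the gradient tolerance.
    """
    cov_c = _check_cov(cov_contra, "cov_contra")
    cov_i = _check_cov(cov_ipsi, "cov_ipsi")
    if cov_c.shape != cov_i.shape:
        raise ValueError("covariances must have the same size")
    n = cov_c.shape[0]
    if 2 * d > n:
        raise ValueError("need 2*d <= number of neurons")
    sa = _top_eigensum(cov_c, d)
    sb = _top_eigensum(cov_i, d)
    if sa <= 0 or sb <= 0:
        raise ValueError("a covariance has no variance in its top-d eigenvalues")

    rng = np.random.default_rng(seed)
    wc, Vc = np.linalg.eigh(cov_c)
    wi, Vi = np.linalg.eigh(cov_i)
    pca_start = _retract(np.concatenate([Vc[:, ::-1][:, :d], Vi[:, ::-1][:, :d]], axis=1))

    starts = [pca_start] + [
        _retract(rng.standard_normal((n, 2 * d))) for _ in range(n_restarts)
    ]
    best = None
    for Q in starts:
        f, G = _objective_and_grad(Q, cov_c, cov_i, sa, sb, d)
        step = 1.0
        grad_norm = np.inf
        for _ in range(max_iter):
            R = _riemannian_grad(Q, G)
            grad_norm = float(np.linalg.norm(R))
            if grad_norm <= gtol:
                break
            # backtracking line search on the retracted step
            improved = False
            for _bt in range(40):
                Q_new = _retract(Q + step * R)
                f_new, G_new = _objective_and_grad(Q_new, cov_c, cov_i, sa, sb, d)
                if f_new > f + 1e-4 * step * grad_norm**2:
                    improved = True
                    break
                step *= 0.5
            if not improved:
                break
            Q, f, G = Q_new, f_new, G_new
            step = min(step * 2.0, 1e6)
        cand = (f, grad_norm, Q)
        if best is None or cand[0] > best[0]:
            best = cand
    f, grad_norm, Q = best
    converged = grad_norm <= gtol
    if not converged:
        raise RuntimeError(
            f"joint orthogonalization did not converge: best objective {f:.6f}, "
            f"gradient norm {grad_norm:.3g} > {gtol:g} after {max_iter} iterations "
            f"x {len(starts)} starts"
        )
    Qc, Qi = Q[:, :d], Q[:, d:]
    tc, ti = np.trace(cov_c), np.trace(cov_i)
    var = {
        "contra_dims": {
            "contra": float(np.trace(Qc.T @ cov_c @ Qc) / tc),
            "ipsi": float(np.trace(Qc.T @ cov_i @ Qc) / ti),
        },
        "ipsi_dims": {
            "contra": float(np.trace(Qi.T @ cov_c @ Qi) / tc),
            "ipsi": float(np.trace(Qi.T @ cov_i @ Qi) / ti),
        },
    }
    return OrthogonalPair(
        Q_contra=Qc, Q_ipsi=Qi, objective=float(f),
        var_captured=var, grad_norm=grad_norm, converged=converged,
        restarts=len(starts), d=d,
    )


# ---------------------------------------------------------------------------
# projections


def relative_difference(proj_ref: np.ndarray, proj_other: np.ndarray) -> float:
    """Frobenius-norm percent difference between two projected activities.

    ``100 * ||P_ref - P_other|| / ||P_ref||``: ~100% when the other context
    contributes nothing to these dimensions, 0% when the projections match,
    200% when they are antipodal.
    """
    ref_norm = np.linalg.norm(proj_ref)
    if ref_norm == 0:
        raise ValueError("reference projection has zero norm")
    return float(100.0 * np.linalg.norm(proj_ref - proj_other) / ref_norm)


@dataclass
class ProjectionDifference:
    reference: str
    value_percent: float
    bootstrap: np.ndarray
    ci_low: float
    ci_high: float
    p: float  # fraction of bootstrap replicates <= 0
    n_boot: int
    seed: int


def relative_projection_difference(
    pair: OrthogonalPair,
    rates: RateSeries,
    C: ContextMatrix,
    I: ContextMatrix,
    reference: str = "contra",
    n_boot: int = 1000,
    seed: int = 0,
) -> ProjectionDifference:
    """Relative difference between contexts within one context's dimensions.

    Both context matrices are projected onto the reference context's
    orthogonal dimensions; the non-reference context's trials are
    bootstrapped (resampled with replacement within each condition, matrix
    rebuilt with the full-data divisors) to give a CI and a one-sided p for
    the difference exceeding zero.
    """
    if reference not in ("contra", "ipsi"):
        raise ValueError("reference must be 'contra' or 'ipsi'")
    Q = pair.Q_contra if reference == "contra" else pair.Q_ipsi
    ref_cm, other_cm = (C, I) if reference == "contra" else (I, C)
    proj_ref = Q.T @ ref_cm.matrix
    observed = relative_difference(proj_ref, Q.T @ other_cm.matrix)

    other_ctx = other_cm.context
    per_trial = sampled_perturbation_rates(rates, other_ctx)  # (N, 8, n_trials, T)
    n_trials = per_trial.shape[2]
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        draw = rng.integers(0, n_trials, size=(8, n_trials))
        avg = np.stack(
            [per_trial[:, c, draw[c]].mean(axis=1) for c in range(8)], axis=1
        )
        mat, _ = _assemble(avg, other_cm.divisors)
        boot[b] = relative_difference(proj_ref, Q.T @ mat)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return ProjectionDifference(
        reference=reference, value_percent=observed, bootstrap=boot,
        ci_low=float(lo), ci_high=float(hi),
        p=float(np.mean(boot <= 0.0)), n_boot=n_boot, seed=seed,
    )


# ---------------------------------------------------------------------------
# weight balance


@dataclass
class WeightBalance:
    neuron_ids: list[int]
    index: np.ndarray  # (w_ipsi - w_contra) / (w_ipsi + w_contra), in [-1, 1]
    ks_statistic: float
    ks_p: float
    excluded: list[int]


def weight_balance_index(
    pcs_contra: np.ndarray,
    pcs_ipsi: np.ndarray,
    neuron_ids: list[int] | None = None,
) -> WeightBalance:
    """Per-neuron balance of PCA weights between contexts.

    ``w`` per neuron is the summed |weight| across the top-k components of a
    context; the index (w_ipsi - w_contra)/(w_ipsi + w_contra) is +1 for a
    neuron loading only on ipsilateral components and -1 for contralateral
    only.  A bimodal index distribution would mean PCA separated two neuron
    groups; the standardized indices are tested against normality with a
    one-sample Kolmogorov-Smirnov test.
    """
    pcs_contra = np.asarray(pcs_contra, float)
    pcs_ipsi = np.asarray(pcs_ipsi, float)
    if pcs_contra.shape != pcs_ipsi.shape:
        raise ValueError("component matrices must have the same shape")
    n = pcs_contra.shape[0]
    ids = list(range(n)) if neuron_ids is None else list(neuron_ids)
    w_c = np.abs(pcs_contra).sum(axis=1)
    w_i = np.abs(pcs_ipsi).sum(axis=1)
    total = w_i + w_c
    keep = total > 0
    excluded = [ids[i] for i in np.flatnonzero(~keep)]
    if excluded:
        import warnings

        warnings.warn(f"neurons with zero total weight excluded: {excluded}")
    idx = (w_i[keep] - w_c[keep]) / total[keep]
    if idx.size >= 3 and idx.std(ddof=1) > 0:
        z = (idx - idx.mean()) / idx.std(ddof=1)
        ks = stats.kstest(z, "norm")
        ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
    else:  # too few neurons to standardize; normality is undefined
        ks_stat, ks_p = float("nan"), float("nan")
    return WeightBalance(
        neuron_ids=[ids[i] for i in np.flatnonzero(keep)],
        index=idx, ks_statistic=ks_stat, ks_p=ks_p,
        excluded=excluded,
    )
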