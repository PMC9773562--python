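"""Heteroscedastic multivariate group comparison via the MATS statistic
with parametric-bootstrap inference.

The modified ANOVA-type statistic (MATS) compares mean vectors of ``a``
groups of d-variate observations without assuming normality, covariance
homogeneity or even non-singular covariances:

    Q_N = N (T ybar)' (T D_N T')^+ (T ybar)

where ybar stacks the a group mean vectors, D_N is the diagonal matrix of
the stacked empirical covariances scaled by N/n_i, N = sum n_i, T is a
contrast projection (default: the one-way all-groups-equal contrast
(P_a ⊗ I_d) with P_a the centering projection), and ^+ the Moore-Penrose
inverse. Using only the diagonal of the covariances makes Q_N invariant to
per-descriptor rescaling — the defining MATS property.

The p-value comes from a parametric bootstrap (paramBS): group samples are
redrawn from mean-zero multivariate normals with the groups' empirical
covariances and sizes, Q* is recomputed each iteration, and
p = #{Q* >= Q_obs} / iterations. Post-hoc pairwise contrasts rerun the
two-group bootstrap for every pair, with Holm-adjusted p-values reported
alongside the unadjusted ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "MatsResult",
    "global_contrast",
    "mats_statistic",
    "param_bootstrap_p",
    "posthoc_pairwise",
]


@dataclass
class MatsResult:
    """MATS statistic with its parametric-bootstrap p-value."""

    statistic: float
    p_boot: float
    iterations: int
    contrast: str
    per_group: list[tuple[int, np.ndarray, np.ndarray]]  # (n_i, mean, cov)

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("MATS statistic must be nonnegative")
        if not 0.0 <= self.p_boot <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


def _as_groups(groups) -> list[np.ndarray]:
    gs = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    d = gs[0].shape[1]
    for g in gs:
        if g.shape[1] != d:
            raise ValueError("all groups must share the descriptor dimension")
        if g.shape[0] < 2:
            raise ValueError("every group needs at least 2 observations")
    return gs


def global_contrast(a: int, d: int) -> np.ndarray:
    """One-way all-groups-equal contrast projection (P_a ⊗ I_d)."""
    p_a = np.eye(a) - np.full((a, a), 1.0 / a)
    return np.kron(p_a, np.eye(d))


def _stats(gs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, int]:
    """Stacked mean vector, stacked diagonal of N/n_i * cov_i, and N."""
    n_tot = sum(g.shape[0] for g in gs)
    ybar = np.concatenate([g.mean(axis=0) for g in gs])
    dvec = np.concatenate(
        [n_tot / g.shape[0] * g.var(axis=0, ddof=1) for g in gs]
    )
    return ybar, dvec, n_tot


def mats_statistic(groups, contrast: np.ndarray | None = None) -> float:
    """Compute Q_N for a list of (n_i x d) group data matrices.

    Q_N = 0 exactly when the contrast of the stacked sample means vanishes
    (e.g. identical group means under the default contrast).

    Raises
    ------
    ValueError
        If every descriptor has zero variance in every group (the scaling
        diagonal is all zero).
    """
    gs = _as_groups(groups)
    a, d = len(gs), gs[0].shape[1]
    t = global_contrast(a, d) if contrast is None else np.asarray(contrast, float)
    ybar, dvec, n_tot = _stats(gs)
    if np.all(dvec == 0):
        raise ValueError("all empirical variances are zero; MATS undefined")
    ty = t @ ybar
    middle = np.linalg.pinv((t * dvec) @ t.T, hermitian=True)
    q = float(n_tot * ty @ middle @ ty)
    return max(q, 0.0)


def _nearest_psd_chol(cov: np.ndarray, label: str = "") -> np.ndarray:
    """Cholesky-like factor of a covariance, projecting to the nearest PSD
    matrix (eigenvalue clipping) with a warning when needed."""
    cov = (cov + cov.T) / 2.0
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(cov)
        # semidefinite covariances (collinear/constant descriptors) are
        # expected and handled silently; warn only if truly indefinite
        if vals.min() < -1e-10 * max(vals.max(), 1e-300):
            warnings.warn(
                f"empirical covariance{label and ' of ' + label} not PSD; "
                "projected by eigenvalue clipping",
                RuntimeWarning,
                stacklevel=3,
            )
        vals = np.clip(vals, 0.0, None)
        return vecs * np.sqrt(vals)


def param_bootstrap_p(
    groups,
    contrast: np.ndarray | None = None,
    iterations: int = 10_000,
    seed: int | None = None,
    batch: int = 2_000,
) -> MatsResult:
    """MATS test with parametric-bootstrap (paramBS) p-value.

    Each iteration draws every group anew from a mean-zero multivariate
    normal with that group's empirical covariance and size (the null
    construction), recomputes Q*, and p is the fraction of Q* at or above
    the observed statistic.
    """
    if iterations < 1:
        raise ValueError("need at least 1 bootstrap iteration")
    gs = _as_groups(groups)
    a, d = len(gs), gs[0].shape[1]
    t = global_contrast(a, d) if contrast is None else np.asarray(contrast, float)
    q_obs = mats_statistic(gs, t)
    n_tot = sum(g.shape[0] for g in gs)
    chols = [
        _nearest_psd_chol(np.cov(g, rowvar=False, ddof=1).reshape(d, d), f"group {i}")
        for i, g in enumerate(gs)
    ]
    rng = np.random.default_rng(seed)
    n_ge = 0
    done = 0
    while done < iterations:
        b = min(batch, iterations - done)
        ybar_s = np.empty((b, a * d))
        dvec_s = np.empty((b, a * d))
        for i, (g, ch) in enumerate(zip(gs, chols)):
            n_i = g.shape[0]
            z = rng.standard_normal((b, n_i, d))
            x = z @ ch.T
            ybar_s[:, i * d : (i + 1) * d] = x.mean(axis=1)
            dvec_s[:, i * d : (i + 1) * d] = n_tot / n_i * x.var(axis=1, ddof=1)
        ty = ybar_s @ t.T  # (b, m)
        mid = np.linalg.pinv((t[None, :, :] * dvec_s[:, None, :]) @ t.T)
        q_star = n_tot * np.einsum("bi,bij,bj->b", ty, mid, ty)
        n_ge += int(np.sum(q_star >= q_obs - 1e-12))
        done += b
    return MatsResult(
        statistic=q_obs,
        p_boot=n_ge / iterations,
        iterations=iterations,
        contrast="one-way all-groups-equal (P_a ⊗ I_d)"
        if contrast is None
        else "user-supplied",
        per_group=[
            (g.shape[0], g.mean(axis=0), np.cov(g, rowvar=False, ddof=1).reshape(d, d))
            for g in gs
        ],
    )


def posthoc_pairwise(
    groups: dict[str, np.ndarray],
    iterations: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pairwise MATS bootstrap contrasts for every unordered group pair.

    Returns a table with columns group_a, group_b, statistic, p_boot and
    p_holm (Holm step-down adjustment of the unadjusted bootstrap
    p-values). Rows are unordered pairs (symmetric in a, b).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    from statsmodels.stats.multitest import multipletests

    labels = list(groups)
    seeds = np.random.SeedSequence(seed).generate_state(
        len(labels) * (len(labels) - 1) // 2
    ) % (2**31 - 1)
    rows = []
    for s, (la, lb) in zip(seeds, combinations(labels, 2)):
        res = param_bootstrap_p(
            [groups[la], groups[lb]], iterations=iterations, seed=int(s)
        )
        rows.append(
            {"group_a": la, "group_b": lb, "statistic": res.statistic, "p_boot": res.p_boot}
        )
    table = pd.DataFrame(rows)
    table["p_holm"] = multipletests(table["p_boot"], method="holm")[1]
    return table
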