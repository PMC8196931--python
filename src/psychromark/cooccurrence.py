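"""SparCC-style correlation inference on compositional OTU counts.

Sequencing counts are compositional: row sums are fixed by depth, so
Pearson correlations of relative abundances are biased.  The SparCC
procedure estimates correlations of the unobserved *basis* abundances
from the log-ratio variance matrix T_ij = var(log(x_i/x_j)) under a
sparsity assumption: basis variances solve the linear system

    [(D-1) on the diagonal, 1 elsewhere] @ w = rowsums(T)

and rho_ij = (w_i + w_j - T_ij) / (2 sqrt(w_i w_j)).  Strongly
correlated pairs violate the sparsity assumption and are iteratively
excluded from the system, which is then re-solved.  Fractions are
estimated by Dirichlet resampling of each sample's counts and the
estimate averaged over resamples.

Significance comes from shuffle nulls: each OTU's counts are bootstrap
resampled across samples (destroying inter-OTU association, preserving
marginals), the full estimator is re-run, and add-one pseudo p-values
are computed; with 100 nulls the smallest attainable p is 1/101.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

DEFAULT_ITERATIONS = 20
EXCLUSION_THRESHOLD = 0.1
N_NULL = 100
RHO_THRESHOLD = 0.5
P_MAX = 0.05


def filter_otus(
    counts: pd.DataFrame,
    min_mean: float = 2.0,
    min_prevalence_fraction: float = 56.0 / 76.0,
) -> pd.DataFrame:
    """Keep OTUs with mean count >= min_mean and detection in at least
    ceil(min_prevalence_fraction * n_samples) samples.

    ``counts`` is samples x OTUs.
    """
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    n_samples = counts.shape[0]
    min_prev = int(np.ceil(min_prevalence_fraction * n_samples))
    mean_ok = counts.mean(axis=0) >= min_mean
    prev_ok = (counts > 0).sum(axis=0) >= min_prev
    kept = counts.loc[:, mean_ok & prev_ok]
    if kept.shape[1] == 0:
        raise ValueError("all OTUs removed by filtering")
    return kept


def _basis_correlations(
    log_fracs: np.ndarray, iterations: int, exclusion_threshold: float
) -> np.ndarray:
    """Solve the basis-variance system with iterative strong-pair exclusion."""
    d = log_fracs.shape[1]
    # variation matrix T_ij = var over samples of log(x_i/x_j)
    var = np.var(log_fracs, axis=0)
    cov = np.cov(log_fracs, rowvar=False)
    t_mat = var[:, None] + var[None, :] - 2.0 * cov
    np.fill_diagonal(t_mat, 0.0)

    m = np.ones((d, d)) + np.diag([d - 2.0] * d)
    t_vec = t_mat.sum(axis=1)
    excluded: set[tuple[int, int]] = set()
    rho = None
    for _ in range(max(iterations, 1)):
        w = np.linalg.solve(m, t_vec)
        w = np.clip(w, 1e-12, None)
        denom = 2.0 * np.sqrt(np.outer(w, w))
        rho = (w[:, None] + w[None, :] - t_mat) / denom
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        # most correlated not-yet-excluded pair
        cand = np.abs(rho).copy()
        np.fill_diagonal(cand, 0.0)
        for i, j in excluded:
            cand[i, j] = cand[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        excluded.add((min(i, j), max(i, j)))
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        m[i, j] -= 1.0
        m[j, i] -= 1.0
        t_vec[i] -= t_mat[i, j]
        t_vec[j] -= t_mat[i, j]
        if m[i, i] < 2 or m[j, j] < 2:  # an OTU excluded from almost everything
            break
    return rho


def sparcc_correlations(
    counts: pd.DataFrame,
    iterations: int = DEFAULT_ITERATIONS,
    exclusion_threshold: float = EXCLUSION_THRESHOLD,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Estimate basis correlations from a samples x OTUs count matrix.

    ``iterations`` sets both the number of Dirichlet resamples averaged
    and the cap on strong-pair exclusion rounds per resample.
    """
    arr = counts.to_numpy(dtype=float)
    n, d = arr.shape
    if d < 10:
        raise ValueError("SparCC needs >= 10 OTUs")
    if n < 10:
        raise ValueError("SparCC needs >= 10 samples")
    if (arr.sum(axis=0) == 0).any():
        raise ValueError("OTUs with all-zero counts must be filtered first")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    acc = np.zeros((d, d))
    for _ in range(iterations):
        fracs = np.empty_like(arr)
        for s in range(n):
            fracs[s] = rng.dirichlet(arr[s] + 1.0)
        rho = _basis_correlations(np.log(fracs), iterations, exclusion_threshold)
        acc += rho
    rho_mean = np.clip(acc / iterations, -1.0, 1.0)
    np.fill_diagonal(rho_mean, 1.0)
    rho_mean = (rho_mean + rho_mean.T) / 2.0
    return pd.DataFrame(rho_mean, index=counts.columns, columns=counts.columns)


def pseudo_pvalues(
    counts: pd.DataFrame,
    n_null: int = N_NULL,
    seed: int | np.random.Generator = 0,
    iterations: int = DEFAULT_ITERATIONS,
    exclusion_threshold: float = EXCLUSION_THRESHOLD,
    rho_obs: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Shuffle-null pseudo p-values for the observed correlation matrix.

    Each null dataset bootstrap-resamples every OTU's counts across
    samples independently (with replacement).  Add-one formulas:

        p_two(i,j) = (1 + #{null: |rho_null| >= |rho_obs|}) / (1 + n_null)
        p_one(i,j) = (1 + #{null: rho_null >= rho_obs}) / (1 + n_null)
                     (mirrored for negative rho_obs)

    Returns (rho_obs, p_one_sided, p_two_sided).
    """
    if n_null < 10:
        warnings.warn("fewer than 10 null datasets; pseudo p-values are coarse")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if rho_obs is None:
        rho_obs = sparcc_correlations(
            counts, iterations, exclusion_threshold, seed=rng
        )
    obs = rho_obs.to_numpy()
    arr = counts.to_numpy()
    n, d = arr.shape
    ge_two = np.zeros((d, d))
    ge_one = np.zeros((d, d))
    for _ in range(n_null):
        null = np.empty_like(arr)
        for k in range(d):
            null[:, k] = arr[rng.integers(0, n, size=n), k]
        # a resampled OTU can be all-zero by chance; re-draw that column
        while (null.sum(axis=0) == 0).any():
            for k in np.where(null.sum(axis=0) == 0)[0]:
                null[:, k] = arr[rng.integers(0, n, size=n), k]
        rho_null = sparcc_correlations(
            pd.DataFrame(null, columns=counts.columns),
            iterations,
            exclusion_threshold,
            seed=rng,
        ).to_numpy()
        ge_two += np.abs(rho_null) >= np.abs(obs)
        ge_one += np.where(obs >= 0, rho_null >= obs, rho_null <= obs)
    p_two = (1.0 + ge_two) / (1.0 + n_null)
    p_one = (1.0 + ge_one) / (1.0 + n_null)
    idx = counts.columns
    return (
        rho_obs,
        pd.DataFrame(p_one, index=idx, columns=idx),
        pd.DataFrame(p_two, index=idx, columns=idx),
    )


def strong_edges(
    rho: pd.DataFrame,
    p_two_sided: pd.DataFrame,
    rho_threshold: float = RHO_THRESHOLD,
    p_max: float = P_MAX,
) -> pd.DataFrame:
    """Edges with |rho| strictly above the threshold and p <= p_max."""
    if rho.shape != p_two_sided.shape:
        raise ValueError("rho and p matrices must be conformable")
    rows = []
    otus = list(rho.index)
    r = rho.to_numpy()
    p = p_two_sided.to_numpy()
    for i in range(len(otus)):
        for j in range(i + 1, len(otus)):
            if abs(r[i, j]) > rho_threshold and p[i, j] <= p_max:
                rows.append(
                    {
                        "otu_i": otus[i],
                        "otu_j": otus[j],
                        "rho": float(r[i, j]),
                        "p_two_sided": float(p[i, j]),
                        "sign": "positive" if r[i, j] > 0 else "negative",
                    }
                )
    return pd.DataFrame(rows, columns=["otu_i", "otu_j", "rho", "p_two_sided", "sign"])
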