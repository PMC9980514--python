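"""Nonparametric group statistics, multiple-testing correction, and
compositional correlation networks.

Group comparisons (Kruskal-Wallis, Dunn post-hoc, Mann-Whitney, Pearson
chi-squared) are the tests used throughout infant-microbiome association
tables; correlations between taxa are estimated on compositional count data
with SparCC (log-ratio variances solved for basis variances, with iterative
exclusion of strongly correlated pairs) after centered log-ratio thinking,
because raw relative abundances induce spurious negative correlation.

All tests are two-sided. BH-FDR q-values are computed within one analysis
table (one family per call).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# rank-based tests
# ---------------------------------------------------------------------------

def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-squared p-value.

    Degenerate input where every value is identical yields ``(0.0, 1.0)``
    rather than NaN: no evidence against the null.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("kruskal_wallis requires >= 2 non-empty groups")
    samples = [values[groups == g] for g in levels]
    if np.ptp(values) == 0:
        return 0.0, 1.0
    H, p = sps.kruskal(*samples)
    return float(H), float(p)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when ``len(x)+len(y) <= 16`` and there are no ties,
    otherwise the normal approximation with tie and continuity correction.
    Returns (U of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:  # every value tied: no evidence either way
        return float(x.size * y.size / 2.0), 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 16 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def dunn_posthoc(values, groups, adjust: str = "bh") -> pd.DataFrame:
    """Dunn's post-hoc z-tests on the joint ranks, after Kruskal-Wallis.

    For groups i, j::

        z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))

    with the tie correction ``T = sum(t^3 - t) / (12 (N - 1))`` over tie
    groups of size t. Two-sided normal p-values; BH adjustment across the
    family of pairs when ``adjust='bh'``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 3:
        raise ValueError("dunn_posthoc needs >= 3 groups (use mann_whitney for 2)")
    counts = {g: int((groups == g).sum()) for g in levels}
    if min(counts.values()) == 0:
        raise ValueError("empty group")
    N = values.size
    ranks = sps.rankdata(values)
    _, tie_sizes = np.unique(values, return_counts=True)
    T = float(((tie_sizes**3 - tie_sizes).sum()) / (12.0 * (N - 1)))
    var_term = N * (N + 1) / 12.0 - T
    rows = []
    for a_idx in range(len(levels)):
        for b_idx in range(a_idx + 1, len(levels)):
            a, b = levels[a_idx], levels[b_idx]
            ra = ranks[groups == a].mean()
            rb = ranks[groups == b].mean()
            se = np.sqrt(var_term * (1.0 / counts[a] + 1.0 / counts[b]))
            z = (ra - rb) / se if se > 0 else 0.0
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append((a, b, z, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])
    out["q"] = bh_fdr(out["p"].to_numpy()) if adjust == "bh" else out["p"]
    return out


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def chi_squared(table) -> tuple[float, float]:
    """Pearson's chi-squared test of independence on a two-way count table.

    No Yates correction. Warns when any expected count is below 5; raises
    when a margin is zero or an expected count falls below 1.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or np.any(tab < 0):
        raise ValueError("table must be a 2-d non-negative count table")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
    if np.any(expected < 1):
        raise ValueError("expected count below 1; chi-squared unreliable")
    if np.any(expected < 5):
        warnings.warn("expected count below 5; chi-squared approximation is weak")
    stat, p, _, _ = sps.chi2_contingency(tab, correction=False)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# compositional transforms and SparCC
# ---------------------------------------------------------------------------

def clr_transform(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centered log-ratio transform per sample (row): log(x+pc) minus the
    row mean of log(x+pc). Rows sum to zero."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    x = np.log(np.asarray(counts, dtype=float) + pseudocount)
    x = x - x.mean(axis=1, keepdims=True)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(x, index=counts.index, columns=counts.columns)
    return x


def _basis_variances(t_mat: np.ndarray, active: np.ndarray) -> np.ndarray:
    """Solve the SparCC linear system for basis variances omega_i^2.

    Under the sparsity assumption t_ij ~ omega_i^2 + omega_j^2 for active
    (non-excluded) pairs, so summing over each row's active partners gives a
    linear system M w = t_rowsum with M[i,i] = #active partners of i and
    M[i,j] = active indicator.
    """
    M = active.astype(float)
    np.fill_diagonal(M, active.sum(axis=1))
    t_sum = (t_mat * active).sum(axis=1)
    try:
        w = np.linalg.solve(M, t_sum)
    except np.linalg.LinAlgError:
        w = np.linalg.lstsq(M, t_sum, rcond=None)[0]
    return np.clip(w, 1e-10, None)


def sparcc(
    counts: pd.DataFrame,
    n_exclusion_iters: int = 10,
    exclusion_threshold: float = 0.1,
    pseudocount: float = 0.5,
    seed: int | None = None,
) -> pd.DataFrame:
    """SparCC correlation estimate for compositional count data.

    Computes the variation matrix t_ij = var(log((x_i+pc)/(x_j+pc))) across
    samples, solves for basis variances, and converts to correlations
    rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j)), clipped to [-1, 1].
    The most correlated pair with |rho| above ``exclusion_threshold`` is
    removed from the basis system each round (up to ``n_exclusion_iters``
    rounds) to de-bias the sparsity assumption.

    ``seed`` is accepted for interface symmetry; this fixed-pseudocount
    variant is deterministic.
    """
    X = np.asarray(counts, dtype=float)
    n, d = X.shape
    if d < 4:
        raise ValueError("sparcc needs >= 4 taxa for an identifiable basis")
    if n < 10:
        raise ValueError("sparcc needs >= 10 samples")
    logx = np.log(X + pseudocount)
    # t_ij = var(log x_i - log x_j) = v_i + v_j - 2 cov_ij
    cov = np.cov(logx, rowvar=False)
    v = np.diag(cov)
    t_mat = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(t_mat, 0.0)

    active = ~np.eye(d, dtype=bool)
    w = _basis_variances(t_mat, active)
    for _ in range(int(n_exclusion_iters)):
        sw = np.sqrt(w)
        rho = (w[:, None] + w[None, :] - t_mat) / (2.0 * np.outer(sw, sw))
        np.fill_diagonal(rho, 1.0)
        cand = np.abs(rho) * active
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        active[i, j] = active[j, i] = False
        if active.sum(axis=1).min() < 2:  # keep system solvable
            active[i, j] = active[j, i] = True
            break
        w = _basis_variances(t_mat, active)
    sw = np.sqrt(w)
    rho = (w[:, None] + w[None, :] - t_mat) / (2.0 * np.outer(sw, sw))
    rho = np.clip(rho, -1.0, 1.0)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(rho, index=counts.columns, columns=counts.columns)
    return rho


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

@dataclass
class Network:
    """Thresholded taxon co-occurrence network.

    nodes: per-taxon prevalence, mean relative abundance and degree;
    edges: undirected (taxon_a < taxon_b), |correlation| >= threshold.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame
    corr: pd.DataFrame = field(repr=False, default=None)


def build_network(
    counts: pd.DataFrame,
    top_n: int = 20,
    prevalence_min: float = 0.25,
    corr_threshold: float = 0.2,
    method: str = "sparcc",
    seed: int | None = None,
) -> Network:
    """Species co-occurrence network: prevalence filter, top-``top_n`` taxa
    by mean relative abundance, SparCC correlations, absolute-value
    thresholding at ``corr_threshold``."""
    if method != "sparcc":
        raise ValueError(f"unknown correlation method: {method}")
    X = counts.astype(float)
    prevalence = (X > 0).mean(axis=0)
    keep = prevalence[prevalence >= prevalence_min].index
    if len(keep) < top_n:
        warnings.warn(
            f"only {len(keep)} taxa pass the prevalence filter (< top_n={top_n})"
        )
    rel = X.div(X.sum(axis=1), axis=0)
    mean_abund = rel[keep].mean(axis=0)
    top = mean_abund.sort_values(ascending=False).index[:top_n]
    if len(top) < 4:
        raise ValueError("fewer than 4 taxa after filtering; network undefined")
    rho = sparcc(X[top], seed=seed)
    rows = []
    taxa = list(top)
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            r = float(rho.iloc[i, j])
            if abs(r) >= corr_threshold:
                a, b = sorted((taxa[i], taxa[j]))
                rows.append((a, b, r, "positive" if r > 0 else "negative"))
    edges = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "correlation", "sign"])
    degree = pd.Series(0, index=taxa, dtype=int)
    for _, e in edges.iterrows():
        degree[e.taxon_a] += 1
        degree[e.taxon_b] += 1
    nodes = pd.DataFrame(
        {
            "taxon": taxa,
            "prevalence": prevalence[top].to_numpy(),
            "mean_abundance": mean_abund[top].to_numpy(),
            "degree": degree[top].to_numpy(),
        }
    )
    return Network(nodes=nodes, edges=edges, corr=rho)
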