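"""Dirichlet-multinomial mixture (DMM) community typing and ecological
diversity statistics.

The DMM models each stool sample's genus-level count vector as a multinomial
draw whose composition comes from one of K Dirichlet components; the fitted
components are the gut microbiome community (GMC) types. Fitting is EM:
responsibilities in the E-step, mixture weights and per-component Dirichlet
parameters (numerical maximization in log-alpha space) in the M-step. The
number of components is chosen by minimizing a Laplace approximation to the
negative log model evidence.

Also here: rarefaction, alpha diversity (richness, Shannon, inverse
Simpson), Bray-Curtis dissimilarity, and a permutation PERMANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform
from scipy.special import digamma, gammaln, logsumexp
from sklearn.cluster import KMeans

from .stats import clr_transform

_LOG_ALPHA_MIN = np.log(1e-6)  # keeps the Dirichlet domain open
_LOG_ALPHA_MAX = np.log(1e6)
_PRIOR_SD = 3.0  # N(0, sd^2) prior on each log-alpha (Laplace evidence)


# ---------------------------------------------------------------------------
# Dirichlet-multinomial density
# ---------------------------------------------------------------------------

def dm_log_pmf(x, alpha) -> float:
    """Log pmf of the Dirichlet-multinomial for count vector ``x`` with
    Dirichlet parameter ``alpha``::

        log C(N; x) + logG(A) - logG(N+A) + sum_j [logG(x_j+a_j) - logG(a_j)]

    where A = sum(alpha), N = sum(x) and C is the multinomial coefficient.
    Sums to 1 over all count vectors with total N (enumeration-tested).
    """
    x = np.asarray(x, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if x.shape != alpha.shape:
        raise ValueError("x and alpha must have the same length")
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise ValueError("counts must be non-negative integers")
    if np.any(alpha <= 0):
        raise ValueError("alpha must be strictly positive")
    N = x.sum()
    A = alpha.sum()
    coef = gammaln(N + 1) - gammaln(x + 1).sum()
    return float(
        coef + gammaln(A) - gammaln(N + A) + (gammaln(x + alpha) - gammaln(alpha)).sum()
    )


def _component_loglik(X: np.ndarray, N: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-sample DM log-likelihood for one component, without the
    multinomial coefficient (constant across components)."""
    A = alpha.sum()
    return (
        gammaln(A)
        - gammaln(N + A)
        + (gammaln(X + alpha) - gammaln(alpha)).sum(axis=1)
    )


def _fit_dirichlet_weighted(
    X: np.ndarray, N: np.ndarray, w: np.ndarray, alpha0: np.ndarray
) -> np.ndarray:
    """Maximize the responsibility-weighted DM log-likelihood over alpha > 0
    by L-BFGS in log-alpha space (gradient analytic)."""

    def neg(log_a):
        a = np.exp(log_a)
        return -float(w @ _component_loglik(X, N, a))

    def grad(log_a):
        a = np.exp(log_a)
        A = a.sum()
        g = w @ (digamma(X + a) - digamma(a)) + (w * (digamma(A) - digamma(N + A))).sum()
        return -g * a

    res = minimize(
        neg,
        np.log(np.clip(alpha0, 1e-6, 1e6)),
        jac=grad,
        method="L-BFGS-B",
        bounds=[(_LOG_ALPHA_MIN, _LOG_ALPHA_MAX)] * X.shape[1],
        options={"maxiter": 200},
    )
    return np.exp(res.x)


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class DMMModel:
    K: int
    pi: np.ndarray
    alpha: np.ndarray  # (K, J)
    responsibilities: pd.DataFrame  # n x K
    log_likelihood: float
    laplace_score: float
    converged: bool
    n_iter: int
    loglik_trace: list = field(default_factory=list, repr=False)
    taxa: list = field(default_factory=list, repr=False)


@dataclass
class GMCAssignment:
    sample_id: str
    gmc_type: int
    max_responsibility: float


def _counts_to_array(counts: pd.DataFrame) -> tuple[np.ndarray, list, list]:
    X = np.asarray(counts, dtype=float)
    if np.any(X < 0):
        raise ValueError("counts must be non-negative")
    if np.any(X.sum(axis=1) == 0):
        raise ValueError("every sample needs at least one positive count")
    idx = list(counts.index) if isinstance(counts, pd.DataFrame) else list(range(X.shape[0]))
    cols = list(counts.columns) if isinstance(counts, pd.DataFrame) else list(range(X.shape[1]))
    return X, idx, cols


def _log_prior(log_alpha: np.ndarray) -> float:
    return float(
        -0.5 * (log_alpha**2).sum() / _PRIOR_SD**2
        - log_alpha.size * np.log(_PRIOR_SD * np.sqrt(2 * np.pi))
    )


def _laplace_score(
    X: np.ndarray, N: np.ndarray, pi: np.ndarray, alpha: np.ndarray, resp: np.ndarray,
    loglik: float,
) -> float:
    """Negative log model evidence by Laplace approximation.

    Evidence ~ L(theta*) p(theta*) (2 pi)^{d/2} |H|^{-1/2}, with H the
    negative Hessian of the log posterior over the d = K*J log-alpha
    parameters, approximated block-diagonally per component with E-step
    weights frozen (central finite differences of the analytic gradient).
    """
    K, J = alpha.shape
    d = K * J
    log_prior_total = 0.0
    logdet_total = 0.0
    for k in range(K):
        la = np.log(alpha[k])
        w = resp[:, k]
        log_prior_total += _log_prior(la)

        def grad(log_a):
            a = np.exp(log_a)
            A = a.sum()
            g = w @ (digamma(X + a) - digamma(a)) + (
                w * (digamma(A) - digamma(N + A))
            ).sum()
            return g * a - log_a / _PRIOR_SD**2  # gradient of log posterior

        H = np.zeros((J, J))
        h = 1e-4
        for j in range(J):
            e = np.zeros(J)
            e[j] = h
            H[:, j] = -(grad(la + e) - grad(la - e)) / (2 * h)
        H = (H + H.T) / 2.0
        eig, V = np.linalg.eigh(H)
        eig = np.clip(eig, 1e-8, None)  # guard flat/indefinite directions
        logdet_total += float(np.log(eig).sum())
    log_evidence = (
        loglik + log_prior_total + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet_total
    )
    return -log_evidence


# ---------------------------------------------------------------------------
# EM fit and model selection
# ---------------------------------------------------------------------------

def dmm_fit(
    counts: pd.DataFrame,
    K: int,
    seed: int,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> DMMModel:
    """Fit a K-component Dirichlet-multinomial mixture by EM.

    Initialization is k-means on CLR-transformed proportions; an emptied
    component is re-seeded from the worst-fit sample (at most 3 times).
    The observed-data log-likelihood is non-decreasing across plain EM
    iterations; ``converged`` is False if ``max_iter`` is exhausted.
    """
    X, idx, cols = _counts_to_array(counts)
    n, J = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of samples n={n}")
    N = X.sum(axis=1)
    coef = float((gammaln(N + 1) - gammaln(X + 1).sum(axis=1)).sum())
    rng = np.random.default_rng(seed)

    # --- init: k-means on CLR proportions
    clr = np.asarray(clr_transform(pd.DataFrame(X)))
    if K == 1:
        labels = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=K, n_init=3, random_state=int(rng.integers(2**31 - 1)))
        labels = km.fit_predict(clr)
    P = X / N[:, None]
    alpha = np.empty((K, J))
    pi = np.empty(K)
    for k in range(K):
        mask = labels == k
        if mask.sum() == 0:
            mask = np.ones(n, dtype=bool)
        mean_p = np.clip(P[mask].mean(axis=0), 1e-6, None)
        alpha[k] = mean_p * 50.0  # moderate initial precision; refined by M-step
        pi[k] = max(mask.mean(), 1e-3)
    pi /= pi.sum()

    loglik = -np.inf
    trace = []
    converged = False
    reseeds = 0
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        comp_ll = np.column_stack([_component_loglik(X, N, alpha[k]) for k in range(K)])
        log_w = np.log(pi)[None, :] + comp_ll
        log_norm = logsumexp(log_w, axis=1)
        resp = np.exp(log_w - log_norm[:, None])
        new_loglik = float(log_norm.sum()) + coef

        # handle emptied components by re-seeding from the worst-fit sample
        sizes = resp.sum(axis=0)
        if sizes.min() < 1e-8 and reseeds < 3:
            k_empty = int(np.argmin(sizes))
            worst = int(np.argmin(log_norm))
            alpha[k_empty] = np.clip(P[worst], 1e-6, None) * 50.0
            pi = np.clip(pi, 1e-6, None)
            pi /= pi.sum()
            reseeds += 1
            continue

        # M-step
        pi = np.clip(resp.mean(axis=0), 1e-10, None)
        pi /= pi.sum()
        for k in range(K):
            alpha[k] = _fit_dirichlet_weighted(X, N, resp[:, k], alpha[k])

        trace.append(new_loglik)
        if np.isfinite(loglik):
            rel = abs(new_loglik - loglik) / (abs(loglik) + 1e-12)
            if rel < tol:
                loglik = new_loglik
                converged = True
                break
        loglik = new_loglik
    if not converged:
        warnings.warn(f"DMM EM did not converge in {max_iter} iterations (K={K})")

    comp_ll = np.column_stack([_component_loglik(X, N, alpha[k]) for k in range(K)])
    log_w = np.log(pi)[None, :] + comp_ll
    log_norm = logsumexp(log_w, axis=1)
    resp = np.exp(log_w - log_norm[:, None])
    loglik = float(log_norm.sum()) + coef
    score = _laplace_score(X, N, pi, alpha, resp, loglik)
    return DMMModel(
        K=K,
        pi=pi,
        alpha=alpha,
        responsibilities=pd.DataFrame(resp, index=idx, columns=[f"C{k+1}" for k in range(K)]),
        log_likelihood=loglik,
        laplace_score=score,
        converged=converged,
        n_iter=it,
        loglik_trace=trace,
        taxa=cols,
    )


def dmm_select(
    counts: pd.DataFrame,
    K_range,
    seed: int,
    n_restarts: int = 3,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[int, dict]:
    """Fit every K in ``K_range`` with ``n_restarts`` seeds each, keep the
    best-likelihood fit per K, and return the K minimizing the Laplace
    score together with the fitted models (``models[K]``)."""
    K_list = sorted(set(int(k) for k in K_range))
    if not K_list or min(K_list) < 1:
        raise ValueError("K_range must be a non-empty set of integers >= 1")
    ss = np.random.SeedSequence(seed)
    models: dict[int, DMMModel] = {}
    for K in K_list:
        best = None
        for child in ss.spawn(n_restarts):
            m = dmm_fit(counts, K, seed=int(child.generate_state(1)[0] % (2**31)),
                        max_iter=max_iter, tol=tol)
            if best is None or m.log_likelihood > best.log_likelihood:
                best = m
        models[K] = best
    best_K = min(K_list, key=lambda K: models[K].laplace_score)
    return best_K, models


def assign_gmc(model: DMMModel) -> pd.DataFrame:
    """Hard GMC assignments from the responsibilities (argmax, ties to the
    lower index), with types relabeled 1..K in decreasing prevalence so that
    GMC type 1 is always the most common community type."""
    resp = model.responsibilities.to_numpy()
    raw = resp.argmax(axis=1)  # argmax takes the first (lowest) index on ties
    sizes = np.bincount(raw, minlength=model.K)
    order = np.argsort(-sizes, kind="stable")  # stable: ties keep original order
    relabel = np.empty(model.K, dtype=int)
    relabel[order] = np.arange(1, model.K + 1)
    return pd.DataFrame(
        {
            "sample_id": model.responsibilities.index,
            "gmc_type": relabel[raw],
            "max_responsibility": resp.max(axis=1),
        }
    )


# ---------------------------------------------------------------------------
# counts utilities, diversity, beta-diversity
# ---------------------------------------------------------------------------

def rescale_to_counts(rel_abund: pd.DataFrame, pseudo_total: int = 10000) -> pd.DataFrame:
    """Convert relative abundances to integer pseudo-counts summing exactly
    to ``pseudo_total`` per sample, by largest-remainder rounding."""
    if pseudo_total < 100:
        raise ValueError("pseudo_total must be >= 100")
    R = np.asarray(rel_abund, dtype=float)
    if np.any(R < 0):
        raise ValueError("relative abundances must be non-negative")
    R = R / R.sum(axis=1, keepdims=True)
    raw = R * pseudo_total
    base = np.floor(raw).astype(int)
    short = pseudo_total - base.sum(axis=1)
    frac = raw - base
    out = base.copy()
    for i in range(R.shape[0]):
        if short[i] > 0:
            top = np.argsort(-frac[i], kind="stable")[: short[i]]
            out[i, top] += 1
    return pd.DataFrame(out, index=rel_abund.index, columns=rel_abund.columns)


def rarefy(counts: pd.DataFrame, depth: int | None = None, seed: int = 0) -> pd.DataFrame:
    """Subsample each sample to ``depth`` reads without replacement
    (multivariate hypergeometric). Samples shallower than ``depth`` are
    dropped with a warning. Default depth: the minimum sample total."""
    X = np.asarray(counts, dtype=np.int64)
    if np.any(X < 0):
        raise ValueError("counts must be non-negative")
    totals = X.sum(axis=1)
    if depth is None:
        depth = int(totals.min())
    if depth <= 0:
        raise ValueError("depth must be positive")
    keep = totals >= depth
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} samples shallower than depth={depth}")
    rng = np.random.default_rng(seed)
    rows = []
    for x, tot in zip(X[keep], totals[keep]):
        if tot == depth:
            rows.append(x.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(x, depth))
    idx = counts.index[keep] if isinstance(counts, pd.DataFrame) else np.arange(keep.sum())
    return pd.DataFrame(np.array(rows, dtype=np.int64), index=idx, columns=counts.columns)


def alpha_diversity(counts: pd.DataFrame) -> pd.DataFrame:
    """Richness (taxa with count > 0), Shannon's H (natural log), and
    inverse Simpson per sample."""
    X = np.asarray(counts, dtype=float)
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("all-zero sample")
    P = X / totals[:, None]
    richness = (X > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    shannon = -plogp.sum(axis=1)
    inv_simpson = 1.0 / (P**2).sum(axis=1)
    return pd.DataFrame(
        {"richness": richness, "shannon": shannon, "inv_simpson": inv_simpson},
        index=counts.index,
    )


def bray_curtis(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity:
    d(u, v) = 1 - 2 sum_j min(u_j, v_j) / (sum u + sum v)."""
    X = np.asarray(counts, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    D = squareform(pdist(X, metric="braycurtis"))
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(D, index=counts.index, columns=counts.index)
    return D


def permanova(
    dist, groups, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """One-way PERMANOVA on a distance matrix.

    pseudo-F = (SS_among/(k-1)) / (SS_within/(n-k)) with sums of squared
    distances SS_total = sum_{i<j} d_ij^2 / n and SS_within accumulated per
    group; the p-value is (1 + #{permuted F >= observed}) / (1 + n_perm).
    """
    D = np.asarray(dist, dtype=float)
    labels = np.asarray(groups)
    n = D.shape[0]
    if D.shape != (n, n) or labels.shape[0] != n:
        raise ValueError("distance matrix and labels are inconsistent")
    levels, inv = np.unique(labels, return_inverse=True)
    k = len(levels)
    if k < 2:
        raise ValueError("need >= 2 groups")
    sizes = np.bincount(inv)
    if sizes.min() < 2:
        raise ValueError("every group needs >= 2 samples")
    D2 = D**2
    ss_total = D2.sum() / (2.0 * n)

    def f_from(inv_labels: np.ndarray) -> float:
        ss_within = 0.0
        for g in range(k):
            mask = inv_labels == g
            ss_within += D2[np.ix_(mask, mask)].sum() / (2.0 * mask.sum())
        ss_among = ss_total - ss_within
        return (ss_among / (k - 1)) / (ss_within / (n - k))

    f_obs = f_from(inv)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(inv) for _ in range(n_perm)])
    # vectorized within-group sums over all permutations
    f_perm = np.empty(n_perm)
    ss_within_p = np.zeros(n_perm)
    for g in range(k):
        M = (perms == g).astype(float)  # (n_perm, n)
        ss_within_p += np.einsum("pi,ij,pj->p", M, D2, M) / (2.0 * sizes[g])
    ss_among_p = ss_total - ss_within_p
    f_perm = (ss_among_p / (k - 1)) / (ss_within_p / (n - k))
    p = (1.0 + np.sum(f_perm >= f_obs)) / (1.0 + n_perm)
    return float(f_obs), float(p)
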