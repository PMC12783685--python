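"""Iterative mixture-model batch integration (Harmony-style).

Implements the soft k-means / mixture-of-experts batch-integration scheme of
Korsunsky et al. (2019) on a feature matrix:

1. Soft-cluster records on the cosine sphere with an entropy-regularized
   k-means whose assignment step carries a *diversity* penalty pushing every
   cluster to mix all batch levels,
2. within each soft cluster, fit a ridge-penalized linear model of the
   features on batch indicators (a mixture of experts) and subtract the
   batch-specific terms, keeping the cluster intercept,
3. iterate cluster/correct until the correction stabilizes.

Correction is always recomputed from the *original* matrix with the current
soft assignments, so repeated rounds refine rather than accumulate.  All
randomness (centroid initialization) comes from a caller-supplied seed.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.cluster import KMeans

__all__ = ["harmonize"]


def _one_hot(labels: np.ndarray) -> np.ndarray:
    """(levels x n) indicator matrix for one categorical covariate."""
    levels, inverse = np.unique(np.asarray(labels), return_inverse=True)
    if len(levels) < 2:
        raise ValueError(
            f"batch covariate has a single level ({levels[0]!r}); need >= 2 levels"
        )
    phi = np.zeros((len(levels), len(labels)))
    phi[inverse, np.arange(len(labels))] = 1.0
    return phi


def harmonize(
    X: np.ndarray,
    covariates: list[np.ndarray],
    *,
    n_clusters: int | None = None,
    theta: float = 2.0,
    sigma: float = 0.1,
    ridge_lambda: float = 0.1,
    max_iter: int = 20,
    kmeans_iter: int = 10,
    tol: float = 1e-3,
    seed: int = 0,
) -> np.ndarray:
    """Return a batch-corrected copy of ``X`` (n_records x D).

    Parameters
    ----------
    covariates:
        One label array of length n per batch variable (e.g. replica, FOV);
        each contributes an indicator block to the mixture design.
    theta:
        Diversity-penalty strength; 0 disables batch mixing pressure.
    sigma:
        Entropy regularization (softness) of the cluster assignments.
    ridge_lambda:
        Ridge penalty on the batch terms of each cluster's linear model
        (the intercept is unpenalized and never subtracted).
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least two records to integrate")
    phi = np.vstack([_one_hot(c) for c in covariates])  # B x n
    B = phi.shape[0]
    pr = phi.mean(axis=1)  # marginal batch frequencies

    # few, well-populated clusters: each (cluster, batch) cell needs enough
    # weight for a stable mixture-of-experts estimate of its batch offset
    K = n_clusters if n_clusters is not None else int(min(30, max(2, n // 200)))

    Z_orig = X.T.copy()  # d x n
    Z_corr = Z_orig.copy()

    def _cos(Z):
        return Z / (np.linalg.norm(Z, axis=0, keepdims=True) + 1e-12)

    Z_cos = _cos(Z_corr)
    km = KMeans(n_clusters=K, n_init=4, max_iter=25, random_state=int(seed) % (2**31))
    km.fit(Z_cos.T)
    Y = _cos(km.cluster_centers_.T)  # d x K

    phi1 = np.vstack([np.ones(n), phi])  # (B+1) x n
    lamb = np.concatenate([[0.0], np.full(B, ridge_lambda)])

    converged = False
    prev_delta = np.inf
    for _ in range(max_iter):
        # --- clustering with diversity penalty -----------------------------
        for _ in range(kmeans_iter):
            dist = 2.0 * (1.0 - Y.T @ Z_cos)  # K x n, squared cosine distance
            R = np.exp(-dist / sigma)
            O = R @ phi.T  # K x B observed co-occurrence
            E = R.sum(axis=1, keepdims=True) * pr[None, :]  # expected under mixing
            R *= ((E + 1.0) / (O + 1.0)) ** theta @ phi
            R /= R.sum(axis=0, keepdims=True) + 1e-300
            Y = _cos(Z_cos @ R.T)

        # --- mixture-of-experts ridge correction ---------------------------
        Z_new = Z_orig.copy()
        for k in range(K):
            phi_rk = phi1 * R[k]  # (B+1) x n
            A = phi_rk @ phi1.T + np.diag(lamb)
            W = np.linalg.solve(A, phi_rk @ Z_orig.T)  # (B+1) x d
            W[0] = 0.0  # keep the cluster intercept
            Z_new -= W.T @ phi_rk

        delta = np.linalg.norm(Z_new - Z_corr) / (np.linalg.norm(Z_orig) + 1e-12)
        Z_corr = Z_new
        Z_cos = _cos(Z_corr)
        # converged when the round-to-round correction change is negligible or
        # has plateaued (soft assignments jitter at a small floor forever)
        if delta < tol or delta > 0.95 * prev_delta:
            converged = True
            break
        prev_delta = delta

    if not converged:
        warnings.warn(
            "batch integration did not converge within max_iter; returning best iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    return Z_corr.T
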