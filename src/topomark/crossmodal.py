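"""Regularized canonical correlation between tau and amyloid ROI matrices.

With n subjects not much larger than the number of regions per side,
textbook CCA is degenerate (the first canonical correlation is trivially
1).  The estimator here whitens each modality by its truncated SVD —
keeping at most ``whiten_rank`` components, optionally ridge-smoothing the
singular values — and takes the SVD of the whitened cross-covariance.
Canonical weight vectors are mapped back to ROI space, so each canonical
pair is a pair of interpretable spatial topographies whose projected
subject scores achieve the canonical correlation.

The sensible default for ``whiten_rank`` is the number of components each
modality's permutation rank test retains (the pipeline wires this up);
``fit_cca`` itself defaults to the full numerical rank.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import RoiMatrix, SchemaError


@dataclass
class CanonicalPair:
    """Canonical topography pairs between two PET modalities."""

    weights_tau: np.ndarray      # (k, m) ROI-space canonical weights
    weights_abeta: np.ndarray    # (k, m)
    correlations: np.ndarray     # canonical correlations, descending, in [0, 1]
    cov_explained: np.ndarray    # sigma_i^2 / sum sigma^2 over computed pairs
    n_pairs_retained: int
    regularization: dict         # whiten ranks and ridge actually used
    region_ids: tuple[str, ...]
    center_tau: np.ndarray
    center_abeta: np.ndarray
    subject_ids: tuple[str, ...]

    def summary(self) -> dict:
        return {"correlations": self.correlations,
                "cov_explained": self.cov_explained,
                "n_pairs_retained": self.n_pairs_retained,
                "regularization": self.regularization}


def _whiten(X: np.ndarray, rank_cap: int | None, ridge: float):
    """Truncated-SVD whitening. Returns (Z, map_to_roi, rank_used) where
    ``Z = Xc @ map_to_roi`` has (near-)identity covariance in the retained
    subspace and ``map_to_roi`` carries whitened coordinates to ROI space."""
    n, m = X.shape
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    tol = max(n, m) * np.finfo(float).eps * (S[0] if S.size else 0.0)
    r = int((S > tol).sum())
    if r == 0:
        raise ValueError("degenerate input: modality has zero variance")
    if rank_cap is not None:
        r = min(r, int(rank_cap))
    S_r = S[:r]
    inv = S_r / (S_r ** 2 + ridge) if ridge > 0 else 1.0 / S_r
    T = Vt[:r].T * inv[None, :]      # (m, r): ROI -> whitened coordinates
    Z = X @ T                        # == U_r with ridge=0
    return Z, T, r


def fit_cca(tau: RoiMatrix, abeta: RoiMatrix,
            whiten_rank: int | tuple[int, int] | None = None,
            ridge: float = 0.0) -> CanonicalPair:
    """Canonical correlation between two same-subject ROI matrices.

    ``whiten_rank`` caps the per-modality whitening rank (an int applies to
    both sides, a tuple sets (tau, abeta) separately); ``None`` keeps the
    full numerical rank, which is only sensible when n is comfortably
    larger than the region count.
    """
    if tau.subject_ids != abeta.subject_ids:
        raise SchemaError("tau and abeta matrices must share subjects "
                          "in the same order")
    if tau.region_ids != abeta.region_ids:
        raise SchemaError("tau and abeta matrices must share region labels")
    n = tau.n_subjects
    if n < 4:
        raise ValueError("CCA requires at least 4 subjects")
    if isinstance(whiten_rank, (tuple, list)):
        cap_tau, cap_ab = whiten_rank
    else:
        cap_tau = cap_ab = whiten_rank

    mu_t = tau.values.mean(axis=0)
    mu_a = abeta.values.mean(axis=0)
    for mat, mu in ((tau, mu_t), (abeta, mu_a)):
        scale = max(1.0, float(np.abs(mu).max()))
        if np.allclose(mat.values - mu, 0.0, atol=1e-10 * scale):
            raise ValueError(f"degenerate input: {mat.modality} matrix has "
                             "zero variance")
    Zt, Tt, r_t = _whiten(tau.values - mu_t, cap_tau, ridge)
    Za, Ta, r_a = _whiten(abeta.values - mu_a, cap_ab, ridge)

    M = Zt.T @ Za
    A, sigma, Bt = np.linalg.svd(M, full_matrices=False)
    k = min(r_t, r_a)
    A, sigma, B = A[:, :k], sigma[:k], Bt[:k].T
    rho = np.clip(sigma, 0.0, 1.0)
    total = float((sigma ** 2).sum())
    cov_explained = (sigma ** 2 / total if total > 0
                     else np.full(k, np.nan))

    W_t = (Tt @ A).T   # (k, m)
    W_a = (Ta @ B).T
    # orient each pair so the tau weight sum is >= 0; flip both sides
    # together so the projected correlation stays +rho
    for i in range(k):
        s = W_t[i].sum()
        flip = s < 0
        if s == 0:
            nz = np.flatnonzero(W_t[i])
            flip = bool(nz.size) and W_t[i][nz[0]] < 0
        if flip:
            W_t[i] = -W_t[i]
            W_a[i] = -W_a[i]

    return CanonicalPair(
        weights_tau=W_t, weights_abeta=W_a, correlations=rho,
        cov_explained=cov_explained, n_pairs_retained=k,
        regularization={"whiten_rank_tau": r_t, "whiten_rank_abeta": r_a,
                        "ridge": float(ridge)},
        region_ids=tau.region_ids, center_tau=mu_t, center_abeta=mu_a,
        subject_ids=tau.subject_ids)


def project_canonical(tau: RoiMatrix, abeta: RoiMatrix,
                      pair: CanonicalPair) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject canonical variates ``(variates_tau, variates_abeta)``,
    each n x k.  On the training data the sample correlation of pair 1's
    variates equals the first canonical correlation."""
    if tau.region_ids != pair.region_ids or abeta.region_ids != pair.region_ids:
        raise SchemaError("region labels/order do not match the canonical pair")
    vt = (tau.values - pair.center_tau) @ pair.weights_tau.T
    va = (abeta.values - pair.center_abeta) @ pair.weights_abeta.T
    return vt, va


def compare_weight_vectors(pair: CanonicalPair,
                           i: int = 0) -> tuple[float, float]:
    """Pearson r (and p) between the tau and amyloid ROI weight vectors of
    canonical pair ``i`` — low r with high canonical correlation is the
    signature of coupled pathologies in distinct spatial patterns."""
    if not (0 <= i < pair.n_pairs_retained):
        raise IndexError(f"pair index {i} out of range")
    res = stats.pearsonr(pair.weights_tau[i], pair.weights_abeta[i])
    return float(res.statistic), float(res.pvalue)
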