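"""SVD topography extraction and permutation-based rank estimation.

A subject x ROI SUVR matrix is decomposed by thin singular value
decomposition after column (region) mean-centering.  The right singular
vectors are spatial *topographies* — unit-norm weightings over regions —
and the projections of subjects onto them (``U S``, equivalently the
centered data times ``V^T``) quantify how strongly each subject expresses
each topography.

The number of statistically meaningful components is estimated by a
Horn-style permutation test: each column of the centered matrix is
independently shuffled across subjects (destroying inter-region
correlation, preserving marginals) and the k-th observed singular value is
compared against the permutation distribution of k-th singular values,
with sequential stopping at the first non-significant component.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import RoiMatrix, SchemaError


@dataclass
class TopographySet:
    """Result of decomposing one modality's subject x ROI matrix."""

    modality: str
    center: np.ndarray                   # per-region column means (m,)
    singular_values: np.ndarray          # descending, nonnegative (r,)
    weights: np.ndarray                  # (r, m) unit-norm rows (V^T)
    scores: np.ndarray                   # (n, r) = centered data @ weights.T
    region_ids: tuple[str, ...]
    subject_ids: tuple[str, ...]
    centered: bool = True
    rank_estimate: int | None = None
    perm_pvalues: np.ndarray | None = None
    n_permutations: int | None = None
    alpha: float | None = None

    @property
    def n_components(self) -> int:
        return len(self.singular_values)

    def summary(self) -> dict:
        return {
            "modality": self.modality,
            "singular_values": self.singular_values,
            "rank_estimate": self.rank_estimate,
            "perm_pvalues": self.perm_pvalues,
            "n_permutations": self.n_permutations,
            "alpha": self.alpha,
            "centered": self.centered,
            "center": self.center,
            "variance_explained": (self.singular_values ** 2
                                   / max(float((self.singular_values ** 2).sum()),
                                         np.finfo(float).tiny)),
        }


def _orient_rows(V: np.ndarray) -> np.ndarray:
    """Sign convention: each weight row oriented so its sum is >= 0; an
    exactly-zero sum falls back to making the first nonzero entry positive."""
    V = V.copy()
    for i, row in enumerate(V):
        s = row.sum()
        if s < 0:
            V[i] = -row
        elif s == 0:
            nz = np.flatnonzero(row)
            if nz.size and row[nz[0]] < 0:
                V[i] = -row
    return V


def decompose(matrix: RoiMatrix, center: bool = True) -> TopographySet:
    """Thin SVD of the (optionally column-centered) subject x ROI matrix.

    With ``center=False`` the raw matrix is decomposed, in which case the
    first topography typically tracks the regional mean image.
    """
    X = matrix.values
    n, m = X.shape
    if n < 3:
        raise ValueError("decompose requires at least 3 subjects")
    mu = X.mean(axis=0) if center else np.zeros(m)
    Xc = X - mu
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    V = _orient_rows(Vt)
    scores = Xc @ V.T
    return TopographySet(modality=matrix.modality, center=mu,
                         singular_values=S, weights=V, scores=scores,
                         region_ids=matrix.region_ids,
                         subject_ids=matrix.subject_ids, centered=center)


def _permuted_singular_values(Xc: np.ndarray, n_permutations: int,
                              rng: np.random.Generator,
                              k: int) -> np.ndarray:
    """(B, k) matrix of leading singular values of within-column-shuffled
    copies of the centered data."""
    out = np.empty((n_permutations, k))
    for b in range(n_permutations):
        Xp = rng.permuted(Xc, axis=0)  # each column shuffled independently
        out[b] = np.linalg.svd(Xp, compute_uv=False)[:k]
    return out


def estimate_rank(matrix: RoiMatrix, n_permutations: int = 1000,
                  alpha: float = 0.05, seed: int | None = None,
                  center: bool = True) -> tuple[int, np.ndarray]:
    """Permutation test for the number of significant components.

    Component k's p-value is the fraction of permutations whose k-th
    singular value is >= the observed k-th, with the +1/(B+1) correction.
    The rank estimate is the largest K such that components 1..K are all
    significant at ``alpha`` (sequential stopping at the first failure).

    Returns ``(rank_estimate, pvalues)`` where ``pvalues`` covers all thin
    components.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    X = matrix.values
    mu = X.mean(axis=0) if center else 0.0
    Xc = X - mu
    obs = np.linalg.svd(Xc, compute_uv=False)
    k = len(obs)
    rng = np.random.default_rng(seed)
    perm = _permuted_singular_values(Xc, n_permutations, rng, k)
    exceed = (perm >= obs[None, :]).sum(axis=0)
    pvalues = (1.0 + exceed) / (n_permutations + 1.0)
    rank = 0
    for p in pvalues:
        if p <= alpha:
            rank += 1
        else:
            break
    return rank, pvalues


def analyze(matrix: RoiMatrix, n_permutations: int = 1000,
            alpha: float = 0.05, seed: int | None = None,
            center: bool = True) -> TopographySet:
    """Decompose and attach the permutation rank estimate."""
    topo = decompose(matrix, center=center)
    rank, pvalues = estimate_rank(matrix, n_permutations=n_permutations,
                                  alpha=alpha, seed=seed, center=center)
    topo.rank_estimate = rank
    topo.perm_pvalues = pvalues
    topo.n_permutations = n_permutations
    topo.alpha = alpha
    return topo


def project(matrix: RoiMatrix, topo: TopographySet) -> np.ndarray:
    """Project (possibly new) subjects onto stored topographies.

    Scores are ``(values - topo.center) @ weights.T``; projecting the
    training matrix reproduces ``topo.scores``.
    """
    if matrix.region_ids != topo.region_ids:
        raise SchemaError("region labels/order do not match the topography set")
    return (matrix.values - topo.center) @ topo.weights.T


@dataclass
class LooStability:
    """Leave-one-out weight-vector stability for one component."""

    component: int
    correlations: np.ndarray  # |Pearson r| per held-out subject
    subject_ids: tuple[str, ...]

    @property
    def min(self) -> float:
        return float(self.correlations.min())

    @property
    def mean(self) -> float:
        return float(self.correlations.mean())


def loo_stability(matrix: RoiMatrix, component: int,
                  center: bool = True) -> LooStability:
    """Refit the decomposition with each subject held out and report the
    absolute Pearson correlation between refit and full-sample weight
    vectors for ``component`` (absolute value handles sign flips)."""
    n = matrix.n_subjects
    if n < 4:
        raise ValueError("leave-one-out requires at least 4 subjects")
    full = decompose(matrix, center=center)
    if not (0 <= component < full.n_components):
        raise IndexError(f"component {component} out of range")
    w_full = full.weights[component]
    corrs = np.empty(n)
    for i in range(n):
        keep = [s for j, s in enumerate(matrix.subject_ids) if j != i]
        refit = decompose(matrix.subset(keep), center=center)
        w_i = refit.weights[component]
        corrs[i] = abs(stats.pearsonr(w_i, w_full).statistic)
    return LooStability(component=component, correlations=corrs,
                        subject_ids=matrix.subject_ids)
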