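"""Synthetic dual-tracer cohort generator with planted ground truth.

Every downstream stage of the pipeline (topography extraction, staging,
canonical correlation, penalized prediction) is exercised against cohorts
generated here, because the generator knows the truth: the planted
low-rank ROI structure, the subject component scores, and the linear
couplings from pathology burden to CSF analytes and cognition.

The generative model per modality is

    X = baseline + sum_k  s_k * sv_k * w_k^T + E,     E_ij ~ N(0, noise_sd^2)

with unit-norm, mutually orthogonal planted topographies ``w_k`` (component
1 uniform-positive, the disease component temporal-lobe-weighted for tau
and frontoparietal for amyloid), standard-normal subject scores ``s_k``
shifted additively for clinically impaired (CDR>0) subjects, and tau/amyloid
scores of the same component correlated at ``cross_loading``.  CSF analytes
are linear in the disease-component scores (amyloid-beta 42 inversely, as
in vivo), and cognitive composites are driven predominantly by temporal-tau
burden; the working-memory composite is left uncoupled by default.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (COMPOSITE_DOMAINS, RoiMatrix, RoiRegistry,
                      load_registry)

#: name -> spawn index of the per-table RNG streams; adding a stream at the
#: end never perturbs existing tables for a fixed global seed.
_STREAMS = {"scores": 0, "noise_tau": 1, "noise_abeta": 2,
            "demographics": 3, "csf": 4, "cognition": 5, "subsets": 6}

_SUVR_FLOOR = 0.05  # SUVR is a positive ratio; rare deep noise dips are floored


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[name],)))


@dataclass
class SyntheticConfig:
    """All generator parameters; defaults mirror the study conditions."""

    n_subjects: int = 46
    n_regions: int = 42
    rank: int = 2
    #: modality -> (rank x n_regions); None builds lobe-based defaults
    component_weights: Mapping[str, np.ndarray] | None = None
    singular_values: tuple[float, ...] = (1.0, 0.6)
    noise_sd: float = 0.1
    baseline_suvr: float | np.ndarray = 1.2
    cdr_effect: float = 2.0
    n_impaired: int = 10
    cross_loading: float = 0.9
    #: analyte -> (intercept, slope on disease-component score, noise sd), pg/mL
    csf_coupling: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"tau": (300.0, 80.0, 60.0),
                                 "ptau": (55.0, 15.0, 12.0),
                                 "abeta42": (650.0, -110.0, 90.0)})
    #: domain -> (tau slope, abeta slope, noise sd) on Z-score scale;
    #: working memory is uncoupled (pure noise) by default
    cognition_coupling: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "episodic": (0.8, 0.1, 0.6), "semantic": (0.8, 0.1, 0.6),
            "working": (0.0, 0.0, 0.6), "visuospatial": (0.8, 0.1, 0.6),
            "global": (0.8, 0.1, 0.6)})
    n_csf: int = 36
    n_neuropsych: int = 40
    seed: int = 0
    registry: RoiRegistry | None = None

    def validate(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.n_impaired <= self.n_subjects):
            raise ValueError("n_impaired must be in [0, n_subjects]")
        if len(self.singular_values) < self.rank:
            raise ValueError("need one singular value per planted component")
        if not (-1.0 <= self.cross_loading <= 1.0):
            raise ValueError("cross_loading must be a correlation in [-1, 1]")
        if not (0 <= self.n_csf <= self.n_subjects):
            raise ValueError("n_csf must be in [0, n_subjects]")
        if not (0 <= self.n_neuropsych <= self.n_subjects):
            raise ValueError("n_neuropsych must be in [0, n_subjects]")


@dataclass
class SimulatedCohort:
    tau: RoiMatrix
    abeta: RoiMatrix
    cohort: pd.DataFrame
    csf: pd.DataFrame
    composites: pd.DataFrame
    ground_truth: dict


def _default_weights(registry: RoiRegistry, rank: int,
                     n_regions: int) -> dict[str, np.ndarray]:
    """Planted topographies: uniform first component; disease component
    temporal for tau, frontoparietal for amyloid; extra components random-free
    (indicator on successive lobes) — all orthonormalized per modality."""
    m = n_regions
    if len(registry) != m:
        raise ValueError(f"registry has {len(registry)} regions, config asks "
                         f"for {m}")
    lobes = np.array([registry.lobe_map[r] for r in registry.region_ids])
    uniform = np.ones(m)

    def indicator(tags: Sequence[str]) -> np.ndarray:
        v = np.isin(lobes, tags).astype(float)
        if v.sum() == 0:  # registry without those tags: fall back to a block
            v = np.zeros(m)
            v[: max(2, m // 4)] = 1.0
        return v

    per_modality = {"tau": indicator(["temporal"]),
                    "abeta": indicator(["frontal", "parietal"])}
    out = {}
    for modality, disease in per_modality.items():
        raw = [uniform, disease]
        # deterministic fillers for rank > 2: alternating-sign patterns
        k = 2
        while len(raw) < rank:
            filler = np.cos(np.pi * k * np.arange(m) / m)
            raw.append(filler)
            k += 1
        W = _gram_schmidt(np.array(raw[:rank]))
        out[modality] = W
    return out


def _gram_schmidt(W: np.ndarray) -> np.ndarray:
    """Row-wise orthonormalization preserving the leading directions."""
    Q = np.zeros_like(W, dtype=float)
    for i, w in enumerate(W):
        v = w.astype(float).copy()
        for j in range(i):
            v -= (Q[j] @ v) * Q[j]
        nrm = np.linalg.norm(v)
        if nrm < 1e-12:
            raise ValueError(f"planted component {i} is degenerate after "
                             "orthogonalization")
        Q[i] = v / nrm
    return Q


def _subject_ids(n: int) -> tuple[str, ...]:
    return tuple(f"sub-{i + 1:03d}" for i in range(n))


def simulate_cohort(config: SyntheticConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort; identical seed -> identical output."""
    config.validate()
    registry = config.registry or load_registry()
    n, m, rank = config.n_subjects, config.n_regions, config.rank
    if config.component_weights is None:
        weights = _default_weights(registry, rank, m)
    else:
        weights = {mod: _check_weights(np.asarray(W, dtype=float), rank, m)
                   for mod, W in config.component_weights.items()}
        for mod in ("tau", "abeta"):
            if mod not in weights:
                raise ValueError(f"component_weights missing modality {mod!r}")
    sv = np.asarray(config.singular_values[:rank], dtype=float)
    subjects = _subject_ids(n)
    impaired = np.zeros(n, dtype=bool)
    if config.n_impaired:
        impaired[-config.n_impaired:] = True

    # component scores: per component, (tau, abeta) bivariate normal with
    # correlation cross_loading; impaired subjects shifted by cdr_effect
    rng = _stream(config.seed, "scores")
    rho = config.cross_loading
    scores = {"tau": np.empty((n, rank)), "abeta": np.empty((n, rank))}
    for k in range(rank):
        z = rng.standard_normal((n, 2))
        s_tau = z[:, 0]
        s_ab = rho * z[:, 0] + np.sqrt(max(0.0, 1 - rho ** 2)) * z[:, 1]
        scores["tau"][:, k] = s_tau + config.cdr_effect * impaired
        scores["abeta"][:, k] = s_ab + config.cdr_effect * impaired

    baseline = np.broadcast_to(
        np.asarray(config.baseline_suvr, dtype=float), (m,))
    mats = {}
    for modality in ("tau", "abeta"):
        noise = _stream(config.seed, f"noise_{modality}")
        X = (baseline[None, :]
             + scores[modality] @ (sv[:, None] * weights[modality])
             + (noise.standard_normal((n, m)) * config.noise_sd))
        np.maximum(X, _SUVR_FLOOR, out=X)
        mats[modality] = RoiMatrix(subject_ids=subjects, modality=modality,
                                   values=X, region_ids=registry.region_ids,
                                   pvc=True)

    # demographics: ages ~ N(75.4, 6.6), sex and APOE4 at study frequencies,
    # impaired split ~70/30 between CDR 0.5 and 1+
    demo = _stream(config.seed, "demographics")
    age = np.clip(demo.normal(75.4, 6.6, size=n), 55.0, 95.0)
    sex = np.where(demo.random(n) < 30 / 46, "M", "F")
    apoe4 = demo.random(n) < 20 / 46
    cdr = np.full(n, "0", dtype=object)
    n_mild = int(round(0.7 * config.n_impaired))
    imp_idx = np.flatnonzero(impaired)
    cdr[imp_idx[:n_mild]] = "0.5"
    cdr[imp_idx[n_mild:]] = "1+"
    cohort = pd.DataFrame({"age": age, "sex": sex, "cdr": cdr,
                           "apoe4": apoe4},
                          index=pd.Index(subjects, name="subject_id"))

    disease_k = min(1, rank - 1)  # component 2 when planted, else component 1
    tau_burden = scores["tau"][:, disease_k]
    ab_burden = scores["abeta"][:, disease_k]

    csf_rng = _stream(config.seed, "csf")
    csf_full = {}
    for analyte, (intercept, slope, noise_sd) in config.csf_coupling.items():
        burden = ab_burden if analyte == "abeta42" else tau_burden
        vals = intercept + slope * burden + csf_rng.normal(0, noise_sd, n)
        csf_full[analyte] = np.maximum(vals, 5.0)  # analytes are positive pg/mL
    csf_df = pd.DataFrame(csf_full, index=pd.Index(subjects, name="subject_id"))

    cog_rng = _stream(config.seed, "cognition")
    comp_full = {}
    for domain in COMPOSITE_DOMAINS:
        c_tau, c_ab, noise_sd = config.cognition_coupling[domain]
        comp_full[domain] = (-c_tau * tau_burden - c_ab * ab_burden
                             + cog_rng.normal(0, noise_sd, n))
    comp_df = pd.DataFrame(comp_full,
                           index=pd.Index(subjects, name="subject_id"))

    sub_rng = _stream(config.seed, "subsets")
    csf_subset = sorted(sub_rng.choice(n, size=config.n_csf, replace=False))
    np_subset = sorted(sub_rng.choice(n, size=config.n_neuropsych,
                                      replace=False))
    csf_df = csf_df.iloc[csf_subset]
    comp_df = comp_df.iloc[np_subset]

    ground_truth = {
        "weights": {mod: weights[mod] for mod in ("tau", "abeta")},
        "singular_values": sv,
        "scores": scores,
        "impaired_subjects": [subjects[i] for i in imp_idx],
        "disease_component": disease_k,
        "csf_coupling": dict(config.csf_coupling),
        "cognition_coupling": dict(config.cognition_coupling),
        "seed": config.seed,
    }
    return SimulatedCohort(tau=mats["tau"], abeta=mats["abeta"],
                           cohort=cohort, csf=csf_df, composites=comp_df,
                           ground_truth=ground_truth)


def _check_weights(W: np.ndarray, rank: int, m: int) -> np.ndarray:
    if W.shape != (rank, m):
        raise ValueError(f"component_weights must be {rank} x {m}, "
                         f"got {W.shape}")
    norms = np.linalg.norm(W, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-8):
        raise ValueError("planted topographies must have unit norm per "
                         f"component (norms {norms})")
    return W


def simulate_null_matrix(n: int, m: int, noise_sd: float, seed: int,
                         baseline_suvr: float = 1.2,
                         modality: str = "tau",
                         registry: RoiRegistry | None = None) -> RoiMatrix:
    """Pure-noise subject x ROI matrix: i.i.d. Gaussian around the baseline,
    no planted structure.  Serves as the null for the permutation rank test.
    """
    if n < 2 or m < 2:
        raise ValueError("need n, m >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if registry is not None and len(registry) != m:
        raise ValueError("registry size does not match m")
    rng = np.random.default_rng(seed)
    X = baseline_suvr + rng.standard_normal((n, m)) * noise_sd
    np.maximum(X, _SUVR_FLOOR, out=X)
    region_ids = (registry.region_ids if registry is not None
                  else tuple(f"roi_{j + 1:02d}" for j in range(m)))
    return RoiMatrix(subject_ids=_subject_ids(n), modality=modality,
                     values=X, region_ids=region_ids)
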