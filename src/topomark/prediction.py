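"""Joint penalized regression of CSF/cognition outcomes on regional PET.

A single elastic-net model regresses one outcome (a CSF analyte or a
neuropsychological composite) on the *concatenated* tau + amyloid ROI
predictors, letting the data decide which modality, and which regions,
carry the predictive weight.  The objective is

    (1 / 2n) * ||y - X b||^2  +  lambda * [ mix * ||b||_1
                                            + (1 - mix) / 2 * ||b||_2^2 ]

with the total penalty ``lambda`` and the L1/L2 mixing weight ``mix``
chosen by K-fold cross-validation.  Predictors are z-scored over the
analysis subset so coefficient magnitudes are comparable across regions
and modalities; the modality-attribution statistic is the within-block sum
of absolute standardized coefficients, Sum|beta_tau| vs Sum|beta_abeta|.

Significance of the fit is assessed by a permutation null: the outcome
vector is permuted B times and the *entire* protocol — including the
cross-validated hyperparameter search — is rerun each time, yielding the
null distribution of R-squared and hence a Z score and an empirical
p-value with the +1/(B+1) correction.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .core_io import RoiMatrix, SchemaError

DEFAULT_MIX_GRID = (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)


@dataclass
class Design:
    """Standardized joint predictor matrix with (modality, region) labels."""

    X: np.ndarray                       # (n, 2m) z-scored columns
    raw: np.ndarray                     # (n, 2m) original values
    columns: tuple[tuple[str, str], ...]
    subject_ids: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    zero_variance: tuple[int, ...]      # flagged column indices (X set to 0)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def subset(self, subject_ids: Sequence[str]) -> "Design":
        """Row-subset and re-standardize over the new analysis subset."""
        index = {s: i for i, s in enumerate(self.subject_ids)}
        try:
            rows = [index[s] for s in subject_ids]
        except KeyError as exc:
            raise SchemaError(f"unknown subject ID {exc.args[0]!r}") from exc
        return _standardize(self.raw[rows], self.columns, tuple(subject_ids))


def _standardize(raw: np.ndarray, columns, subject_ids) -> Design:
    mu = raw.mean(axis=0)
    sd = raw.std(axis=0)
    # constant columns up to float rounding of the mean
    zero = tuple(int(j) for j in np.flatnonzero(
        sd <= 1e-12 * np.maximum(1.0, np.abs(mu))))
    sd = np.where(np.isin(np.arange(raw.shape[1]), zero), 0.0, sd)
    sd_safe = np.where(sd == 0, 1.0, sd)
    X = (raw - mu) / sd_safe
    if zero:
        X[:, list(zero)] = 0.0  # constant columns carry no information
    return Design(X=X, raw=raw, columns=columns, subject_ids=subject_ids,
                  mean=mu, sd=sd, zero_variance=zero)


def build_design(tau: RoiMatrix, abeta: RoiMatrix) -> Design:
    """Concatenate tau then amyloid ROI columns (registry order) and z-score.

    Zero-variance columns are kept and flagged; their coefficients are
    constrained to zero by zeroing the standardized column.
    """
    if tau.subject_ids != abeta.subject_ids:
        raise SchemaError("tau and abeta matrices must share subjects in "
                          "the same order")
    raw = np.hstack([tau.values, abeta.values])
    columns = tuple([("tau", r) for r in tau.region_ids]
                    + [("abeta", r) for r in abeta.region_ids])
    return _standardize(raw, columns, tau.subject_ids)


@dataclass
class EnetProtocol:
    """Hyperparameter search protocol for one elastic-net fit."""

    cv_folds: int = 5
    mix_grid: tuple[float, ...] = DEFAULT_MIX_GRID
    n_lambdas: int = 50
    lambda_min_ratio: float = 1e-4
    lambdas: tuple[float, ...] | None = None  # explicit grid overrides path
    max_iter: int = 50_000
    tol: float = 1e-7
    #: "1se" picks the sparsest (largest-lambda) model within one standard
    #: error of the CV minimum — this keeps the permutation null of the
    #: in-sample R^2 well behaved when predictors outnumber subjects;
    #: "min" takes the raw CV-MSE minimizer.
    selection: str = "1se"


@dataclass
class PenalizedFit:
    """One fitted elastic-net model plus (optional) permutation inference."""

    outcome: str
    beta: np.ndarray            # standardized-scale coefficients (2m,)
    beta_raw: np.ndarray        # back-transformed to raw predictor scale
    intercept: float
    lambda_: float
    mix: float
    r2: float
    columns: tuple[tuple[str, str], ...]
    zero_variance: tuple[int, ...]
    n_subjects: int
    perm_null_mean: float | None = None
    perm_null_sd: float | None = None
    z: float | None = None
    p_perm: float | None = None
    n_permutations: int | None = None
    perm_draws: np.ndarray | None = None

    def summary(self) -> dict:
        att = modality_attribution(self)
        return {"outcome": self.outcome, "r2": self.r2,
                "lambda": self.lambda_, "mix": self.mix,
                "intercept": self.intercept, "z": self.z,
                "p_perm": self.p_perm,
                "perm_null_mean": self.perm_null_mean,
                "perm_null_sd": self.perm_null_sd,
                "n_permutations": self.n_permutations,
                "n_subjects": self.n_subjects, "attribution": att}


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """In-sample squared Pearson correlation between fitted and observed."""
    if np.ptp(yhat) == 0 or np.ptp(y) == 0:
        return 0.0
    r = np.corrcoef(y, yhat)[0, 1]
    return float(r * r)


def _fit_once(X: np.ndarray, y: np.ndarray, protocol: EnetProtocol,
              seed: int) -> tuple[np.ndarray, float, float, float]:
    """Run the CV protocol, refit at the selected hyperparameters on all
    data, and return (beta, intercept, lambda, mix)."""
    single = (protocol.lambdas is not None and len(protocol.lambdas) == 1
              and len(protocol.mix_grid) == 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        if single:
            lam, mix = float(protocol.lambdas[0]), float(protocol.mix_grid[0])
            model = ElasticNet(alpha=lam, l1_ratio=mix,
                               max_iter=protocol.max_iter, tol=protocol.tol)
            model.fit(X, y)
            return model.coef_.copy(), float(model.intercept_), lam, mix
        cv = KFold(n_splits=protocol.cv_folds, shuffle=True,
                   random_state=int(seed) % (2 ** 31))
        kwargs = dict(l1_ratio=list(protocol.mix_grid), cv=cv,
                      max_iter=protocol.max_iter, tol=protocol.tol)
        if protocol.lambdas is not None:
            kwargs["alphas"] = list(protocol.lambdas)
        else:
            kwargs["alphas"] = protocol.n_lambdas
            kwargs["eps"] = protocol.lambda_min_ratio
        model = ElasticNetCV(**kwargs)
        model.fit(X, y)
        if protocol.selection == "min":
            return (model.coef_.copy(), float(model.intercept_),
                    float(model.alpha_), float(model.l1_ratio_))
        lam, mix = _one_se_choice(model, protocol)
        refit = ElasticNet(alpha=lam, l1_ratio=mix,
                           max_iter=protocol.max_iter, tol=protocol.tol)
        refit.fit(X, y)
        return refit.coef_.copy(), float(refit.intercept_), lam, mix


def _one_se_choice(model: ElasticNetCV,
                   protocol: EnetProtocol) -> tuple[float, float]:
    """Largest lambda whose mean CV-MSE is within one standard error of the
    minimum; sparser mixes win ties."""
    if protocol.selection != "1se":
        raise ValueError("selection must be 'min' or '1se'")
    mixes = np.atleast_1d(protocol.mix_grid).astype(float)
    mse = model.mse_path_  # (n_mix, n_alphas, n_folds) or (n_alphas, n_folds)
    alphas = model.alphas_
    if mse.ndim == 2:
        mse = mse[None, ...]
        alphas = np.asarray(alphas)[None, ...]
    mean = mse.mean(axis=-1)
    se = mse.std(axis=-1, ddof=1) / np.sqrt(mse.shape[-1])
    i_best, j_best = np.unravel_index(np.argmin(mean), mean.shape)
    threshold = mean[i_best, j_best] + se[i_best, j_best]
    best = (float(model.alpha_), float(model.l1_ratio_))
    best_alpha = -np.inf
    for i in range(mean.shape[0]):
        ok = np.flatnonzero(mean[i] <= threshold)
        if ok.size:
            j = ok[np.argmax(alphas[i][ok])]
            cand_alpha = float(alphas[i][j])
            if (cand_alpha > best_alpha
                    or (cand_alpha == best_alpha and mixes[i] > best[1])):
                best_alpha = cand_alpha
                best = (cand_alpha, float(mixes[i]))
    return best


def fit_enet(design: Design, outcome: np.ndarray | pd.Series,
             protocol: EnetProtocol | None = None, seed: int = 0,
             outcome_name: str = "outcome") -> PenalizedFit:
    """Cross-validated elastic-net fit of one outcome on the joint design."""
    protocol = protocol or EnetProtocol()
    if isinstance(outcome, pd.Series):
        outcome_name = str(outcome.name) if outcome.name is not None else outcome_name
        outcome = outcome.to_numpy()
    y = np.asarray(outcome, dtype=float)
    if y.shape != (design.n,):
        raise SchemaError(f"outcome length {y.shape} does not match design "
                          f"n={design.n}")
    if not np.all(np.isfinite(y)):
        raise ValueError("outcome contains non-finite values")
    if design.n < protocol.cv_folds or protocol.cv_folds < 3:
        raise ValueError("need n >= cv_folds >= 3")
    beta, intercept, lam, mix = _fit_once(design.X, y, protocol, seed)
    if design.zero_variance:
        beta[list(design.zero_variance)] = 0.0
    yhat = design.X @ beta + intercept
    sd_safe = np.where(design.sd == 0, 1.0, design.sd)
    beta_raw = beta / sd_safe
    return PenalizedFit(outcome=outcome_name, beta=beta, beta_raw=beta_raw,
                        intercept=intercept, lambda_=lam, mix=mix,
                        r2=_r_squared(y, yhat), columns=design.columns,
                        zero_variance=design.zero_variance,
                        n_subjects=design.n)


def permutation_significance(design: Design, outcome: np.ndarray | pd.Series,
                             protocol: EnetProtocol | None = None,
                             n_permutations: int = 1000, seed: int = 0,
                             fit: PenalizedFit | None = None) -> PenalizedFit:
    """Permutation null for R-squared; returns the fit with inference fields.

    Each of the ``n_permutations`` draws permutes the outcome vector and
    reruns the full protocol (cross-validation included), so the null
    honestly reflects the selection procedure.
    """
    protocol = protocol or EnetProtocol()
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    if isinstance(outcome, pd.Series):
        outcome = outcome.to_numpy()
    y = np.asarray(outcome, dtype=float)
    if fit is None:
        fit = fit_enet(design, y, protocol, seed=seed)
    rng = np.random.default_rng(seed)
    draws = np.empty(n_permutations)
    for b in range(n_permutations):
        y_perm = rng.permutation(y)
        fold_seed = int(rng.integers(2 ** 31))
        beta, intercept, _, _ = _fit_once(design.X, y_perm, protocol,
                                          fold_seed)
        if design.zero_variance:
            beta[list(design.zero_variance)] = 0.0
        draws[b] = _r_squared(y_perm, design.X @ beta + intercept)
    null_mean = float(draws.mean())
    null_sd = float(draws.std(ddof=1))
    z = (fit.r2 - null_mean) / null_sd if null_sd > 0 else float("nan")
    p = float((1 + (draws >= fit.r2).sum()) / (n_permutations + 1))
    return replace(fit, perm_null_mean=null_mean, perm_null_sd=null_sd,
                   z=float(z), p_perm=p, n_permutations=n_permutations,
                   perm_draws=draws)


def modality_attribution(fit: PenalizedFit) -> dict:
    """Block sums of |beta| per modality on the standardized scale.

    ``tau_share`` is Sum|beta_tau| / (Sum|beta_tau| + Sum|beta_abeta|),
    None when all coefficients are zero.
    """
    mods = np.array([c[0] for c in fit.columns])
    absb = np.abs(fit.beta)
    s_tau = float(absb[mods == "tau"].sum())
    s_ab = float(absb[mods == "abeta"].sum())
    total = s_tau + s_ab
    return {"sum_abs_beta_tau": s_tau, "sum_abs_beta_abeta": s_ab,
            "tau_share": (s_tau / total) if total > 0 else None,
            "n_nonzero_tau": int((absb[mods == "tau"] > 0).sum()),
            "n_nonzero_abeta": int((absb[mods == "abeta"] > 0).sum())}


def compare_topography_fits(fit_a: PenalizedFit,
                            fit_b: PenalizedFit) -> tuple[float | None,
                                                          float | None]:
    """Pearson r (and p) between two fits' full coefficient vectors."""
    if fit_a.columns != fit_b.columns:
        raise SchemaError("fits have different predictor columns")
    a, b = fit_a.beta, fit_b.beta
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None, None
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass
class BatteryResult:
    """Per-outcome fits with family-wise corrected significance flags."""

    fits: dict[str, PenalizedFit]
    p_adjusted: dict[str, float]
    significant: dict[str, bool]
    correction: str
    alpha: float


def run_outcome_battery(design: Design, outcomes: pd.DataFrame,
                        protocol: EnetProtocol | None = None,
                        n_permutations: int = 1000, seed: int = 0,
                        correction: str = "holm",
                        alpha: float = 0.05) -> BatteryResult:
    """Fit each outcome column independently and correct across the family.

    Outcomes are indexed by subject ID; each is fit on the subjects it
    covers (design rows are subset and re-standardized per outcome).
    ``correction`` is any statsmodels ``multipletests`` method (default
    Holm; "bonferroni" available).
    """
    if outcomes.shape[1] < 1:
        raise ValueError("need at least one outcome column")
    protocol = protocol or EnetProtocol()
    fits: dict[str, PenalizedFit] = {}
    for i, name in enumerate(outcomes.columns):
        col = outcomes[str(name)].dropna()
        common = sorted(set(col.index) & set(design.subject_ids))
        if len(common) < protocol.cv_folds:
            raise ValueError(f"outcome {name!r} covers too few subjects")
        sub = design.subset(common)
        sub_seed = int(np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed),
                                   spawn_key=(i,))).integers(2 ** 31))
        fits[str(name)] = permutation_significance(
            sub, col.loc[common], protocol,
            n_permutations=n_permutations, seed=sub_seed)
    names = list(fits)
    pvals = [fits[n].p_perm for n in names]
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method=correction)
    return BatteryResult(
        fits=fits,
        p_adjusted={n: float(p) for n, p in zip(names, p_adj)},
        significant={n: bool(r) for n, r in zip(names, reject)},
        correction=correction, alpha=alpha)
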