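"""End-to-end pipeline: simulate/load -> topographies -> staging -> CCA ->
penalized prediction, aggregated into one machine-readable report.

A single global seed fans out to named per-stage substreams, so toggling
one stage never perturbs another stage's randomness, and an identical
config + seed yields a byte-identical JSON report.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import crossmodal, group_inference, prediction, synthetic, topography
from .core_io import (AlignedCohort, RoiRegistry, align_cohort, load_registry,
                      read_cohort, read_composites, read_csf, read_roi_matrix,
                      write_json, write_results)

log = logging.getLogger("topomark")

_STAGE_STREAMS = {"rank_tau": 0, "rank_abeta": 1, "predict": 2}


def _stage_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(entropy=int(seed),
                                spawn_key=(100 + _STAGE_STREAMS[stage],))
    return int(np.random.default_rng(ss).integers(2 ** 31))


@dataclass
class RunConfig:
    """Everything one pipeline run needs; serializable to/from YAML."""

    # either a synthetic generator config ...
    synthetic: synthetic.SyntheticConfig | None = None
    # ... or paths to the five input tables
    tau_path: str | None = None
    abeta_path: str | None = None
    cohort_path: str | None = None
    csf_path: str | None = None
    composites_path: str | None = None
    registry_path: str | None = None

    n_permutations_rank: int = 1000
    alpha: float = 0.05
    center: bool = True
    whiten_rank: str | int = "auto"   # "auto": use permutation rank estimates
    ridge: float = 0.0
    cv_folds: int = 5
    mix_grid: tuple[float, ...] = prediction.DEFAULT_MIX_GRID
    n_lambdas: int = 50
    lambda_min_ratio: float = 1e-4
    enet_max_iter: int = 5000
    enet_tol: float = 1e-5
    n_permutations_r2: int = 1000
    correction: str = "holm"
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if self.synthetic is None:
            needed = {"tau_path": self.tau_path, "abeta_path": self.abeta_path,
                      "cohort_path": self.cohort_path}
            missing = [k for k, v in needed.items() if v is None]
            if missing:
                raise ValueError(
                    f"config needs a synthetic block or input paths; missing "
                    f"{missing}")
            for name, p in {**needed, "csf_path": self.csf_path,
                            "composites_path": self.composites_path}.items():
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p} does not exist")


def _load_inputs(config: RunConfig) -> tuple[AlignedCohort, RoiRegistry,
                                             dict | None]:
    registry = load_registry(config.registry_path)
    if config.synthetic is not None:
        sim = synthetic.simulate_cohort(config.synthetic)
        aligned = align_cohort([sim.tau, sim.abeta], sim.cohort, sim.csf,
                               sim.composites)
        return aligned, registry, sim.ground_truth
    tau = read_roi_matrix(config.tau_path, registry, "tau")
    abeta = read_roi_matrix(config.abeta_path, registry, "abeta")
    cohort = read_cohort(config.cohort_path)
    csf = read_csf(config.csf_path) if config.csf_path else None
    comps = (read_composites(config.composites_path)
             if config.composites_path else None)
    return align_cohort([tau, abeta], cohort, csf, comps), registry, None


def summarize_topography_table(topo: topography.TopographySet,
                               registry: RoiRegistry,
                               k: int) -> pd.DataFrame:
    """Ranked |weight| listing of component ``k`` (0-based) with lobe tags
    and the per-lobe share of total absolute weight."""
    if not (0 <= k < topo.n_components):
        raise IndexError(f"component {k} out of range "
                         f"(0..{topo.n_components - 1})")
    w = topo.weights[k]
    df = pd.DataFrame({
        "region": list(topo.region_ids),
        "lobe": [registry.lobe_map[r] for r in topo.region_ids],
        "weight": w,
        "abs_weight": np.abs(w),
    }).sort_values("abs_weight", ascending=False, kind="mergesort")
    total = df["abs_weight"].sum()
    share = (df.groupby("lobe")["abs_weight"].sum() / total if total > 0
             else df.groupby("lobe")["abs_weight"].sum())
    df["lobe_share"] = df["lobe"].map(share)
    return df.reset_index(drop=True)


def lobe_weight_shares(topo: topography.TopographySet, registry: RoiRegistry,
                       k: int) -> dict[str, float]:
    tab = summarize_topography_table(topo, registry, k)
    return tab.groupby("lobe")["lobe_share"].first().to_dict()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage on the aligned cohort and return the report.

    When ``config.out_dir`` is set, per-stage artifacts (weight/score
    tables, beta tables) and the report JSON are also written there.
    """
    config.validate()
    t0 = time.perf_counter()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    aligned, registry, _truth = _load_inputs(config)
    log.info("aligned cohort: %s", aligned.subset_sizes)

    report: dict[str, Any] = {
        "seed": config.seed,
        "subset_sizes": aligned.subset_sizes,
        "parameters": {
            "n_permutations_rank": config.n_permutations_rank,
            "alpha": config.alpha, "center": config.center,
            "whiten_rank": config.whiten_rank, "ridge": config.ridge,
            "cv_folds": config.cv_folds,
            "n_permutations_r2": config.n_permutations_r2,
            "correction": config.correction,
        },
        "warnings": [],
    }

    # --- per-modality topographies with permutation rank ---
    topos: dict[str, topography.TopographySet] = {}
    for modality in ("tau", "abeta"):
        topo = topography.analyze(
            aligned.matrices[modality],
            n_permutations=config.n_permutations_rank, alpha=config.alpha,
            seed=_stage_seed(config.seed, f"rank_{modality}"),
            center=config.center)
        topos[modality] = topo
        log.info("%s: rank=%d, top singular values %s", modality,
                 topo.rank_estimate, np.round(topo.singular_values[:3], 3))
        if out_dir:
            write_results(topo, out_dir / f"topography_{modality}")
    report["topography"] = {
        mod: {"rank_estimate": t.rank_estimate,
              "singular_values": t.singular_values,
              "perm_pvalues": t.perm_pvalues[: max(t.rank_estimate + 1, 3)],
              "lobe_shares": {f"component_{k + 1}":
                              lobe_weight_shares(t, registry, k)
                              for k in range(max(t.rank_estimate, 1))}}
        for mod, t in topos.items()}

    # --- ANCOVA of retained component scores on age/CDR/APOE4 ---
    ancova: dict[str, Any] = {}
    for mod, topo in topos.items():
        n_keep = max(topo.rank_estimate or 0, 1)
        scores = pd.DataFrame(
            topo.scores[:, :n_keep], index=list(topo.subject_ids),
            columns=[f"component_{k + 1}" for k in range(n_keep)])
        res = group_inference.ancova_scores(scores, aligned.cohort)
        ancova[mod] = [r.factors | {"component": r.component} for r in res]
    report["ancova"] = ancova

    # --- CSF analyses ---
    if aligned.csf is not None and len(aligned.csf) >= 4:
        staging = group_inference.stage_preclinical(aligned.csf,
                                                    aligned.cohort)
        report["staging"] = {
            "counts": staging.counts(),
            "median_abeta42": staging.median_abeta42,
            "median_tau": staging.median_tau,
            "n_skipped": staging.n_skipped,
            "labels": {lab.subject_id: lab.stage for lab in staging.labels},
        }
        corr = group_inference.mean_suvr_csf_correlations(
            aligned.tau, aligned.abeta, aligned.csf, registry)
        report["mean_suvr_csf_correlations"] = {
            mod: {analyte: {"r": corr.loc[mod, (analyte, "r")],
                            "p": corr.loc[mod, (analyte, "p")]}
                  for analyte in ("tau", "ptau", "abeta42")}
            for mod in corr.index}

    # --- canonical correlation with rank-informed whitening ---
    if config.whiten_rank == "auto":
        wr = (max(topos["tau"].rank_estimate or 1, 1),
              max(topos["abeta"].rank_estimate or 1, 1))
    else:
        wr = int(config.whiten_rank)
    pair = crossmodal.fit_cca(aligned.tau, aligned.abeta, whiten_rank=wr,
                              ridge=config.ridge)
    w_r, w_p = crossmodal.compare_weight_vectors(pair, 0)
    report["cca"] = pair.summary() | {"weight_vector_r": w_r,
                                      "weight_vector_p": w_p}
    if out_dir:
        write_results(pair, out_dir / "cca")

    # --- penalized prediction battery ---
    design = prediction.build_design(aligned.tau, aligned.abeta)
    protocol = prediction.EnetProtocol(
        cv_folds=config.cv_folds, mix_grid=tuple(config.mix_grid),
        n_lambdas=config.n_lambdas,
        lambda_min_ratio=config.lambda_min_ratio,
        max_iter=config.enet_max_iter, tol=config.enet_tol)
    outcome_tables = []
    if aligned.csf is not None:
        outcome_tables.append(
            aligned.csf.rename(columns=lambda c: f"csf_{c}"))
    if aligned.composites is not None:
        outcome_tables.append(
            aligned.composites.rename(columns=lambda c: f"np_{c}"))
    if outcome_tables:
        outcomes = pd.concat(outcome_tables, axis=1)
        battery = prediction.run_outcome_battery(
            design, outcomes, protocol,
            n_permutations=config.n_permutations_r2,
            seed=_stage_seed(config.seed, "predict"),
            correction=config.correction, alpha=config.alpha)
        report["prediction"] = {
            name: fit.summary() | {
                "p_adjusted": battery.p_adjusted[name],
                "significant": battery.significant[name]}
            for name, fit in battery.fits.items()}
        if out_dir:
            for name, fit in battery.fits.items():
                write_results(fit, out_dir / f"fit_{name}")

    # timing goes to the log only, so reports stay byte-identical per seed
    log.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    if out_dir:
        write_json(report, out_dir / "report.json")
        (out_dir / "summary.txt").write_text(render_summary(report))
    return report


def render_summary(report: Mapping[str, Any]) -> str:
    """Short human-readable digest of a report bundle."""
    lines = [f"topomark report (seed {report['seed']})",
             f"cohort sizes: {report['subset_sizes']}"]
    for mod, t in report.get("topography", {}).items():
        lines.append(f"{mod}: rank estimate {t['rank_estimate']}")
    if "staging" in report:
        lines.append(f"preclinical staging counts: {report['staging']['counts']}")
    if "cca" in report:
        rho = report["cca"]["correlations"]
        rho1 = rho[0] if len(rho) else float("nan")
        cov1 = report["cca"]["cov_explained"][0] if len(rho) else float("nan")
        lines.append(f"canonical correlation rho1={float(rho1):.3f} "
                     f"(cov explained {float(cov1):.2f}, "
                     f"weight-vector r={report['cca']['weight_vector_r']:.3f})")
    for name, fit in report.get("prediction", {}).items():
        att = fit["attribution"]
        share = att["tau_share"]
        share_s = "n/a" if share is None else f"{share:.2f}"
        lines.append(
            f"{name}: R2={fit['r2']:.3f} Z={fit['z']:.2f} "
            f"p_perm={fit['p_perm']:.4g} "
            f"(adj {fit['p_adjusted']:.4g}, "
            f"{'significant' if fit['significant'] else 'not significant'}); "
            f"S|b_tau|={att['sum_abs_beta_tau']:.2f} "
            f"S|b_abeta|={att['sum_abs_beta_abeta']:.2f} tau_share={share_s}")
    return "\n".join(lines) + "\n"
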