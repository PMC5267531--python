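"""Group-level inference on topography scores and CSF biomarkers.

Three analyses live here:

* ANCOVA of per-subject topography scores on age, clinical status (CDR,
  dichotomized 0 vs >0 by default) and APOE epsilon-4 carriage, with
  Type-II F tests.
* Preclinical staging of cognitively normal (CDR 0) participants by cohort
  median splits of CSF amyloid-beta 42 and total tau: amyloid-positive
  means Aβ42 *below* the median (CSF Aβ42 falls as plaque burden rises),
  tau-positive means CSF tau above the median.  Amyloid-positive/
  tau-negative is stage 1 preclinical disease; amyloid-positive/
  tau-positive is stage 2.
* The 2 x 3 correlation table between mean gray-matter SUVR per modality
  and the three CSF analytes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .core_io import RoiMatrix, RoiRegistry, SchemaError

ANCOVA_FACTORS = ("age", "cdr", "apoe4")
STAGES = ("healthy", "stage1", "stage2", "tau_only")


@dataclass
class AncovaResult:
    component: int  # 1-based component id
    factors: dict   # factor -> {"F": float, "df_num": int, "df_den": int, "p": float}


def ancova_scores(scores: pd.DataFrame, cohort: pd.DataFrame,
                  cdr_coding: str = "binary") -> list[AncovaResult]:
    """ANCOVA of each score column on age + CDR + APOE4 (Type-II F tests).

    ``scores`` is a subject x component DataFrame indexed by subject ID;
    ``cdr_coding`` is ``"binary"`` (0 vs >0, default) or ``"ordinal"``.
    Degenerate (zero-variance) scores are reported as F=0, p=1 for every
    factor rather than raising.
    """
    common = sorted(set(scores.index) & set(cohort.index))
    if not common:
        raise SchemaError("no overlapping subjects between scores and cohort")
    scores = scores.loc[common]
    meta = cohort.loc[common]
    if cdr_coding == "binary":
        cdr_term = (meta["cdr"] != "0").astype(int)
    elif cdr_coding == "ordinal":
        cdr_term = meta["cdr"].map({"0": 0, "0.5": 1, "1+": 2}).astype(int)
    else:
        raise ValueError("cdr_coding must be 'binary' or 'ordinal'")
    for name, col in (("cdr", cdr_term), ("apoe4", meta["apoe4"].astype(int))):
        if col.nunique() < 2:
            raise ValueError(f"singular design: factor {name!r} has a single "
                             "level in the aligned cohort")
    groups = cdr_term.value_counts()
    if (groups < 2).any():
        raise ValueError("need at least 2 subjects per CDR group")

    results = []
    for k, col in enumerate(scores.columns):
        y = scores[col].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            factors = {f: {"F": 0.0, "df_num": 1,
                           "df_den": len(common) - 4, "p": 1.0}
                       for f in ANCOVA_FACTORS}
            results.append(AncovaResult(component=k + 1, factors=factors))
            continue
        df = pd.DataFrame({"score": y, "age": meta["age"].to_numpy(float),
                           "cdr_f": cdr_term.to_numpy(int),
                           "apoe4_f": meta["apoe4"].to_numpy(int)})
        model = smf.ols("score ~ age + C(cdr_f) + C(apoe4_f)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        factors = {}
        for name, row_key in (("age", "age"), ("cdr", "C(cdr_f)"),
                              ("apoe4", "C(apoe4_f)")):
            row = table.loc[row_key]
            factors[name] = {"F": float(row["F"]),
                             "df_num": int(row["df"]),
                             "df_den": int(table.loc["Residual", "df"]),
                             "p": float(row["PR(>F)"])}
        results.append(AncovaResult(component=k + 1, factors=factors))
    return results


@dataclass
class StageLabel:
    subject_id: str
    stage: str
    abeta_positive: bool
    tau_positive: bool


@dataclass
class StagingResult:
    labels: list[StageLabel]
    median_abeta42: float
    median_tau: float
    n_skipped: int

    def counts(self) -> dict[str, int]:
        out = {s: 0 for s in STAGES}
        for lab in self.labels:
            out[lab.stage] += 1
        return out


def stage_preclinical(csf: pd.DataFrame, cohort: pd.DataFrame,
                      population: str = "cdr0") -> StagingResult:
    """Stage CDR 0 participants by CSF median splits.

    Medians are computed over the CDR 0 subjects with CSF (default) or over
    all CSF subjects (``population="all"``).  Positivity is strict:
    amyloid-positive iff Aβ42 strictly below its median, tau-positive iff
    CSF total tau strictly above its median — ties count as negative.
    Subjects missing an analyte are skipped and counted.
    """
    cdr0 = cohort.index[cohort["cdr"] == "0"]
    targets = sorted(set(cdr0) & set(csf.index))
    if len(targets) < 2:
        raise ValueError("need at least 2 CDR0 subjects with CSF to stage")
    if population == "cdr0":
        pool = csf.loc[targets]
    elif population == "all":
        pool = csf
    else:
        raise ValueError("population must be 'cdr0' or 'all'")
    med_ab = float(np.nanmedian(pool["abeta42"]))
    med_tau = float(np.nanmedian(pool["tau"]))

    labels, skipped = [], 0
    for sid in targets:
        ab42, tau = csf.at[sid, "abeta42"], csf.at[sid, "tau"]
        if not (np.isfinite(ab42) and np.isfinite(tau)):
            skipped += 1
            continue
        ab_pos = ab42 < med_ab
        tau_pos = tau > med_tau
        if ab_pos and tau_pos:
            stage = "stage2"
        elif ab_pos:
            stage = "stage1"
        elif tau_pos:
            stage = "tau_only"
        else:
            stage = "healthy"
        labels.append(StageLabel(subject_id=sid, stage=stage,
                                 abeta_positive=bool(ab_pos),
                                 tau_positive=bool(tau_pos)))
    if skipped:
        warnings.warn(f"staging skipped {skipped} subject(s) with missing "
                      "CSF analytes", stacklevel=2)
    return StagingResult(labels=labels, median_abeta42=med_ab,
                         median_tau=med_tau, n_skipped=skipped)


def mean_suvr_csf_correlations(tau: RoiMatrix, abeta: RoiMatrix,
                               csf: pd.DataFrame,
                               registry: RoiRegistry) -> pd.DataFrame:
    """Pearson correlations between mean gray-matter SUVR and CSF analytes.

    The per-subject summary is the unweighted mean SUVR over the registry's
    gray-matter regions.  Returns a DataFrame indexed by PET modality with
    MultiIndex columns ``(analyte, "r"/"p")``; undefined correlations
    (zero variance) are NaN.
    """
    gm = list(registry.gray_matter_regions)
    analytes = ("tau", "ptau", "abeta42")
    rows = {}
    for mat in (tau, abeta):
        idx = [mat.region_ids.index(r) for r in gm]
        mean_suvr = pd.Series(mat.values[:, idx].mean(axis=1),
                              index=list(mat.subject_ids))
        common = sorted(set(mean_suvr.index) & set(csf.index))
        if len(common) < 4:
            raise ValueError("need at least 4 overlapping subjects")
        x = mean_suvr.loc[common].to_numpy()
        row = {}
        for analyte in analytes:
            y = csf.loc[common, analyte].to_numpy(dtype=float)
            ok = np.isfinite(y)
            if ok.sum() < 4 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                row[(analyte, "r")] = np.nan
                row[(analyte, "p")] = np.nan
            else:
                res = stats.pearsonr(x[ok], y[ok])
                row[(analyte, "r")] = float(res.statistic)
                row[(analyte, "p")] = float(res.pvalue)
        rows[mat.modality] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.columns = pd.MultiIndex.from_tuples(out.columns)
    out.index.name = "modality"
    return out
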