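"""Tabular I/O, validation, and the cohort data model.

All analyses operate on regional standardized-uptake-value-ratio (SUVR)
tables: one row per subject, one column per bilateral region of interest
(ROI), one table per PET modality (tau tracer, amyloid tracer).  Clinical
metadata, CSF analytes and neuropsychological composites live in companion
tables keyed by subject ID.  This module reads and validates those tables,
aligns them into a single cohort object, and serializes every downstream
result type.

Subject ordering is lexicographic by ID everywhere so that all downstream
matrices are bit-reproducible regardless of input row order.
"""
from __future__ import annotations

import dataclasses
import json
import math
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

MODALITIES = ("tau", "abeta")
LOBES = ("temporal", "frontal", "parietal", "occipital", "subcortical",
         "cingulate", "insula")
CDR_LEVELS = ("0", "0.5", "1+")


class SchemaError(ValueError):
    """Input table violates the expected schema (columns, labels, keys)."""


class ParseError(ValueError):
    """A cell value cannot be interpreted (non-numeric, non-positive, ...)."""


# ---------------------------------------------------------------------------
# ROI registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoiRegistry:
    """Ordered list of bilateral region labels with lobe tags."""

    region_ids: tuple[str, ...]
    lobe_map: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(set(self.region_ids)) != len(self.region_ids):
            raise SchemaError("region labels must be unique")
        missing = [r for r in self.region_ids if r not in self.lobe_map]
        if missing:
            raise SchemaError(f"regions without lobe tag: {missing}")
        bad = {r: t for r, t in self.lobe_map.items() if t not in LOBES}
        if bad:
            raise SchemaError(f"unknown lobe tags: {bad}")

    def __len__(self) -> int:
        return len(self.region_ids)

    def regions_in_lobe(self, lobe: str) -> list[str]:
        return [r for r in self.region_ids if self.lobe_map[r] == lobe]

    @property
    def gray_matter_regions(self) -> tuple[str, ...]:
        """All registry regions; every default entry is gray matter."""
        return self.region_ids


def load_registry(path: str | Path | None = None) -> RoiRegistry:
    """Load an ROI registry from YAML; ``None`` loads the packaged default.

    The default registry holds exactly 42 bilaterally-averaged regions:
    the 34 Desikan-Killiany cortical parcels plus 8 subcortical structures.
    """
    if path is None:
        ref = importlib.resources.files("topomark").joinpath(
            "data/default_registry.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    try:
        entries = raw["regions"]
        ids = tuple(str(e["id"]) for e in entries)
        lobes = {str(e["id"]): str(e["lobe"]) for e in entries}
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed registry file: {exc}") from exc
    return RoiRegistry(region_ids=ids, lobe_map=lobes)


# ---------------------------------------------------------------------------
# Core tables
# ---------------------------------------------------------------------------

@dataclass
class RoiMatrix:
    """One modality's subject x ROI SUVR table.

    ``values[i, j]`` is the SUVR (dimensionless uptake ratio, reference
    cerebellar gray) of subject ``subject_ids[i]`` in region
    ``region_ids[j]``.  ``pvc`` records whether the upstream pipeline
    applied partial-volume correction; it is metadata only.
    """

    subject_ids: tuple[str, ...]
    modality: str
    values: np.ndarray
    region_ids: tuple[str, ...]
    pvc: bool = False

    def __post_init__(self) -> None:
        self.subject_ids = tuple(str(s) for s in self.subject_ids)
        self.region_ids = tuple(str(r) for r in self.region_ids)
        if self.modality not in MODALITIES:
            raise SchemaError(f"modality must be one of {MODALITIES}, "
                              f"got {self.modality!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.region_ids)):
            raise SchemaError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.region_ids)} regions")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise SchemaError("duplicate subject IDs")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ParseError(f"non-finite SUVR at subject "
                             f"{self.subject_ids[i]!r}, region {self.region_ids[j]!r}")
        if np.any(self.values <= 0):
            i, j = np.argwhere(self.values <= 0)[0]
            raise ParseError(
                f"non-positive SUVR {self.values[i, j]!r} at subject "
                f"{self.subject_ids[i]!r}, region {self.region_ids[j]!r}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.copy(),
                            index=list(self.subject_ids),
                            columns=list(self.region_ids))

    def subset(self, subject_ids: Sequence[str]) -> "RoiMatrix":
        """Row-subset in the given order; unknown IDs raise."""
        index = {s: i for i, s in enumerate(self.subject_ids)}
        try:
            rows = [index[s] for s in subject_ids]
        except KeyError as exc:
            raise SchemaError(f"unknown subject ID {exc.args[0]!r}") from exc
        return RoiMatrix(subject_ids=tuple(subject_ids), modality=self.modality,
                         values=self.values[rows], region_ids=self.region_ids,
                         pvc=self.pvc)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(path, sep=sep, dtype={0: str})


def read_roi_matrix(path: str | Path, registry: RoiRegistry,
                    modality: str, pvc: bool = False) -> RoiMatrix:
    """Read a delimited subject x ROI SUVR table, validated and reordered.

    The file must carry a header row of region labels and a first column of
    subject IDs.  Columns are reordered to registry order; missing or extra
    region columns are a schema error naming the offending labels.
    """
    df = _read_table(path)
    df = df.set_index(df.columns[0])
    have = set(df.columns)
    want = set(registry.region_ids)
    missing = sorted(want - have)
    extra = sorted(have - want)
    if missing or extra:
        raise SchemaError(
            f"ROI columns do not match registry: missing={missing}, extra={extra}")
    df = df[list(registry.region_ids)]
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, (sid, cell) in enumerate(df[col].items()):
            try:
                v = float(cell)
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"non-numeric SUVR {cell!r} at subject {sid!r}, "
                    f"region {col!r}") from exc
            if not math.isfinite(v) or v <= 0:
                raise ParseError(
                    f"invalid SUVR {cell!r} at subject {sid!r}, region {col!r}"
                    " (must be finite and > 0)")
            values[i, j] = v
    return RoiMatrix(subject_ids=tuple(str(s) for s in df.index),
                     modality=modality, values=values,
                     region_ids=registry.region_ids, pvc=pvc)


def write_roi_matrix(matrix: RoiMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "subject_id"
    sep = "\t" if str(path).lower().endswith((".tsv", ".tab", ".txt")) else ","
    df.to_csv(path, sep=sep, float_format="%.17g")


def _validate_subject_frame(df: pd.DataFrame, name: str) -> pd.DataFrame:
    if "subject_id" != df.columns[0]:
        df = df.rename(columns={df.columns[0]: "subject_id"})
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise SchemaError(f"{name}: duplicate subject IDs {dups}")
    return df.set_index("subject_id")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Cohort metadata: subject_id, age, sex, cdr ('0'/'0.5'/'1+'), apoe4."""
    df = _validate_subject_frame(_read_table(path), "cohort")
    return validate_cohort(df)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    need = {"age", "sex", "cdr", "apoe4"}
    missing = sorted(need - set(df.columns))
    if missing:
        raise SchemaError(f"cohort table missing columns {missing}")
    df = df.copy()
    df["cdr"] = df["cdr"].astype(str)
    bad = sorted(set(df["cdr"]) - set(CDR_LEVELS))
    if bad:
        raise ParseError(f"cohort cdr values outside {CDR_LEVELS}: {bad}")
    df["age"] = df["age"].astype(float)
    if (df["age"] <= 0).any():
        raise ParseError("cohort age must be > 0")
    df["apoe4"] = df["apoe4"].astype(str).str.lower().isin(
        {"1", "true", "yes", "carrier"}) | (df["apoe4"] == True)  # noqa: E712
    return df


def read_csf(path: str | Path) -> pd.DataFrame:
    """CSF analytes (pg/mL): subject_id, tau, ptau, abeta42."""
    df = _validate_subject_frame(_read_table(path), "csf")
    return validate_csf(df)


def validate_csf(df: pd.DataFrame) -> pd.DataFrame:
    need = {"tau", "ptau", "abeta42"}
    missing = sorted(need - set(df.columns))
    if missing:
        raise SchemaError(f"CSF table missing columns {missing}")
    df = df.copy()
    for col in need:
        df[col] = df[col].astype(float)
        if (df[col].dropna() <= 0).any():
            raise ParseError(f"CSF {col} must be > 0 (pg/mL)")
    return df


COMPOSITE_DOMAINS = ("episodic", "semantic", "working", "visuospatial", "global")


def read_composites(path: str | Path) -> pd.DataFrame:
    """Neuropsychological composite Z-scores, one column per domain."""
    df = _validate_subject_frame(_read_table(path), "composites")
    return validate_composites(df)


def validate_composites(df: pd.DataFrame) -> pd.DataFrame:
    missing = sorted(set(COMPOSITE_DOMAINS) - set(df.columns))
    if missing:
        raise SchemaError(f"composite table missing columns {missing}")
    df = df.copy()
    for col in COMPOSITE_DOMAINS:
        df[col] = df[col].astype(float)
        if not np.isfinite(df[col]).all():
            raise ParseError(f"composite {col} contains non-finite values")
    return df


# ---------------------------------------------------------------------------
# Cohort alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignedCohort:
    """Inner-joined dataset: PET matrices + metadata, sorted by subject ID.

    ``csf`` and ``composites`` hold only the subjects that have those
    measures (subsets of ``subjects``); ``subset_sizes`` records the n used
    by each family of analyses.
    """

    subjects: tuple[str, ...]
    matrices: dict[str, RoiMatrix]
    cohort: pd.DataFrame
    csf: pd.DataFrame | None
    composites: pd.DataFrame | None
    subset_sizes: dict[str, int]

    @property
    def tau(self) -> RoiMatrix:
        return self.matrices["tau"]

    @property
    def abeta(self) -> RoiMatrix:
        return self.matrices["abeta"]


def align_cohort(matrices: Sequence[RoiMatrix], cohort: pd.DataFrame,
                 csf: pd.DataFrame | None = None,
                 composites: pd.DataFrame | None = None) -> AlignedCohort:
    """Inner-join PET matrices and metadata on subject ID.

    The core analysis set is the intersection of all PET matrices and the
    cohort table; CSF and composite tables define (possibly smaller)
    per-analysis subsets.  Ordering is lexicographic by ID and independent
    of the order of ``matrices``.
    """
    if not matrices:
        raise SchemaError("no PET matrices supplied")
    common: set[str] = set(cohort.index)
    for m in matrices:
        common &= set(m.subject_ids)
    if not common:
        raise SchemaError("empty subject intersection between PET matrices "
                          "and cohort table")
    subjects = tuple(sorted(common))
    mats = {m.modality: m.subset(subjects)
            for m in sorted(matrices, key=lambda m: m.modality)}
    sizes = {"pet": len(subjects)}
    csf_out = None
    if csf is not None:
        keep = sorted(set(csf.index) & common)
        csf_out = csf.loc[keep]
        sizes["csf"] = len(keep)
    comp_out = None
    if composites is not None:
        keep = sorted(set(composites.index) & common)
        comp_out = composites.loc[keep]
        sizes["neuropsych"] = len(keep)
    return AlignedCohort(subjects=subjects, matrices=mats,
                         cohort=cohort.loc[list(subjects)], csf=csf_out,
                         composites=comp_out, subset_sizes=sizes)


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------

def _jsonable(obj: Any) -> Any:
    """Recursively convert to JSON-safe types; NaN/inf become null."""
    if obj is None or isinstance(obj, (str, bool, int)):
        return obj
    if isinstance(obj, float):
        return obj if math.isfinite(obj) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if math.isfinite(v) else None
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(x) for x in obj.tolist()]
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="list"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    raise TypeError(f"cannot serialize {type(obj)!r}")


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(_jsonable(obj), indent=2, sort_keys=True,
                   allow_nan=False) + "\n")


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())


def write_matrix_csv(values: np.ndarray, index: Sequence[str],
                     columns: Sequence[str], path: str | Path,
                     index_name: str = "id") -> None:
    df = pd.DataFrame(np.asarray(values, dtype=float),
                      index=list(index), columns=list(columns))
    df.index.name = index_name
    df.to_csv(path, float_format="%.17g")


def read_matrix_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_results(obj: Any, path: str | Path) -> list[Path]:
    """Serialize a result object.

    Matrix-valued results (topography sets, canonical pairs, penalized
    fits) produce delimited weight/score tables next to a JSON summary;
    everything else becomes a single JSON file.  Returns the written paths.
    The write/read pair round-trips numeric content to 1e-12.
    """
    # imported here to avoid circular imports at module load
    from . import topography, crossmodal, prediction

    path = Path(path)
    written: list[Path] = []

    def emit_json(summary: Mapping[str, Any]) -> None:
        p = path.with_suffix(".json")
        write_json(summary, p)
        written.append(p)

    if isinstance(obj, topography.TopographySet):
        wpath = path.parent / (path.stem + "_weights.csv")
        spath = path.parent / (path.stem + "_scores.csv")
        comp = [f"component_{k + 1}" for k in range(obj.weights.shape[0])]
        write_matrix_csv(obj.weights.T, obj.region_ids, comp, wpath, "region")
        write_matrix_csv(obj.scores, obj.subject_ids, comp, spath, "subject_id")
        written += [wpath, spath]
        emit_json(obj.summary())
    elif isinstance(obj, crossmodal.CanonicalPair):
        for tag, w in (("tau", obj.weights_tau), ("abeta", obj.weights_abeta)):
            p = path.parent / (path.stem + f"_weights_{tag}.csv")
            comp = [f"pair_{k + 1}" for k in range(w.shape[0])]
            write_matrix_csv(w.T, obj.region_ids, comp, p, "region")
            written.append(p)
        emit_json(obj.summary())
    elif isinstance(obj, prediction.PenalizedFit):
        p = path.parent / (path.stem + "_beta.csv")
        rows = pd.DataFrame({
            "modality": [c[0] for c in obj.columns],
            "region": [c[1] for c in obj.columns],
            "beta_std": obj.beta,
            "beta_raw": obj.beta_raw,
        })
        rows.to_csv(p, index=False, float_format="%.17g")
        written.append(p)
        emit_json(obj.summary())
    elif isinstance(obj, RoiMatrix):
        p = path.with_suffix(".csv")
        write_roi_matrix(obj, p)
        written.append(p)
    elif isinstance(obj, pd.DataFrame):
        p = path.with_suffix(".csv")
        out = obj.copy()
        out.to_csv(p, float_format="%.17g")
        written.append(p)
    else:
        emit_json(obj if isinstance(obj, Mapping) else _jsonable(obj))
    return written
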