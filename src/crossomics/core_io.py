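"""Data model, file I/O, configuration, and logging shared by all pipeline stages.

The pipeline's on-disk interchange is plain delimited text (TSV by default,
CSV via an explicit delimiter flag — the reader never guesses). Missing
values are encoded by a configurable token (default ``"NA"``) and held
internally as ``NaN``; numeric sentinels are never used. All sample/feature
alignment is by ID string, never by position.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("crossomics")
if not log.handlers:  # default stderr handler; applications may reconfigure
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

FLUIDS = ("serum", "csf", "stool")
DIETS = ("MMKD", "AHAD", "none")
TIMEPOINTS = ("pre", "post", "baseline", "followup")
SEQUENCES = ("MMKD_first", "AHAD_first")
DIAGNOSES = ("CN", "MCI")
SEXES = ("F", "M")
VALUE_KINDS = ("concentration", "percentage", "count", "derived")

#: metadata columns required for every sample record
METADATA_COLUMNS = (
    "subject_id",
    "fluid",
    "diet",
    "timepoint",
    "sequence",
    "diagnosis",
    "age",
    "sex",
)

_ENUM_DOMAINS = {
    "fluid": FLUIDS,
    "diet": DIETS,
    "timepoint": TIMEPOINTS,
    "sequence": SEQUENCES,
    "diagnosis": DIAGNOSES,
    "sex": SEXES,
}


class DataError(ValueError):
    """Raised on malformed or inconsistent input data."""


@dataclass
class FeatureMatrix:
    """Samples x features value matrix plus per-feature metadata.

    ``values`` is a float DataFrame indexed by sample_id with feature names
    as columns; missing cells are NaN. ``feature_meta`` is indexed by
    feature name with columns ``fluid``, ``value_kind`` and ``group``.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if list(self.values.columns) != list(self.feature_meta.index):
            raise DataError("feature columns do not align with feature_meta index")
        if self.values.index.has_duplicates:
            raise DataError("duplicated sample IDs in feature matrix")
        if self.feature_meta.index.has_duplicates:
            raise DataError("duplicated feature names")
        bad_kind = set(self.feature_meta["value_kind"]) - set(VALUE_KINDS)
        if bad_kind:
            raise DataError(f"unknown value_kind(s): {sorted(bad_kind)}")
        pct = self.feature_meta.index[self.feature_meta["value_kind"] == "percentage"]
        if len(pct):
            block = self.values[pct].to_numpy(float)
            with np.errstate(invalid="ignore"):
                if np.nanmin(block, initial=0.0) < -1e-9 or np.nanmax(block, initial=0.0) > 100 + 1e-9:
                    raise DataError("percentage features must lie in [0, 100]")
        cnt = self.feature_meta.index[self.feature_meta["value_kind"] == "count"]
        if len(cnt):
            block = self.values[cnt].to_numpy(float)
            obs = block[~np.isnan(block)]
            if obs.size and ((obs < 0).any() or (np.abs(obs - np.round(obs)) > 1e-9).any()):
                raise DataError("count features must be non-negative integers")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def subset_features(self, names) -> "FeatureMatrix":
        names = list(names)
        return FeatureMatrix(self.values[names].copy(), self.feature_meta.loc[names].copy())

    def subset_samples(self, ids) -> "FeatureMatrix":
        ids = list(ids)
        return FeatureMatrix(self.values.loc[ids].copy(), self.feature_meta.copy())

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.values.copy(), self.feature_meta.copy())


@dataclass
class StudyDataset:
    """Sample metadata plus one FeatureMatrix per omic.

    ``samples`` is indexed by sample_id with the columns in
    :data:`METADATA_COLUMNS`; ``tables`` maps an omic name (e.g. ``serum``)
    to its FeatureMatrix. Ground-truth annotations from simulation ride
    along in ``truth`` when available.
    """

    samples: pd.DataFrame
    tables: dict[str, FeatureMatrix]
    truth: object | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.samples.index.has_duplicates:
            raise DataError("duplicated sample IDs in metadata")
        missing_cols = set(METADATA_COLUMNS) - set(self.samples.columns)
        if missing_cols:
            raise DataError(f"metadata missing columns: {sorted(missing_cols)}")
        for col, domain in _ENUM_DOMAINS.items():
            bad = set(self.samples[col].dropna()) - set(domain)
            if bad:
                raise DataError(f"unknown {col} value(s): {sorted(bad)}")
        # a subject's samples may hold at most one pre and one post per diet per fluid
        key = self.samples.groupby(["subject_id", "fluid", "diet", "timepoint"]).size()
        if (key > 1).any():
            dup = key[key > 1].index[0]
            raise DataError(f"multiple samples for subject/fluid/diet/timepoint {dup}")
        for omic, fm in self.tables.items():
            unknown = set(fm.sample_ids) - set(self.samples.index)
            if unknown:
                raise DataError(
                    f"table '{omic}' contains samples absent from metadata: {sorted(unknown)[:5]}"
                )

    def samples_for(self, fluid: str, diet: str | None = None) -> pd.DataFrame:
        sel = self.samples[self.samples["fluid"] == fluid]
        if diet is not None:
            sel = sel[sel["diet"] == diet]
        return sel


@dataclass
class PipelineConfig:
    """Tunable parameters of every stage, mirrored 1:1 by the YAML config."""

    missing_frac_threshold: float = 0.40
    knn_k: int = 10
    lof_k: int = 10
    lof_threshold: float = 1.5
    fdr_serum: float = 0.20
    fdr_csf: float = 0.05
    fdr_network: float = 0.05
    clr_pseudocount: float = 1.0
    extreme_z: float = 4.0
    cp_rank: int = 2
    cp_n_restarts: int = 10
    cp_max_iter: int = 200
    cp_tol: float = 1e-8
    min_pairs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_frac_threshold", "fdr_serum", "fdr_csf", "fdr_network"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise DataError(f"{name} must lie in (0, 1); got {v}")
        for name in ("knn_k", "lof_k", "cp_rank", "cp_n_restarts", "min_pairs"):
            if getattr(self, name) < 1:
                raise DataError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_table(path, delimiter: str, missing_token: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=delimiter,
        index_col=0,
        na_values=[missing_token],
        keep_default_na=False,
        dtype=str,
    )
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"non-numeric cell at sample {df.index[r]!r}, feature {df.columns[c]!r}: "
            f"{df.iat[r, c]!r} (missing token is {missing_token!r})"
        )
    num.index = num.index.astype(str)
    return num


def read_dataset(
    metadata_path,
    table_paths: Mapping[str, object],
    feature_meta_paths: Mapping[str, object] | None = None,
    delimiter: str = "\t",
    missing_token: str = "NA",
) -> StudyDataset:
    """Read sample metadata and per-omic feature tables into a StudyDataset.

    Feature tables have sample IDs as rows and features as columns. Samples
    present in a table but absent from metadata are an error; metadata
    samples absent from a table are allowed (fluid not collected). When no
    feature metadata file accompanies a table, value kinds default to
    ``concentration`` (``count`` for the ``stool`` omic).
    """
    meta = pd.read_csv(
        metadata_path, sep=delimiter, index_col=0,
        na_values=[missing_token], keep_default_na=False,
    )
    meta.index = meta.index.astype(str)
    if meta.index.has_duplicates:
        raise DataError("duplicated sample IDs in metadata")
    meta["age"] = pd.to_numeric(meta["age"], errors="raise")
    tables: dict[str, FeatureMatrix] = {}
    for omic, path in table_paths.items():
        values = _read_table(path, delimiter, missing_token)
        if feature_meta_paths and omic in feature_meta_paths:
            fmeta = pd.read_csv(feature_meta_paths[omic], sep=delimiter, index_col=0)
            fmeta = fmeta.loc[values.columns]
        else:
            kind = "count" if omic == "stool" else "concentration"
            fmeta = pd.DataFrame(
                {"fluid": omic, "value_kind": kind, "group": "unannotated"},
                index=values.columns,
            )
        tables[omic] = FeatureMatrix(values, fmeta)
    ds = StudyDataset(meta, tables)
    log.info(
        "read_dataset: %d samples; tables: %s",
        len(meta),
        {k: v.values.shape for k, v in tables.items()},
    )
    return ds


def write_dataset(ds: StudyDataset, out_dir, delimiter: str = "\t", missing_token: str = "NA") -> dict:
    """Write metadata, per-omic tables and feature metadata; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"metadata": out_dir / "samples.tsv"}
    ds.samples.to_csv(paths["metadata"], sep=delimiter, index_label="sample_id", na_rep=missing_token)
    for omic, fm in ds.tables.items():
        p = out_dir / f"{omic}.tsv"
        fm.values.to_csv(p, sep=delimiter, index_label="sample_id", na_rep=missing_token)
        pm = out_dir / f"{omic}.features.tsv"
        fm.feature_meta.to_csv(pm, sep=delimiter, index_label="feature")
        paths[omic] = p
        paths[f"{omic}.features"] = pm
    return paths


DA_COLUMNS = ["feature", "term", "fluid", "estimate", "se", "ci_low", "ci_high", "p", "adj_p", "significant"]
EDGE_COLUMNS = ["serum_feature", "csf_feature", "r", "n", "p", "adj_p", "serum_group", "csf_group"]


def write_da_results(results: pd.DataFrame, path, delimiter: str = "\t") -> Path:
    """Write a differential-abundance result table (one row per feature x term)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    results[DA_COLUMNS].to_csv(path, sep=delimiter, index=False)
    return path


def read_da_results(path, delimiter: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter)
    df["significant"] = df["significant"].astype(bool)
    return df


def write_edges(edges: pd.DataFrame, path, delimiter: str = "\t") -> Path:
    """Write the bipartite delta-correlation edge list (header always present)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in EDGE_COLUMNS if c in edges.columns] or EDGE_COLUMNS
    if edges.empty:
        pd.DataFrame(columns=EDGE_COLUMNS).to_csv(path, sep=delimiter, index=False)
    else:
        edges[cols].to_csv(path, sep=delimiter, index=False)
    return path


def read_edges(path, delimiter: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=delimiter)


def write_factorization(fact, out_dir, delimiter: str = "\t") -> list[Path]:
    """Write a joint factorization as one loading table per mode per omic.

    Layout: one shared subject-loading table, then per omic a feature
    table, a time table and a scales vector — 1 + 3 x n_omics files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cols = [f"comp_{r + 1}" for r in range(fact.rank)]
    paths = [out_dir / "subjects.tsv"]
    pd.DataFrame(fact.A, index=fact.subject_ids, columns=cols).to_csv(
        paths[0], sep=delimiter, index_label="subject_id"
    )
    for omic in fact.omics:
        pf = out_dir / f"{omic}.features.tsv"
        pd.DataFrame(fact.B[omic], index=fact.feature_ids[omic], columns=cols).to_csv(
            pf, sep=delimiter, index_label="feature"
        )
        pt = out_dir / f"{omic}.time.tsv"
        pd.DataFrame(fact.C[omic], index=fact.time_ids[omic], columns=cols).to_csv(
            pt, sep=delimiter, index_label="time"
        )
        ps = out_dir / f"{omic}.scales.tsv"
        pd.DataFrame({"scale": fact.scales[omic]}, index=pd.Index(cols, name="component")).to_csv(
            ps, sep=delimiter
        )
        paths += [pf, pt, ps]
    return paths


def read_factorization(in_dir, delimiter: str = "\t"):
    """Read back a factorization written by :func:`write_factorization`."""
    from .tensorfact import JointFactorization  # local import avoids a cycle

    in_dir = Path(in_dir)
    subj = pd.read_csv(in_dir / "subjects.tsv", sep=delimiter, index_col=0)
    omics = sorted(
        p.name[: -len(".features.tsv")]
        for p in in_dir.glob("*.features.tsv")
        if p.name != "subjects.tsv"
    )
    B, C, scales, feat_ids, time_ids = {}, {}, {}, {}, {}
    for omic in omics:
        bf = pd.read_csv(in_dir / f"{omic}.features.tsv", sep=delimiter, index_col=0)
        cf = pd.read_csv(in_dir / f"{omic}.time.tsv", sep=delimiter, index_col=0)
        sf = pd.read_csv(in_dir / f"{omic}.scales.tsv", sep=delimiter, index_col=0)
        B[omic] = bf.to_numpy(float)
        C[omic] = cf.to_numpy(float)
        scales[omic] = sf["scale"].to_numpy(float)
        feat_ids[omic] = list(bf.index)
        time_ids[omic] = list(cf.index)
    return JointFactorization(
        rank=subj.shape[1],
        A=subj.to_numpy(float),
        B=B,
        C=C,
        scales=scales,
        omics=omics,
        subject_ids=list(subj.index),
        feature_ids=feat_ids,
        time_ids=time_ids,
        fit={},
        objective_trace=[],
    )
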