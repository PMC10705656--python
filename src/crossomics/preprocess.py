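"""Feature-matrix preprocessing: transforms, filtering, imputation and QC.

Pipeline order is fixed: transform (log2 for concentrations, clr for the
percentage block) -> filter features by missing fraction -> kNN imputation
-> LOF outlier-sample removal -> extreme-value re-imputation. Each stage
logs its input dimensions and what it removed or imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import LocalOutlierFactor

from .core_io import DataError, FeatureMatrix, PipelineConfig, log


@dataclass
class PreprocessReport:
    n_features_in: int = 0
    n_features_out: int = 0
    removed_features: list = field(default_factory=list)  # (feature, missing_frac)
    n_samples_in: int = 0
    n_samples_out: int = 0
    removed_samples: list = field(default_factory=list)  # (sample, lof_score)
    n_values_imputed: int = 0
    n_extreme_values_reimputed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("n_features_in", self.n_features_in),
            ("n_features_out", self.n_features_out),
            ("n_samples_in", self.n_samples_in),
            ("n_samples_out", self.n_samples_out),
            ("n_values_imputed", self.n_values_imputed),
            ("n_extreme_values_reimputed", self.n_extreme_values_reimputed),
            ("removed_features", ";".join(f"{f}:{m:.3f}" for f, m in self.removed_features)),
            ("removed_samples", ";".join(f"{s}:{v:.3f}" for s, v in self.removed_samples)),
        ]
        return pd.DataFrame(rows, columns=["key", "value"])


def log2_transform(m: FeatureMatrix, features=None) -> FeatureMatrix:
    """log2 each selected (concentration-kind by default) value in place of x.

    Zeros are replaced by half the feature's minimum positive value before
    the log; negative values are an error; missing stays missing.
    """
    if features is None:
        features = m.feature_meta.index[m.feature_meta["value_kind"] == "concentration"]
    features = list(features)
    vals = m.values.copy()
    block = vals[features].to_numpy(float)
    if np.nanmin(block, initial=0.0) < 0:
        raise DataError("negative values cannot be log2-transformed")
    for j, f in enumerate(features):
        col = block[:, j]
        zero = col == 0.0
        if zero.any():
            pos = col[(col > 0) & ~np.isnan(col)]
            if pos.size == 0:
                raise DataError(f"feature {f!r} has no positive values to anchor zeros")
            col[zero] = pos.min() / 2.0
        block[:, j] = np.log2(col)
    vals[features] = block
    meta = m.feature_meta.copy()
    if "source_kind" not in meta.columns:
        meta["source_kind"] = meta["value_kind"]
    # log2 values can be negative; relabel so range checks no longer apply
    meta.loc[features, "value_kind"] = "derived"
    return FeatureMatrix(vals, meta)


def clr_transform(m: FeatureMatrix, features=None, pseudocount: float = 0.0) -> FeatureMatrix:
    """Centered log-ratio over the selected (percentage-kind) block, per sample.

    y_j = ln(x_j + pc) - mean_j ln(x_j + pc). Rows with missing values in
    the block center on the observed subset (logged); missing stays missing.
    """
    if features is None:
        features = m.feature_meta.index[m.feature_meta["value_kind"] == "percentage"]
    features = list(features)
    if not features:
        raise DataError("clr_transform: empty feature block")
    vals = m.values.copy()
    block = vals[features].to_numpy(float)
    if np.nanmin(block + pseudocount, initial=np.inf) <= 0:
        raise DataError("clr requires value + pseudocount > 0")
    logged = np.log(block + pseudocount)
    center = np.nanmean(logged, axis=1, keepdims=True)
    n_partial = int(np.isnan(block).any(axis=1).sum())
    if n_partial:
        log.info("clr_transform: %d rows centered on a partial block", n_partial)
    vals[features] = logged - center
    meta = m.feature_meta.copy()
    if "source_kind" not in meta.columns:
        meta["source_kind"] = meta["value_kind"]
    # values are now on the unconstrained clr scale, no longer [0, 100]
    meta.loc[features, "value_kind"] = "derived"
    return FeatureMatrix(vals, meta)


def filter_missing_features(
    m: FeatureMatrix, threshold: float = 0.40
) -> tuple[FeatureMatrix, list]:
    """Drop features whose missing fraction is strictly greater than threshold."""
    if not (0.0 < threshold < 1.0):
        raise DataError("threshold must lie in (0, 1)")
    frac = m.values.isna().mean(axis=0)
    removed = [(f, float(fr)) for f, fr in frac.items() if fr > threshold]
    keep = [f for f in m.features if frac[f] <= threshold]
    if removed:
        log.info("filter_missing_features: removed %d of %d features", len(removed), len(m.features))
    return m.subset_features(keep), removed


def _zscore_columns(x: np.ndarray) -> np.ndarray:
    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def knn_impute(m: FeatureMatrix, k: int = 10) -> FeatureMatrix:
    """Impute each missing cell from the k nearest samples' values.

    Distances are mean-squared Euclidean over columns observed in both rows,
    computed on per-column z-scored values. For a missing cell, neighbors
    lacking that column are skipped in favor of the next nearest; if no
    neighbor carries the column, the column mean is used.
    """
    x = m.values.to_numpy(float)
    n, p = x.shape
    if n < k + 1:
        raise DataError(f"knn_impute needs at least k+1={k + 1} samples, got {n}")
    if np.isnan(x).all(axis=0).any():
        raise DataError("fully-missing column; run filter_missing_features first")
    obs = ~np.isnan(x)
    if obs.all():
        return m.copy()
    z = _zscore_columns(x)
    col_mean = np.nanmean(x, axis=0)
    out = x.copy()
    missing_rows = np.where(~obs.all(axis=1))[0]
    n_imputed = 0
    for i in missing_rows:
        diffs = z - z[i]
        shared = obs & obs[i]
        sq = np.where(shared, diffs**2, 0.0)
        cnt = shared.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.sqrt(sq.sum(axis=1) / cnt)
        d[cnt == 0] = np.inf
        d[i] = np.inf
        order = np.argsort(d, kind="stable")
        for j in np.where(~obs[i])[0]:
            donors = [r for r in order if np.isfinite(d[r]) and obs[r, j]][:k]
            if donors:
                out[i, j] = x[donors, j].mean()
            else:
                out[i, j] = col_mean[j]
            n_imputed += 1
    log.info("knn_impute: imputed %d cells (k=%d)", n_imputed, k)
    return FeatureMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        m.feature_meta.copy(),
    )


def lof_scores(x: np.ndarray, k: int) -> np.ndarray:
    """Standard local-outlier-factor score per row (>~1 means outlying).

    Uses the usual reachability definition reach(a, b) = max(k-distance(b),
    d(a, b)); all-duplicate neighborhoods degenerate to LOF = 1.
    """
    n = x.shape[0]
    if k >= n:
        raise DataError(f"lof requires k < n_samples (k={k}, n={n})")
    lof = LocalOutlierFactor(n_neighbors=k, metric="euclidean")
    lof.fit(x)
    return -lof.negative_outlier_factor_


def lof_outlier_samples(
    m: FeatureMatrix, k: int = 10, threshold: float = 1.5
) -> tuple[FeatureMatrix, list, pd.Series]:
    """Remove samples whose LOF exceeds threshold; matrix must be complete."""
    x = m.values.to_numpy(float)
    if np.isnan(x).any():
        raise DataError("lof_outlier_samples requires a complete matrix (impute first)")
    scores = pd.Series(lof_scores(x, k), index=m.values.index, name="lof")
    removed = [(s, float(v)) for s, v in scores.items() if v > threshold]
    keep = [s for s in m.sample_ids if scores[s] <= threshold]
    if removed:
        log.info("lof_outlier_samples: removed %d samples (k=%d, thr=%.2f)", len(removed), k, threshold)
    return m.subset_samples(keep), removed, scores


def reimpute_extremes(
    m: FeatureMatrix, z_threshold: float = 4.0, k: int = 10
) -> tuple[FeatureMatrix, int]:
    """Mask values with robust |z| (median/MAD) above threshold, then kNN-impute.

    Features with MAD = 0 are skipped (logged). Returns the replaced count.
    """
    x = m.values.to_numpy(float)
    if np.isnan(x).any():
        raise DataError("reimpute_extremes requires a complete matrix")
    med = np.median(x, axis=0)
    mad = np.median(np.abs(x - med), axis=0) * 1.4826
    skip = mad == 0
    if skip.any():
        log.info("reimpute_extremes: %d features with MAD=0 skipped", int(skip.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs(x - med) / np.where(skip, np.inf, mad)
    mask = z > z_threshold
    count = int(mask.sum())
    if count == 0:
        return m.copy(), 0
    masked = x.copy()
    masked[mask] = np.nan
    fm = FeatureMatrix(
        pd.DataFrame(masked, index=m.values.index, columns=m.values.columns),
        m.feature_meta.copy(),
    )
    return knn_impute(fm, k=k), count


def preprocess_fluid(
    m: FeatureMatrix, config: PipelineConfig | None = None, clr_pseudocount: float = 0.0
) -> tuple[FeatureMatrix, PreprocessReport]:
    """Run the full fixed-order preprocessing pipeline on one fluid's matrix.

    Concentration features are log2-transformed (zeros anchored at half the
    minimum positive value); percentage features are clr-transformed with
    ``clr_pseudocount`` (default 0: platform percentages are positive).
    """
    config = config or PipelineConfig()
    report = PreprocessReport(
        n_features_in=len(m.features), n_samples_in=len(m.sample_ids)
    )
    kinds = m.feature_meta["value_kind"]
    conc = list(kinds.index[kinds == "concentration"])
    pct = list(kinds.index[kinds == "percentage"])
    out = m
    if conc:
        out = log2_transform(out, conc)
    if pct:
        out = clr_transform(out, pct, pseudocount=clr_pseudocount)
    out, removed = filter_missing_features(out, config.missing_frac_threshold)
    report.removed_features = removed
    report.n_values_imputed = int(out.values.isna().to_numpy().sum())
    out = knn_impute(out, k=config.knn_k)
    out, removed_samples, _scores = lof_outlier_samples(
        out, k=config.lof_k, threshold=config.lof_threshold
    )
    report.removed_samples = removed_samples
    out, n_extreme = reimpute_extremes(out, z_threshold=config.extreme_z, k=config.knn_k)
    report.n_extreme_values_reimputed = n_extreme
    report.n_features_out = len(out.features)
    report.n_samples_out = len(out.sample_ids)
    log.info(
        "preprocess_fluid: %dx%d -> %dx%d, %d imputed, %d extremes re-imputed",
        report.n_samples_in, report.n_features_in,
        report.n_samples_out, report.n_features_out,
        report.n_values_imputed, n_extreme,
    )
    return out, report
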