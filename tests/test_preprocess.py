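import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from crossomics import DataError, PipelineConfig, generate_study, preprocess_fluid
from crossomics.preprocess import (
    clr_transform,
    filter_missing_features,
    knn_impute,
    lof_outlier_samples,
    lof_scores,
    log2_transform,
    reimpute_extremes,
)


# --------------------------------------------------------------- oracles ---

def knn_impute_oracle(x: np.ndarray, k: int) -> np.ndarray:
    """Exhaustive-search re-statement of the imputation contract.

    Distances: sqrt of the mean squared difference over columns observed in
    both rows, on per-column z-scored values; for each missing cell sort
    every candidate donor, skip donors lacking that column, average the k
    nearest donor values (column mean if no donor carries the column).
    """
    x = x.astype(float)
    n, p = x.shape
    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    out = x.copy()
    for i in range(n):
        for j in range(p):
            if not np.isnan(x[i, j]):
                continue
            dists = []
            for r in range(n):
                if r == i:
                    continue
                shared = [c for c in range(p) if not np.isnan(x[i, c]) and not np.isnan(x[r, c])]
                if not shared:
                    continue
                d = np.sqrt(sum((z[i, c] - z[r, c]) ** 2 for c in shared) / len(shared))
                dists.append((d, r))
            dists.sort(key=lambda t: t[0])
            donors = [r for _, r in dists if not np.isnan(x[r, j])][:k]
            out[i, j] = np.mean([x[r, j] for r in donors]) if donors else mu[j]
    return out


def lof_oracle(x: np.ndarray, k: int) -> np.ndarray:
    """LOF straight from its definition (k-distance, reachability, lrd)."""
    n = len(x)
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    kdist = np.sort(d, axis=1)[:, k - 1]
    neigh = [np.where(d[i] <= kdist[i])[0] for i in range(n)]
    lrd = np.empty(n)
    for i in range(n):
        reach = np.maximum(kdist[neigh[i]], d[i, neigh[i]])
        lrd[i] = 1.0 / reach.mean()
    return np.array([lrd[neigh[i]].mean() / lrd[i] for i in range(n)])


# ------------------------------------------------------------ transforms ---

def test_log2_closed_forms():
    m = make_matrix(np.array([[8.0, 1.0], [2.0, 2.0]]))
    out = log2_transform(m).values.to_numpy()
    np.testing.assert_allclose(out, [[3.0, 0.0], [1.0, 1.0]])


def test_log2_zero_anchored_at_half_min_positive():
    m = make_matrix(np.array([[0.0], [4.0], [8.0]]))
    out = log2_transform(m).values.to_numpy()
    assert out[0, 0] == np.log2(2.0)  # half of min positive 4


def test_log2_negative_rejected():
    with pytest.raises(DataError, match="negative"):
        log2_transform(make_matrix(np.array([[-1.0]])))


def test_clr_closed_forms_and_zero_sum():
    m = make_matrix(np.array([[1.0, 1.0, 1.0, 1.0]]), kind="percentage")
    np.testing.assert_allclose(clr_transform(m, pseudocount=0).values.to_numpy(), 0.0, atol=1e-12)
    e = np.e
    m = make_matrix(np.array([[1.0, e, e**2]]), kind="percentage")
    np.testing.assert_allclose(
        clr_transform(m, pseudocount=0).values.to_numpy(), [[-1.0, 0.0, 1.0]], atol=1e-12
    )
    rng = np.random.default_rng(0)
    m = make_matrix(rng.uniform(0.5, 20, (6, 8)), kind="percentage")
    out = clr_transform(m, pseudocount=0).values.to_numpy()
    np.testing.assert_allclose(out.sum(axis=1), 0.0, atol=1e-10)


def test_missing_filter_is_strictly_greater_than():
    x = np.ones((10, 3))
    x[:5, 0] = np.nan  # 50% missing -> removed at 0.4
    x[:4, 1] = np.nan  # exactly 40% -> retained ("over" is strict)
    m = make_matrix(x)
    kept, removed = filter_missing_features(m, 0.4)
    assert [f for f, _ in removed] == ["f0"]
    assert kept.features == ["f1", "f2"]
    kept2, removed2 = filter_missing_features(make_matrix(np.ones((4, 3))), 0.4)
    assert removed2 == []


# ------------------------------------------------------------- imputation ---

def test_knn_complete_matrix_unchanged():
    rng = np.random.default_rng(1)
    m = make_matrix(rng.normal(size=(6, 4)))
    pd.testing.assert_frame_equal(knn_impute(m, k=2).values, m.values)


def test_knn_duplicate_row_k1():
    x = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, np.nan], [50.0, 60.0, 70.0]])
    out = knn_impute(make_matrix(x), k=1).values.to_numpy()
    assert out[1, 2] == 3.0  # nearest neighbor is the duplicate row


@pytest.mark.parametrize("seed", range(12))
def test_knn_matches_exhaustive_oracle(seed):
    """Random matrices up to 8x6 with up to 4 missing cells, several k."""
    rng = np.random.default_rng(seed)
    n = rng.integers(4, 9)
    p = rng.integers(2, 7)
    x = rng.normal(size=(n, p)) * rng.uniform(0.5, 3, p)
    n_miss = rng.integers(1, 5)
    idx = rng.choice(n * p, size=n_miss, replace=False)
    x.flat[idx] = np.nan
    if np.isnan(x).all(axis=0).any():
        return
    for k in (1, 2, 3):
        got = knn_impute(make_matrix(x), k=k).values.to_numpy()
        np.testing.assert_allclose(got, knn_impute_oracle(x, k), atol=1e-10)


# ------------------------------------------------------------------- LOF ---

def test_lof_uniform_grid_interior_is_inlier():
    g = np.array([[i, j] for i in range(7) for j in range(7)], float)
    scores = lof_scores(g, k=4)
    interior = [i for i, (a, b) in enumerate(g) if 1 <= a <= 5 and 1 <= b <= 5]
    assert np.all(np.abs(scores[interior] - 1.0) < 0.1)


def test_lof_planted_outlier_detected_and_matches_oracle():
    rng = np.random.default_rng(7)
    cluster = rng.normal(0, 1.0, size=(20, 2))
    radius = np.linalg.norm(cluster, axis=1).max()
    pts = np.vstack([cluster, [[10 * radius, 0.0]]])
    scores = lof_scores(pts, k=5)
    assert scores.argmax() == 20 and scores[20] > 1.5
    np.testing.assert_allclose(scores, lof_oracle(pts, 5), atol=1e-9)


@pytest.mark.parametrize("k", [3, 5, 10])
def test_lof_matches_definition_oracle_random_sets(k):
    rng = np.random.default_rng(100 + k)
    for _ in range(3):
        x = rng.normal(size=(30, 4))
        np.testing.assert_allclose(lof_scores(x, k), lof_oracle(x, k), atol=1e-9)


def test_lof_identical_points_all_inliers():
    x = np.ones((8, 3))
    np.testing.assert_allclose(lof_scores(x, k=3), 1.0, atol=1e-9)


def test_lof_removal_thresholding():
    rng = np.random.default_rng(8)
    x = np.vstack([rng.normal(0, 1, (15, 3)), [[40, 40, 40]]])
    m = make_matrix(x)
    kept, removed, scores = lof_outlier_samples(m, k=5, threshold=1.5)
    assert [s for s, _ in removed] == ["s15"]
    assert len(kept.sample_ids) == 15


# -------------------------------------------------------------- extremes ---

def test_reimpute_extremes_identity_when_clean():
    rng = np.random.default_rng(2)
    m = make_matrix(rng.normal(size=(10, 3)))
    out, count = reimpute_extremes(m, z_threshold=6.0, k=3)
    assert count == 0
    pd.testing.assert_frame_equal(out.values, m.values)


def test_reimpute_extremes_replaces_planted_spike_with_knn_value():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, size=(30, 4))
    med = np.median(x[:, 1])
    mad = np.median(np.abs(x[:, 1] - med)) * 1.4826
    x[3, 1] = med + 10 * mad
    m = make_matrix(x)
    out, count = reimpute_extremes(m, z_threshold=4.0, k=3)
    assert count == 1
    masked = x.copy()
    masked[3, 1] = np.nan
    expected = knn_impute(make_matrix(masked), k=3).values.to_numpy()[3, 1]
    assert out.values.to_numpy()[3, 1] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------- full pipeline ---

def test_pipeline_idempotent(small_study):
    ds, _ = small_study
    cfg = PipelineConfig(knn_k=5, lof_k=5)
    once, rep1 = preprocess_fluid(ds.tables["serum"], cfg)
    twice, rep2 = preprocess_fluid(once, cfg)
    assert rep2.removed_features == []
    assert rep2.removed_samples == []
    assert rep2.n_values_imputed == 0
    assert rep2.n_extreme_values_reimputed == 0
    pd.testing.assert_frame_equal(once.values, twice.values)


def test_pipeline_removes_planted_outlier_samples(small_study):
    ds, _ = small_study
    cfg = PipelineConfig(knn_k=5, lof_k=5)
    _, report = preprocess_fluid(ds.tables["serum"], cfg)
    assert report.n_samples_out <= report.n_samples_in
    assert report.n_values_imputed > 0  # MCAR missingness was injected
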