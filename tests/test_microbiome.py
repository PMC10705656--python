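import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_matrix
from crossomics import DataError
from crossomics.microbiome import (
    _AGQModel,
    bcaa_association,
    differential_ranking,
    enrichment_test,
    nb_lmm_fit,
    serum_bcaa_vector,
)


def mwu_exact_oracle(a, b):
    """Exhaustive enumeration of U over all label assignments (no ties)."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    u_obs = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        ga = pooled[list(comb)]
        gb = np.delete(pooled, list(comb))
        us.append(sum(1 for x in ga for y in gb if x > y))
    us = np.array(us)
    n2 = len(b)
    mid = n1 * n2 / 2.0
    p = np.mean(np.abs(us - mid) >= abs(u_obs - mid) - 1e-12)
    return u_obs, p


# ------------------------------------------------------------------ NB-LMM ---

def test_degenerate_limit_matches_poisson_glm():
    """sigma_u = 0, phi huge: the NB-LMM collapses to a Poisson GLM."""
    import statsmodels.api as sm

    rng = np.random.default_rng(1)
    n_subj = 40
    subj = np.repeat(np.arange(n_subj), 4)
    X = np.column_stack([np.ones(4 * n_subj), rng.integers(0, 2, 4 * n_subj).astype(float)])
    offset = np.log(rng.uniform(800, 1200, 4 * n_subj))
    y = rng.poisson(np.exp(X @ [-3.0, 0.8] + offset)).astype(float)
    fit = nb_lmm_fit(y, X, subj, offset)
    glm = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
    assert np.all(np.abs(fit["beta"] - glm.params) < 2 * glm.bse)


def test_agq_one_node_equals_laplace():
    rng = np.random.default_rng(2)
    subj = np.repeat(np.arange(10), 3)
    X = np.column_stack([np.ones(30), rng.normal(size=30)])
    y = rng.poisson(5.0, 30).astype(float)
    m = _AGQModel(y, X, subj, np.zeros(30), n_nodes=1)
    beta = np.array([1.5, 0.2])
    for sig, phi in [(0.3, 2.0), (1.0, 10.0)]:
        assert m.loglik(beta, sig, phi) == pytest.approx(
            m.laplace_loglik(beta, sig, phi), abs=1e-8
        )


def test_parameter_recovery_diet_coefficient():
    ests = []
    for rep in range(5):
        rng = np.random.default_rng(50 + rep)
        ns = 100
        subj = np.repeat(np.arange(ns), 4)
        diet = rng.integers(0, 2, 4 * ns).astype(float)
        X = np.column_stack([np.ones(4 * ns), diet])
        off = np.log(rng.uniform(5e3, 2e4, 4 * ns))
        u = rng.normal(0, 0.5, ns)
        phi = 5.0
        mu = np.exp(-6.0 + 1.0 * diet + off + u[subj])
        y = rng.negative_binomial(phi, phi / (phi + mu)).astype(float)
        fit = nb_lmm_fit(y, X, subj, off)
        ests.append(fit["beta"][1])
    assert 0.9 <= np.mean(ests) <= 1.1


def test_all_zero_feature_rejected():
    subj = np.repeat(np.arange(4), 2)
    X = np.ones((8, 1))
    with pytest.raises(DataError, match="all-zero"):
        nb_lmm_fit(np.zeros(8), X, subj)


# ----------------------------------------------------------------- ranking ---

def test_ranking_hand_computed_toy():
    """Printed counts at depth 100 reproduce hand-computed log-ratio ordering."""
    counts = make_matrix(np.array([[10.0, 10.0, 80.0], [40.0, 10.0, 50.0]]), kind="count")
    pc = 1e-6
    out = differential_ranking(counts, [True, False], pseudocount=pc)
    scores = out.set_index("feature")["score"]
    assert scores["f0"] == pytest.approx(np.log(0.10 + pc) - np.log(0.40 + pc))
    assert scores["f1"] == pytest.approx(0.0, abs=1e-12)
    assert scores["f2"] == pytest.approx(np.log(0.80 + pc) - np.log(0.50 + pc))
    assert list(out["feature"]) == ["f2", "f1", "f0"]


def test_ranking_antisymmetric_and_depth_invariant():
    rng = np.random.default_rng(3)
    x = rng.integers(0, 200, size=(12, 8)).astype(float)
    g = np.arange(12) < 6
    a = differential_ranking(make_matrix(x, kind="count"), g).set_index("feature")["score"]
    b = differential_ranking(make_matrix(x, kind="count"), ~g).set_index("feature")["score"]
    np.testing.assert_allclose(a, -b[a.index], atol=1e-12)
    scaled = x * rng.integers(1, 10, size=(12, 1))
    c = differential_ranking(make_matrix(scaled, kind="count"), g).set_index("feature")["score"]
    np.testing.assert_allclose(a, c[a.index], atol=1e-12)


# ------------------------------------------------------------- association ---

def test_monotone_species_has_rho_one():
    """A species whose clr abundance rises monotonically with BCAA gets rho = 1."""
    rng = np.random.default_rng(4)
    n = 10
    bcaa = pd.Series(np.sort(rng.uniform(1, 5, n)), index=[f"s{i}" for i in range(n)])
    # f0 strictly increasing, f1/f2 constant: clr(f0) is a monotone transform
    x = np.column_stack([
        np.round(np.exp(np.linspace(1, 5, n))),
        np.full(n, 20.0),
        np.full(n, 20.0),
    ])
    out = bcaa_association(make_matrix(x, kind="count"), bcaa)
    rho0 = out.set_index("feature").loc["f0", "rho"]
    assert rho0 == pytest.approx(1.0)


def test_constant_species_reported_missing():
    rng = np.random.default_rng(5)
    n = 8
    # identical compositions at varying depth: every clr column is constant
    x = np.outer(np.arange(1, n + 1, dtype=float), [10.0, 20.0, 30.0])
    bcaa = pd.Series(rng.uniform(1, 2, n), index=[f"s{i}" for i in range(n)])
    out = bcaa_association(make_matrix(x, kind="count"), bcaa).set_index("feature")
    assert out["rho"].isna().all()


def test_too_few_matched_samples_rejected():
    x = np.ones((4, 3))
    bcaa = pd.Series([1.0, 2.0], index=["s0", "s1"])
    with pytest.raises(DataError, match="matched"):
        bcaa_association(make_matrix(x, kind="count"), bcaa)


def test_serum_bcaa_matching_by_subject_diet_timepoint(small_study):
    ds, _ = small_study
    v = serum_bcaa_vector(ds)
    meta = ds.samples_for("stool")
    assert set(v.index) <= set(meta.index)
    sid = v.index[0]
    subj, diet, tp = meta.loc[sid, ["subject_id", "diet", "timepoint"]]
    serum_meta = ds.samples_for("serum")
    match = serum_meta[
        (serum_meta["subject_id"] == subj)
        & (serum_meta["diet"] == diet)
        & (serum_meta["timepoint"] == tp)
    ].index[0]
    expected = ds.tables["serum"].values.loc[match, "total_bcaa"]
    if np.isnan(expected):
        assert np.isnan(v[sid])
    else:
        assert v[sid] == expected


# -------------------------------------------------------------- enrichment ---

def test_mwu_example_all_pairwise_wins():
    scores = pd.Series([5.0, 6.0, 7.0, 1.0, 2.0, 3.0], index=list("abcdef"))
    flags = pd.Series([True] * 3 + [False] * 3, index=list("abcdef"))
    res = enrichment_test(scores, flags)
    assert res["U"] == 9.0
    assert res["p"] == pytest.approx(0.1)
    assert res["effect_direction"] == "flagged_higher"


@pytest.mark.parametrize("seed", range(6))
def test_mwu_matches_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    n1, n2 = rng.integers(3, 6), rng.integers(3, 6)
    vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # distinct -> no ties
    idx = [f"x{i}" for i in range(n1 + n2)]
    scores = pd.Series(vals, index=idx)
    flags = pd.Series([True] * n1 + [False] * n2, index=idx)
    res = enrichment_test(scores, flags)
    u, p = mwu_exact_oracle(vals[:n1], vals[n1:])
    assert res["U"] == pytest.approx(u)
    assert res["p"] == pytest.approx(p, abs=1e-12)


def test_mwu_shift_invariance():
    rng = np.random.default_rng(9)
    idx = [f"x{i}" for i in range(14)]
    scores = pd.Series(rng.normal(size=14), index=idx)
    flags = pd.Series(rng.random(14) < 0.5, index=idx)
    if flags.sum() < 3 or (~flags).sum() < 3:
        flags.iloc[:3] = True
        flags.iloc[-3:] = False
    r1 = enrichment_test(scores, flags)
    r2 = enrichment_test(scores + 100.0, flags)
    assert r1["U"] == r2["U"] and r1["p"] == r2["p"]
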