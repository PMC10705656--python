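"""Serum-CSF bipartite network of correlated pre/post changes.

For every subject with both draws under a diet, the delta of a feature is
value(post) - value(pre) on its transformed scale. Every (serum feature,
CSF feature) pair is tested by Pearson correlation of deltas over
pairwise-complete subjects; BH adjustment runs across all cross-compartment
pairs and edges with adjusted p below the FDR are returned. The network is
strictly bipartite: within-fluid pairs never enter the family (a
``within_fluid`` flag widens the family for sensitivity analyses).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import DataError, PipelineConfig, StudyDataset, log
from .diffabund import bh_adjust


def compute_deltas(
    dataset: StudyDataset, diet: str, fluid: str, features=None, table=None
) -> pd.DataFrame:
    """Subjects x features matrix of post - pre changes for one diet/fluid.

    ``table`` defaults to the dataset's (preprocessed) table. Subjects
    lacking either draw get NaN for that feature; ``features`` restricts to
    a significant set (empty set yields an empty matrix, logged).
    """
    table = table if table is not None else dataset.tables[fluid]
    meta = dataset.samples_for(fluid, diet)
    meta = meta[meta["timepoint"].isin(["pre", "post"])]
    meta = meta.loc[meta.index.intersection(table.values.index)]
    if features is None:
        features = list(table.values.columns)
    else:
        features = [f for f in features if f in table.values.columns]
    if not features:
        log.info("compute_deltas: empty feature set for %s/%s", fluid, diet)
        return pd.DataFrame(index=pd.Index([], name="subject_id"))
    pre_map = {
        subj: sid
        for sid, subj, tp in zip(meta.index, meta["subject_id"], meta["timepoint"])
        if tp == "pre"
    }
    post_map = {
        subj: sid
        for sid, subj, tp in zip(meta.index, meta["subject_id"], meta["timepoint"])
        if tp == "post"
    }
    subjects = sorted(set(pre_map) | set(post_map))
    out = pd.DataFrame(np.nan, index=pd.Index(subjects, name="subject_id"), columns=features)
    vals = table.values
    for s in subjects:
        if s in pre_map and s in post_map:
            out.loc[s, features] = (
                vals.loc[post_map[s], features].to_numpy(float)
                - vals.loc[pre_map[s], features].to_numpy(float)
            )
    return out


def _pearson_p(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p from the t transform t = r sqrt((n-2)/(1-r^2))."""
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    p[df < 1] = np.nan
    return p


def build_network(
    serum_d: pd.DataFrame,
    csf_d: pd.DataFrame,
    fdr: float = 0.05,
    min_pairs: int = 5,
    method: str = "pearson",
    groups: tuple[pd.Series, pd.Series] | None = None,
) -> pd.DataFrame:
    """Correlate every serum delta column against every CSF delta column.

    Returns the edges with BH-adjusted p < ``fdr`` over the
    cross-compartment family. Pairs with fewer than ``min_pairs`` complete
    subjects are skipped (not failed). ``method`` may be ``spearman``.
    """
    if method not in ("pearson", "spearman"):
        raise DataError(f"unknown correlation method {method!r}")
    subjects = serum_d.index.intersection(csf_d.index)
    sx = serum_d.loc[subjects]
    cx = csf_d.loc[subjects]
    rows = []
    s_arr, c_arr = sx.to_numpy(float), cx.to_numpy(float)
    s_ok, c_ok = ~np.isnan(s_arr), ~np.isnan(c_arr)
    complete = s_ok.all() and c_ok.all()
    if complete and method == "pearson" and len(subjects) >= max(min_pairs, 3):
        # fast path: one matrix product for all pairs
        zs = (s_arr - s_arr.mean(0)) / np.where(s_arr.std(0) > 0, s_arr.std(0), np.nan)
        zc = (c_arr - c_arr.mean(0)) / np.where(c_arr.std(0) > 0, c_arr.std(0), np.nan)
        R = zs.T @ zc / len(subjects)
        n = np.full(R.shape, len(subjects), float)
        P = _pearson_p(R, n)
        for i, sf in enumerate(sx.columns):
            for j, cf in enumerate(cx.columns):
                if np.isfinite(R[i, j]):
                    rows.append((sf, cf, R[i, j], int(n[i, j]), P[i, j]))
    else:
        rank = stats.rankdata
        for i, sf in enumerate(sx.columns):
            for j, cf in enumerate(cx.columns):
                ok = s_ok[:, i] & c_ok[:, j]
                npairs = int(ok.sum())
                if npairs < max(min_pairs, 3):
                    continue
                a, b = s_arr[ok, i], c_arr[ok, j]
                if method == "spearman":
                    a, b = rank(a), rank(b)
                if a.std() == 0 or b.std() == 0:
                    continue
                r = float(np.corrcoef(a, b)[0, 1])
                p = float(_pearson_p(np.array([r]), np.array([npairs]))[0])
                rows.append((sf, cf, r, npairs, p))
    edges = pd.DataFrame(rows, columns=["serum_feature", "csf_feature", "r", "n", "p"])
    if edges.empty:
        log.info("build_network: no testable pairs (min_pairs=%d)", min_pairs)
        edges["adj_p"] = []
        return edges
    edges["adj_p"] = bh_adjust(edges["p"].to_numpy())
    kept = edges[edges["adj_p"] < fdr].reset_index(drop=True)
    if groups is not None:
        sg, cg = groups
        kept["serum_group"] = kept["serum_feature"].map(sg)
        kept["csf_group"] = kept["csf_feature"].map(cg)
    log.info(
        "build_network: %d pairs tested, %d edges at FDR %.2f",
        len(edges), len(kept), fdr,
    )
    return kept


def to_graphml(edges: pd.DataFrame, path) -> None:
    """Export the bipartite edge list for network viewers."""
    import networkx as nx

    g = nx.Graph()
    for _, e in edges.iterrows():
        g.add_node(f"serum:{e['serum_feature']}", fluid="serum")
        g.add_node(f"csf:{e['csf_feature']}", fluid="csf")
        g.add_edge(
            f"serum:{e['serum_feature']}", f"csf:{e['csf_feature']}",
            r=float(e["r"]), adj_p=float(e["adj_p"]),
        )
    nx.write_graphml(g, path)
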