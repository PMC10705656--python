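"""Coupled CP factorization of multi-omics tensors with a shared subject mode.

Each omic is arranged as a subjects x features x time tensor (time being
the ordered diet/timepoint condition grid), clr-transformed with a
pseudocount of 1. All tensors are decomposed jointly under an approximate
CP model

    T_o[s, f, t] ~ sum_r A[s, r] * B_o[f, r] * C_o[t, r]

where the subject loading matrix A is shared across omics. Fitting is
masked alternating least squares: per-omic Khatri-Rao least squares for
B_o and C_o, one stacked weighted least-squares system for the coupled A
update, and EM-style imputation of missing entries from the current
reconstruction each sweep (which keeps the observed-data objective
non-increasing). Cross-omic feature correlations are read off the
denoised low-rank reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core_io import DataError, StudyDataset, log

#: canonical condition (diet, timepoint) order for the time mode
CONDITION_ORDER = ("MMKD_pre", "MMKD_post", "AHAD_pre", "AHAD_post")


@dataclass
class OmicsTensor:
    omic: str
    data: np.ndarray  # subjects x features x time, NaN at missing cells
    mask: np.ndarray  # True where observed
    subject_ids: list[str]
    feature_ids: list[str]
    time_ids: list[str]
    clr_applied: bool = True

    @property
    def shape(self):
        return self.data.shape


@dataclass
class JointFactorization:
    rank: int
    A: np.ndarray  # subjects x R, unit-norm columns
    B: dict[str, np.ndarray]  # omic -> features x R, unit-norm columns
    C: dict[str, np.ndarray]  # omic -> time x R, unit-norm columns
    scales: dict[str, np.ndarray]  # omic -> R component scales
    omics: list[str]
    subject_ids: list[str]
    feature_ids: dict[str, list[str]]
    time_ids: dict[str, list[str]]
    fit: dict[str, float]  # omic -> 1 - ||residual|| / ||data|| (observed cells)
    objective_trace: list = field(default_factory=list)

    def reconstruct(self, omic: str) -> np.ndarray:
        lam = self.scales[omic]
        return np.einsum("sr,fr,tr,r->sft", self.A, self.B[omic], self.C[omic], lam)


def clr_rows(x: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Row-wise centered log-ratio of non-negative data, NaN-tolerant."""
    with np.errstate(invalid="ignore", divide="ignore"):
        logged = np.log(x + pseudocount)
    center = np.nanmean(logged, axis=1, keepdims=True)
    return logged - center


def build_tensors(
    dataset: StudyDataset, omics: list[str], pseudocount: float = 1.0
) -> list[OmicsTensor]:
    """clr-transform each omic's raw table and fold it onto the condition grid.

    The subject axis is the union of subjects over the requested omics, in
    a fixed sorted order shared by every tensor; a subject missing an
    omic's draw leaves that slice masked.
    """
    subjects = sorted(
        set().union(*(
            dataset.samples[dataset.samples["fluid"] == _fluid_of(o)]["subject_id"]
            for o in omics
        ))
    )
    out = []
    for omic in omics:
        fluid = _fluid_of(omic)
        table = dataset.tables[omic]
        meta = dataset.samples_for(fluid)
        meta = meta.loc[meta.index.intersection(table.values.index)]
        conds = [
            c for c in CONDITION_ORDER
            if ((meta["diet"] + "_" + meta["timepoint"]) == c).any()
        ]
        if len(conds) < 2:
            raise DataError(f"omic {omic!r} has fewer than 2 time levels")
        S, F, T = len(subjects), len(table.features), len(conds)
        data = np.full((S, F, T), np.nan)
        clr_vals = clr_rows(table.values.to_numpy(float), pseudocount)
        sidx = {s: i for i, s in enumerate(subjects)}
        cidx = {c: i for i, c in enumerate(conds)}
        for row, (sid, subj, diet, tp) in enumerate(
            zip(meta.index, meta["subject_id"], meta["diet"], meta["timepoint"])
        ):
            cond = f"{diet}_{tp}"
            if cond in cidx and subj in sidx:
                data[sidx[subj], :, cidx[cond]] = clr_vals[table.values.index.get_loc(sid)]
        mask = ~np.isnan(data)
        out.append(
            OmicsTensor(
                omic=omic, data=data, mask=mask,
                subject_ids=subjects, feature_ids=table.features, time_ids=conds,
            )
        )
        log.info("build_tensors: %s -> %s, %.1f%% observed", omic, data.shape, 100 * mask.mean())
    return out


def _fluid_of(omic: str) -> str:
    return omic if omic in ("serum", "csf", "stool") else "stool"


def _solve_gram(gram: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve X @ gram = rhs for X, with a ridge fallback on rank deficiency."""
    try:
        cond = np.linalg.cond(gram)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        ridge = 1e-10 * max(np.trace(gram), 1.0)
        log.warning("rank-deficient Khatri-Rao system; applying ridge %.2e", ridge)
        gram = gram + ridge * np.eye(gram.shape[0])
    return np.linalg.solve(gram.T, rhs.T).T


def _als_run(tensors, rank, weights, max_iter, tol, rng):
    S = tensors[0].shape[0]
    A = np.linalg.qr(rng.normal(size=(S, rank)))[0] if S >= rank else rng.normal(size=(S, rank))
    B, C = {}, {}
    for t in tensors:
        _, F, T = t.shape
        B[t.omic] = np.linalg.qr(rng.normal(size=(F, rank)))[0] if F >= rank else rng.normal(size=(F, rank))
        C[t.omic] = np.linalg.qr(rng.normal(size=(T, rank)))[0] if T >= rank else rng.normal(size=(T, rank))

    data_norm2 = {
        t.omic: float(np.nansum(np.where(t.mask, t.data, 0.0) ** 2)) for t in tensors
    }
    total = sum(weights[t.omic] * data_norm2[t.omic] for t in tensors)

    def recon(o):
        return np.einsum("sr,fr,tr->sft", A, B[o], C[o])

    def observed_objective():
        obj = 0.0
        for t in tensors:
            res = np.where(t.mask, t.data - recon(t.omic), 0.0)
            obj += weights[t.omic] * float((res**2).sum())
        return obj

    trace = [observed_objective()]
    filled = {}
    for it in range(max_iter):
        for t in tensors:  # EM fill from the current reconstruction
            filled[t.omic] = np.where(t.mask, t.data, recon(t.omic))
        for t in tensors:
            o = t.omic
            Sd, F, T = t.shape
            Yf = filled[o].transpose(1, 0, 2).reshape(F, Sd * T)
            G = (A[:, None, :] * C[o][None, :, :]).reshape(Sd * T, rank)
            B[o] = _solve_gram((A.T @ A) * (C[o].T @ C[o]), Yf @ G)
            Yt = filled[o].transpose(2, 0, 1).reshape(T, Sd * F)
            G = (A[:, None, :] * B[o][None, :, :]).reshape(Sd * F, rank)
            C[o] = _solve_gram((A.T @ A) * (B[o].T @ B[o]), Yt @ G)
        gram = np.zeros((rank, rank))
        rhs = np.zeros((S, rank))
        for t in tensors:
            o = t.omic
            Sd, F, T = t.shape
            Ys = filled[o].reshape(Sd, F * T)
            H = (B[o][:, None, :] * C[o][None, :, :]).reshape(F * T, rank)
            gram += weights[o] * (B[o].T @ B[o]) * (C[o].T @ C[o])
            rhs += weights[o] * (Ys @ H)
        A = _solve_gram(gram, rhs)
        obj = observed_objective()
        trace.append(obj)
        if obj <= 1e-14 * max(total, 1e-300):
            break
        if abs(trace[-2] - obj) <= tol * max(trace[-2], 1e-300):
            break
    return A, B, C, trace, data_norm2


def joint_cp_fit(
    tensors: list[OmicsTensor],
    rank: int,
    weights=None,
    max_iter: int = 200,
    tol: float = 1e-8,
    seed: int = 0,
    n_restarts: int = 10,
) -> JointFactorization:
    """Fit the shared-subject-mode coupled CP model by masked ALS.

    ``weights`` default to 1/||T_o||^2 over observed cells so every omic
    contributes equally regardless of size; best of ``n_restarts`` seeded
    random orthonormal initializations is kept.
    """
    subj = tensors[0].subject_ids
    for t in tensors:
        if t.subject_ids != subj:
            raise DataError("all tensors must share the subject axis (IDs and order)")
        if rank > min(t.shape):
            raise DataError(
                f"rank {rank} exceeds a mode dimension of omic {t.omic!r} {t.shape}"
            )
        if not t.mask.any():
            raise DataError(f"omic {t.omic!r} has no observed cells")
    if weights is None:
        weights = {
            t.omic: 1.0 / max(float(np.nansum(np.where(t.mask, t.data, 0.0) ** 2)), 1e-300)
            for t in tensors
        }
    elif not isinstance(weights, dict):
        weights = {t.omic: float(w) for t, w in zip(tensors, weights)}
    if any(w <= 0 for w in weights.values()):
        raise DataError("omic weights must be positive")

    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(n_restarts):
        rng = np.random.default_rng(child)
        A, B, C, trace, data_norm2 = _als_run(tensors, rank, weights, max_iter, tol, rng)
        if best is None or trace[-1] < best[3][-1]:
            best = (A, B, C, trace, data_norm2)
    A, B, C, trace, data_norm2 = best

    # absorb magnitudes into per-omic scales; unit-norm columns everywhere
    a_norm = np.linalg.norm(A, axis=0)
    a_norm = np.where(a_norm > 0, a_norm, 1.0)
    A_u = A / a_norm
    scales, B_u, C_u, fit = {}, {}, {}, {}
    for t in tensors:
        o = t.omic
        b_norm = np.linalg.norm(B[o], axis=0)
        c_norm = np.linalg.norm(C[o], axis=0)
        b_norm = np.where(b_norm > 0, b_norm, 1.0)
        c_norm = np.where(c_norm > 0, c_norm, 1.0)
        B_u[o] = B[o] / b_norm
        C_u[o] = C[o] / c_norm
        scales[o] = a_norm * b_norm * c_norm
        res = np.where(
            t.mask,
            t.data - np.einsum("sr,fr,tr->sft", A, B[o], C[o]),
            0.0,
        )
        fit[o] = 1.0 - np.sqrt(float((res**2).sum()) / max(data_norm2[o], 1e-300))
    log.info(
        "joint_cp_fit: rank=%d, %d sweeps, objective %.3e, fits %s",
        rank, len(trace) - 1, trace[-1], {k: round(v, 4) for k, v in fit.items()},
    )
    return JointFactorization(
        rank=rank, A=A_u, B=B_u, C=C_u, scales=scales,
        omics=[t.omic for t in tensors],
        subject_ids=list(subj),
        feature_ids={t.omic: list(t.feature_ids) for t in tensors},
        time_ids={t.omic: list(t.time_ids) for t in tensors},
        fit=fit, objective_trace=trace,
    )


def select_rank(tensors, max_rank: int = 5, gain_threshold: float = 0.02, **kwargs) -> int:
    """Smallest rank whose overall-fit gain over rank-1 lower is < threshold."""
    max_rank = min(max_rank, *(min(t.shape) for t in tensors))
    fits = []
    for r in range(1, max_rank + 1):
        f = joint_cp_fit(tensors, r, **kwargs)
        fits.append(np.mean([f.fit[o] for o in f.omics]))
        if r > 1 and fits[-1] - fits[-2] < gain_threshold:
            return r - 1
    return max_rank


def cross_omic_correlations(
    fact: JointFactorization, omic_a: str, omic_b: str
) -> pd.DataFrame:
    """Pearson correlations between denoised feature profiles of two omics.

    A feature's profile is its reconstructed value over the full
    (subject, time) grid of its omic; profiles with zero variance yield NaN.
    When the two omics' time grids differ, the shared conditions are used.
    """
    shared_t = [t for t in fact.time_ids[omic_a] if t in fact.time_ids[omic_b]]
    if not shared_t:
        raise DataError("omics share no time conditions")

    def profiles(omic):
        tsel = [fact.time_ids[omic].index(t) for t in shared_t]
        rec = fact.reconstruct(omic)[:, :, tsel]  # S x F x T'
        return rec.transpose(1, 0, 2).reshape(rec.shape[1], -1)

    Pa, Pb = profiles(omic_a), profiles(omic_b)
    za = (Pa - Pa.mean(1, keepdims=True))
    zb = (Pb - Pb.mean(1, keepdims=True))
    sa = za.std(1, keepdims=True)
    sb = zb.std(1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (za / np.where(sa > 0, sa, np.nan)) @ (zb / np.where(sb > 0, sb, np.nan)).T / Pa.shape[1]
    return pd.DataFrame(R, index=fact.feature_ids[omic_a], columns=fact.feature_ids[omic_b])


def match_factors(ref: np.ndarray, est: np.ndarray) -> tuple[np.ndarray, float]:
    """Align estimated loadings to a reference up to permutation and sign.

    Returns the permuted, sign-aligned estimate and the mean column
    congruence (Tucker coefficient) after Hungarian matching.
    """
    rn = np.linalg.norm(ref, axis=0)
    en = np.linalg.norm(est, axis=0)
    phi = (ref / np.where(rn > 0, rn, 1.0)).T @ (est / np.where(en > 0, en, 1.0))
    row, col = linear_sum_assignment(-np.abs(phi))
    aligned = est[:, col] * np.sign(phi[row, col] + 1e-300)[None, :]
    return aligned, float(np.abs(phi[row, col]).mean())
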