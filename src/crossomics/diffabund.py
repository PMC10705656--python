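"""Per-feature random-intercept linear mixed models for crossover data.

Each feature (on its transformed scale) is modeled as

    y = b0 + b1*timepoint + b2*diagnosis + b3*timepoint:diagnosis
        + b4*age_centered + b5*sex + u_subject + e

with u_subject ~ N(0, sigma_u^2) and e ~ N(0, sigma_e^2), fit per diet and
per fluid by REML. The timepoint coefficient is the log2 fold change (or
clr-scale change for compositional features). Estimation profiles the REML
criterion down to a one-dimensional search over the variance ratio
lambda = sigma_u^2 / sigma_e^2 (bounded Brent on log lambda in [-12, 12]);
the GLS solve exploits the block structure of a single random intercept, so
a fit costs O(n p^2). Wald t intervals use df = n - rank(X) - (n_subjects
- 1), which reduces to the paired t-test's n_subjects - 1 in the paired
two-timepoint design.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .core_io import DataError, PipelineConfig, StudyDataset, log

TESTED_TERMS = ("timepoint", "diagnosis", "interaction")

_LOG2PI = np.log(2.0 * np.pi)


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Greedily drop columns that do not increase the design rank."""
    keep, dropped = [], []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
        else:
            dropped.append(names[j])
    return X[:, keep], [names[j] for j in keep], dropped


def fit_lmm(y: np.ndarray, X: np.ndarray, subjects: np.ndarray) -> dict:
    """REML fit of the random-intercept model y = Xb + Zu + e.

    Returns beta, se, vcov, sigma_u2, sigma_e2, reml_loglik, df, t, p,
    ci_low, ci_high (95%). A boundary fit sigma_u2 = 0 is a valid outcome.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    subjects = np.asarray(subjects)
    n, p = X.shape
    if n != len(y) or n != len(subjects):
        raise DataError("y, X and subjects must align")
    codes, _ = pd.factorize(subjects)
    order = np.argsort(codes, kind="stable")
    y, X, codes = y[order], X[order], codes[order]
    G = codes.max() + 1
    starts = np.searchsorted(codes, np.arange(G))
    n_g = np.diff(np.append(starts, n)).astype(float)
    if G < 2 or (n_g >= 2).sum() < 2:
        raise DataError("need >= 2 subjects with >= 2 observations")
    if np.linalg.matrix_rank(X) < p:
        raise DataError("singular design matrix; drop aliased columns first")

    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    Sx = np.add.reduceat(X, starts, axis=0)  # per-subject column sums
    Sy = np.add.reduceat(y, starts)

    def profile(lam: float):
        c = lam / (1.0 + n_g * lam)
        XtViX = XtX - (Sx * c[:, None]).T @ Sx
        XtViy = Xty - Sx.T @ (c * Sy)
        ytViy = yty - float(c @ (Sy**2))
        beta = np.linalg.solve(XtViX, XtViy)
        quad = max(ytViy - float(beta @ XtViy), 0.0)
        logdetV0 = float(np.sum(np.log1p(n_g * lam)))
        sign, logdetXVX = np.linalg.slogdet(XtViX)
        if quad <= 0.0:
            return -np.inf, beta, 0.0, XtViX, logdetV0
        sigma_e2 = quad / (n - p)
        crit = (n - p) * np.log(sigma_e2) + logdetV0 + logdetXVX
        return crit, beta, sigma_e2, XtViX, logdetV0

    def dcrit(lam: float) -> float:
        """Analytic derivative of the profiled REML criterion in lambda."""
        c = lam / (1.0 + n_g * lam)
        dc = 1.0 / (1.0 + n_g * lam) ** 2
        XtViX = XtX - (Sx * c[:, None]).T @ Sx
        XtViy = Xty - Sx.T @ (c * Sy)
        ytViy = yty - float(c @ (Sy**2))
        beta = np.linalg.solve(XtViX, XtViy)
        quad = max(ytViy - float(beta @ XtViy), 1e-300)
        rg = Sy - Sx @ beta  # per-subject residual sums
        dquad = -float(dc @ rg**2)
        M = np.linalg.inv(XtViX)
        dlogdetXVX = -float(dc @ np.einsum("gi,ij,gj->g", Sx, M, Sx))
        dlogdetV0 = float(np.sum(n_g / (1.0 + n_g * lam)))
        return (n - p) * dquad / quad + dlogdetV0 + dlogdetXVX

    lo, hi = np.exp(-12.0), np.exp(12.0)
    if dcrit(lo) >= 0.0:
        lam_opt = 0.0  # criterion increasing from the origin: boundary fit
    elif dcrit(hi) <= 0.0:
        lam_opt = hi
    else:
        lam_opt = float(optimize.brentq(dcrit, lo, hi, xtol=1e-14, rtol=1e-15))
    # guard against a spurious interior stationary point
    if lam_opt > 0.0 and profile(0.0)[0] < profile(lam_opt)[0]:
        lam_opt = 0.0
    crit, beta, sigma_e2, XtViX, logdetV0 = profile(lam_opt)

    degenerate = not np.isfinite(crit)
    if degenerate:  # zero residual variance (e.g. constant response)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        sigma_e2 = 0.0
        lam_opt = 0.0
        XtViX = XtX
    sigma_u2 = lam_opt * sigma_e2
    vcov = sigma_e2 * np.linalg.inv(XtViX)
    se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    df = max(n - p - (G - 1), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    pvals = np.where(se > 0, 2.0 * stats.t.sf(np.abs(t), df), 1.0)
    tcrit = stats.t.ppf(0.975, df)
    if degenerate:
        loglik = np.inf
    else:
        sign, logdetXVX = np.linalg.slogdet(XtViX)
        loglik = -0.5 * (
            (n - p) * (1.0 + _LOG2PI + np.log(sigma_e2)) + logdetV0 + logdetXVX
        )
    return {
        "beta": beta,
        "se": se,
        "vcov": vcov,
        "sigma_u2": float(sigma_u2),
        "sigma_e2": float(sigma_e2),
        "reml_loglik": float(loglik),
        "df": int(df),
        "t": t,
        "p": pvals,
        "ci_low": beta - tcrit * se,
        "ci_high": beta + tcrit * se,
        "lambda": float(lam_opt),
    }


def gls_beta_at_lambda(y, X, subjects, lam: float) -> np.ndarray:
    """Closed-form GLS coefficients at a fixed variance ratio lambda."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    codes, _ = pd.factorize(np.asarray(subjects))
    Z = np.zeros((len(y), codes.max() + 1))
    Z[np.arange(len(y)), codes] = 1.0
    V = np.eye(len(y)) + lam * Z @ Z.T
    Vi = np.linalg.inv(V)
    return np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_design(meta: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    """Fixed-effect design for one diet x fluid subset of the metadata.

    Coding: pre=0/post=1, CN=0/MCI=1, F=0/M=1; age is centered. Aliased
    columns (e.g. a constant diagnosis) are dropped with a warning.
    """
    tp = (meta["timepoint"] == "post").to_numpy(float)
    dx = (meta["diagnosis"] == "MCI").to_numpy(float)
    age = meta["age"].to_numpy(float)
    age = age - age.mean()
    sex = (meta["sex"] == "M").to_numpy(float)
    X = np.column_stack([np.ones(len(meta)), tp, dx, tp * dx, age, sex])
    names = ["intercept", "timepoint", "diagnosis", "interaction", "age", "sex"]
    Xk, kept, dropped = _drop_aliased(X, names)
    if dropped:
        log.warning("build_design: dropped aliased term(s) %s", dropped)
    return Xk, kept, dropped


def run_differential(
    dataset: StudyDataset,
    diet: str,
    fluid: str,
    config: PipelineConfig | None = None,
    table=None,
    joint_adjust: bool = False,
) -> pd.DataFrame:
    """Fit the mixed model for every feature of one fluid under one diet.

    ``table`` defaults to ``dataset.tables[fluid]`` and must already be on
    the transformed scale. BH adjustment is applied separately within each
    term family across features (jointly across terms if ``joint_adjust``).
    Significance uses the per-fluid FDR default (serum 20%, CSF 5%).
    """
    config = config or PipelineConfig()
    table = table if table is not None else dataset.tables[fluid]
    meta = dataset.samples_for(fluid, diet)
    meta = meta[meta["timepoint"].isin(["pre", "post"])]
    meta = meta.loc[meta.index.intersection(table.values.index)]
    paired = (
        meta.groupby("subject_id")["timepoint"].nunique().ge(2).sum()
    )
    if paired < 3:
        raise DataError(f"fluid {fluid!r} diet {diet!r}: fewer than 3 paired subjects")
    fdr = {"serum": config.fdr_serum, "csf": config.fdr_csf}.get(fluid, config.fdr_csf)

    X_full, names_full, _ = build_design(meta)
    subjects_full = meta["subject_id"].to_numpy()
    vals = table.values.loc[meta.index]

    rows = []
    for feat in vals.columns:
        y = vals[feat].to_numpy(float)
        ok = ~np.isnan(y)
        y_f, X_f, subj_f = y[ok], X_full[ok], subjects_full[ok]
        Xk, kept, _ = _drop_aliased(X_f, names_full) if not ok.all() else (X_f, names_full, [])
        try:
            fit = fit_lmm(y_f, Xk, subj_f)
        except DataError as exc:
            log.warning("run_differential: feature %s skipped (%s)", feat, exc)
            continue
        for term in TESTED_TERMS:
            if term not in kept:
                continue
            j = kept.index(term)
            rows.append(
                dict(
                    feature=feat, term=term, fluid=fluid,
                    estimate=fit["beta"][j], se=fit["se"][j],
                    ci_low=fit["ci_low"][j], ci_high=fit["ci_high"][j],
                    p=fit["p"][j],
                )
            )
    res = pd.DataFrame(rows)
    if res.empty:
        return pd.DataFrame(columns=[
            "feature", "term", "fluid", "estimate", "se",
            "ci_low", "ci_high", "p", "adj_p", "significant",
        ])
    if joint_adjust:
        res["adj_p"] = bh_adjust(res["p"].to_numpy())
    else:
        res["adj_p"] = np.nan
        for term in res["term"].unique():
            sel = res["term"] == term
            res.loc[sel, "adj_p"] = bh_adjust(res.loc[sel, "p"].to_numpy())
    res["significant"] = res["adj_p"] <= fdr
    log.info(
        "run_differential: %s/%s, %d features, %d significant rows at FDR %.2f",
        fluid, diet, vals.shape[1], int(res["significant"].sum()), fdr,
    )
    return res
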