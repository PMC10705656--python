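"""Count-based microbiome analysis: NB mixed models, log-ratio ranking,
and the BCAA-biosynthesis enrichment comparison.

The per-species model is a negative-binomial mixed model

    y_ij ~ NB(mu_ij, phi),  log mu_ij = x_ij' beta + offset_ij + u_i,
    u_i ~ N(0, sigma_u^2)

with a log library-size offset and a subject random intercept. The scalar
random effect is integrated out by adaptive Gauss-Hermite quadrature
(AGQ; one node reduces exactly to the Laplace approximation) and
(beta, log sigma_u, log phi) are estimated by quasi-Newton maximum
likelihood with Wald tests on beta. Fixed effects follow the crossover
design: time, dietary sequence, cognitive status, and current diet.

Feature ranking orders species by the log-ratio of mean relative
abundances between two groups (CN vs MCI, or MMKD vs AHAD), highlighting
the top and bottom ten. Species flagged as BCAA-biosynthesis encoders
(genomes carrying ilvB/ilvC/ilvD/ilvN — consumed here as a precomputed
boolean) are compared to unflagged species by a two-sided Mann-Whitney U
test on their association scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp

from .core_io import DataError, FeatureMatrix, StudyDataset, log

_LOG2PI = np.log(2.0 * np.pi)


def _nb_logpmf(y, mu, phi):
    mu = np.maximum(mu, 1e-300)
    return (
        gammaln(y + phi) - gammaln(phi) - gammaln(y + 1.0)
        + phi * np.log(phi / (phi + mu))
        + y * np.log(mu / (phi + mu))
    )


class _AGQModel:
    """Marginal NB-LMM likelihood with the random intercept integrated by AGQ."""

    def __init__(self, y, X, subjects, offset, n_nodes=15):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.offset = np.asarray(offset, float)
        codes, _ = pd.factorize(np.asarray(subjects))
        order = np.argsort(codes, kind="stable")
        self.y, self.X, self.offset = self.y[order], self.X[order], self.offset[order]
        self.codes = codes[order]
        self.G = self.codes.max() + 1
        self.starts = np.searchsorted(self.codes, np.arange(self.G))
        self.nodes, self.weights = hermgauss(n_nodes)

    def _group_sum(self, v):
        return np.add.reduceat(v, self.starts)

    def _modes(self, eta, phi, sigma2):
        """Per-subject posterior mode and curvature of the random effect."""
        y = self.y
        u = np.zeros(self.G)
        for _ in range(50):
            mu = np.exp(eta + u[self.codes])
            grad = self._group_sum(y - (y + phi) * mu / (mu + phi)) - u / sigma2
            hess = -self._group_sum((y + phi) * phi * mu / (mu + phi) ** 2) - 1.0 / sigma2
            step = grad / hess
            # damped Newton; |hess| is bounded below by 1/sigma2 so step is finite
            step = np.clip(step, -2.0, 2.0)
            u = u - step
            if np.max(np.abs(step)) < 1e-12:
                break
        mu = np.exp(eta + u[self.codes])
        hess = -self._group_sum((y + phi) * phi * mu / (mu + phi) ** 2) - 1.0 / sigma2
        return u, hess

    def loglik(self, beta, sigma_u, phi):
        sigma2 = sigma_u**2
        eta = self.X @ beta + self.offset
        u_hat, hess = self._modes(eta, phi, sigma2)
        s_hat = 1.0 / np.sqrt(-hess)
        lls = np.empty((len(self.nodes), self.G))
        for k, (xk, wk) in enumerate(zip(self.nodes, self.weights)):
            u_k = u_hat + np.sqrt(2.0) * s_hat * xk
            mu = np.exp(eta + u_k[self.codes])
            h = (
                self._group_sum(_nb_logpmf(self.y, mu, phi))
                - 0.5 * u_k**2 / sigma2
                - 0.5 * (_LOG2PI + np.log(sigma2))
            )
            lls[k] = h + xk**2 + np.log(wk)
        return float(np.sum(logsumexp(lls, axis=0) + 0.5 * np.log(2.0) + np.log(s_hat)))

    def laplace_loglik(self, beta, sigma_u, phi):
        """Laplace approximation (analytically equal to AGQ with one node)."""
        sigma2 = sigma_u**2
        eta = self.X @ beta + self.offset
        u_hat, hess = self._modes(eta, phi, sigma2)
        mu = np.exp(eta + u_hat[self.codes])
        h = (
            self._group_sum(_nb_logpmf(self.y, mu, phi))
            - 0.5 * u_hat**2 / sigma2
            - 0.5 * (_LOG2PI + np.log(sigma2))
        )
        return float(np.sum(h + 0.5 * (_LOG2PI + np.log(1.0 / -hess))))


def nb_lmm_fit(
    y, X, subjects, offset=None, n_nodes: int = 15, term_names=None
) -> dict:
    """Maximum-likelihood fit of the NB mixed model for one count feature.

    Returns beta, se, p (Wald, normal reference), sigma_u2, phi, loglik and
    a convergence flag. All-zero features raise; callers skip and log them.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if offset is None:
        offset = np.zeros(n)
    offset = np.asarray(offset, float)
    if (y < 0).any() or np.abs(y - np.round(y)).max() > 1e-9:
        raise DataError("counts must be non-negative integers")
    if y.sum() == 0:
        raise DataError("all-zero feature")
    counts_per_subject = pd.Series(subjects).value_counts()
    if (counts_per_subject < 2).any():
        raise DataError("each subject needs >= 2 observations")
    model = _AGQModel(y, X, subjects, offset, n_nodes=n_nodes)

    import statsmodels.api as sm

    glm = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
    beta0 = np.asarray(glm.params, float)
    mu0 = np.exp(X @ beta0 + offset)
    excess = max(np.mean((y - mu0) ** 2 - mu0), 1e-6)
    phi0 = float(np.clip(np.mean(mu0**2) / excess, 0.05, 1e4))

    def negloglik(theta):
        beta, ls, lp = theta[:p], theta[p], theta[p + 1]
        if not np.all(np.isfinite(theta)):
            return 1e12
        try:
            ll = model.loglik(beta, np.exp(ls), np.exp(lp))
        except FloatingPointError:
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    bounds = [(None, None)] * p + [(-6.0, 3.0), (-4.0, 14.0)]
    best = None
    for sig0 in (0.3, 1.0):
        theta0 = np.concatenate([beta0, [np.log(sig0), np.log(phi0)]])
        res = optimize.minimize(
            negloglik, theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-11},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
    res = best
    theta = res.x
    from statsmodels.tools.numdiff import approx_hess

    H = approx_hess(theta, negloglik)
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se_all = np.full(len(theta), np.nan)
    beta = theta[:p]
    se = se_all[:p]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / np.where(se > 0, se, np.nan)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return {
        "beta": beta,
        "se": se,
        "p": pvals,
        "sigma_u2": float(np.exp(theta[p]) ** 2),
        "phi": float(np.exp(theta[p + 1])),
        "loglik": float(-res.fun),
        "converged": bool(res.success),
        "term_names": list(term_names) if term_names else None,
        "model": model,
        "theta": theta,
    }


def build_count_design(meta: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Fixed effects of the crossover count model.

    Coding: time pre=0/post=1; sequence AHAD_first=0/MMKD_first=1;
    diagnosis CN=0/MCI=1; diet AHAD=0/MMKD=1 (the diet the subject is on at
    that draw).
    """
    tp = (meta["timepoint"] == "post").to_numpy(float)
    seq = (meta["sequence"] == "MMKD_first").to_numpy(float)
    dx = (meta["diagnosis"] == "MCI").to_numpy(float)
    diet = (meta["diet"] == "MMKD").to_numpy(float)
    X = np.column_stack([np.ones(len(meta)), tp, seq, dx, diet])
    return X, ["intercept", "time", "sequence", "diagnosis", "diet"]


def run_nb_differential(
    dataset: StudyDataset, omic: str = "stool", n_nodes: int = 15
) -> pd.DataFrame:
    """Fit the NB-LMM for every species; returns one row per species x term."""
    table = dataset.tables[omic]
    meta = dataset.samples_for("stool")
    meta = meta.loc[meta.index.intersection(table.values.index)]
    vals = table.values.loc[meta.index]
    offset = np.log(np.maximum(vals.sum(axis=1).to_numpy(float), 1.0))
    X, names = build_count_design(meta)
    subjects = meta["subject_id"].to_numpy()
    rows = []
    for sp in vals.columns:
        y = vals[sp].to_numpy(float)
        try:
            fit = nb_lmm_fit(y, X, subjects, offset, n_nodes=n_nodes)
        except DataError as exc:
            log.warning("run_nb_differential: %s skipped (%s)", sp, exc)
            continue
        for j, term in enumerate(names):
            if term == "intercept":
                continue
            rows.append(
                dict(
                    feature=sp, term=term, estimate=fit["beta"][j], se=fit["se"][j],
                    p=fit["p"][j], phi=fit["phi"], sigma_u2=fit["sigma_u2"],
                    converged=fit["converged"],
                )
            )
    return pd.DataFrame(rows)


def differential_ranking(
    counts: FeatureMatrix, groups, pseudocount: float = 1e-6, k: int = 10
) -> pd.DataFrame:
    """Rank features by the log-ratio of mean relative abundance between groups.

    ``groups`` is a boolean/binary vector per sample (True = group 1);
    depth rescaling per sample leaves the result unchanged.
    """
    g = np.asarray(pd.Series(groups).to_numpy()).astype(bool)
    if not g.any() or g.all():
        raise DataError("both groups must be non-empty")
    x = counts.values.to_numpy(float)
    depth = x.sum(axis=1, keepdims=True)
    rel = x / np.maximum(depth, 1e-300)
    m1 = rel[g].mean(axis=0)
    m2 = rel[~g].mean(axis=0)
    score = np.log(m1 + pseudocount) - np.log(m2 + pseudocount)
    out = pd.DataFrame({"feature": counts.features, "score": score})
    out = out.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["top_k"] = out["rank"] <= k
    out["bottom_k"] = out["rank"] > len(out) - k
    return out


def serum_bcaa_vector(dataset: StudyDataset, feature: str | None = None) -> pd.Series:
    """Raw-scale serum total-BCAA values keyed by matched stool sample IDs.

    Uses the ``total_bcaa`` serum feature if present, else the sum of
    valine + leucine + isoleucine; stool samples are matched to serum draws
    by (subject, diet, timepoint) equality.
    """
    serum = dataset.tables["serum"]
    if feature is None:
        if "total_bcaa" in serum.values.columns:
            bcaa = serum.values["total_bcaa"]
        else:
            aa = [c for c in serum.values.columns if c.lower() in ("valine", "leucine", "isoleucine")]
            if not aa:
                raise DataError("no total_bcaa feature and no valine/leucine/isoleucine columns")
            bcaa = serum.values[aa].sum(axis=1)
    else:
        bcaa = serum.values[feature]
    smeta = dataset.samples_for("serum")
    key = list(zip(smeta["subject_id"], smeta["diet"], smeta["timepoint"]))
    by_key = dict(zip(key, bcaa.loc[smeta.index]))
    tmeta = dataset.samples_for("stool")
    out = {}
    for sid, subj, diet, tp in zip(tmeta.index, tmeta["subject_id"], tmeta["diet"], tmeta["timepoint"]):
        if (subj, diet, tp) in by_key:
            out[sid] = by_key[(subj, diet, tp)]
    return pd.Series(out, name="serum_bcaa")


def bcaa_association(
    counts: FeatureMatrix, serum_bcaa: pd.Series, pseudocount: float = 1e-6
) -> pd.DataFrame:
    """Per-species Spearman correlation of clr relative abundance vs serum BCAA.

    ``serum_bcaa`` is indexed by (already matched) stool sample IDs; fewer
    than 5 matched samples is an error. Constant species yield NaN.
    """
    shared = [s for s in counts.sample_ids if s in serum_bcaa.index]
    if len(shared) < 5:
        raise DataError("fewer than 5 matched samples")
    x = counts.values.loc[shared].to_numpy(float)
    rel = x / np.maximum(x.sum(axis=1, keepdims=True), 1e-300)
    logged = np.log(rel + pseudocount)
    clr = logged - logged.mean(axis=1, keepdims=True)
    b = serum_bcaa.loc[shared].to_numpy(float)
    rows = []
    for j, sp in enumerate(counts.features):
        col = clr[:, j]
        if np.ptp(col) == 0 or np.ptp(b) == 0:
            rows.append((sp, np.nan, np.nan, len(shared)))
            continue
        rho, p = stats.spearmanr(col, b)
        rows.append((sp, float(rho), float(p), len(shared)))
    return pd.DataFrame(rows, columns=["feature", "rho", "p", "n"])


def enrichment_test(scores: pd.Series, flags: pd.Series) -> dict:
    """Two-sided Mann-Whitney U of flagged vs unflagged species' scores.

    Exact null for combined n <= 20 (no ties), normal approximation with
    tie correction otherwise.
    """
    scores = pd.Series(scores).dropna()
    flags = pd.Series(flags).reindex(scores.index)
    if flags.isna().any():
        raise DataError("every scored species needs a flag")
    a = scores[flags.astype(bool)].to_numpy(float)
    b = scores[~flags.astype(bool)].to_numpy(float)
    if len(a) < 3 or len(b) < 3:
        raise DataError("need >= 3 species per group")
    n = len(a) + len(b)
    has_ties = len(np.unique(np.concatenate([a, b]))) < n
    method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    mid = len(a) * len(b) / 2.0
    direction = "flagged_higher" if res.statistic > mid else (
        "flagged_lower" if res.statistic < mid else "none"
    )
    return {"U": float(res.statistic), "p": float(res.pvalue), "effect_direction": direction}
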