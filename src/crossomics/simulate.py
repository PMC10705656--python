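"""Synthetic crossover-study multi-omics generator with known ground truth.

Emulates the statistical structure of a two-diet crossover trial
(two 6-week diet periods separated by washout): ~20 subjects, each sampled
pre and post of each diet in serum, CSF and stool; subject random
intercepts; diet effects planted on the log2 scale for the ketogenic arm's
post-diet draws; cognitive-status (CN/MCI) effects; a compositional
percentage block that sums to 100 per sample; negative-binomial microbiome
counts with library-size variation; MCAR missingness; outlier samples; an
optional coupled low-rank subject-mode signal shared across omics; and a
latent factor tying BCAA-biosynthesis-flagged species to a serum total-BCAA
biomarker.

Effects are phenomenological log-scale shifts; no physiology is modeled.
Washout is assumed perfect (an optional carryover coefficient exists for
robustness studies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import DataError, FeatureMatrix, StudyDataset, log

#: the (diet, timepoint) condition grid each subject is sampled on
CONDITIONS = [("MMKD", "pre"), ("MMKD", "post"), ("AHAD", "pre"), ("AHAD", "post")]


@dataclass
class SimulationDesign:
    """All knobs of the generator; defaults reproduce the emulated study size."""

    n_subjects: int = 20
    frac_mci: float = 0.45
    n_serum_conc: int = 165
    n_serum_pct: int = 77
    n_csf: int = 28
    n_species: int = 200
    diet_effect_lfc: float = 1.0
    n_diet_affected: int = 20
    n_dx_affected: int = 20
    dx_effect_lfc: float = 1.0
    sigma_subject: float = 0.5
    sigma_noise: float = 0.5
    missing_rate: float = 0.02
    n_outlier_samples: int = 2
    outlier_scale: float = 6.0
    nb_dispersion: float = 5.0
    depth_lognormal_params: tuple[float, float] = (np.log(5e4), 0.5)
    coupling_rank: int = 0
    coupling_scale: float = 0.5
    frac_bcaa_flagged: float = 0.3
    bcaa_loading: float = 0.0
    dropout_rate: float = 0.0
    carryover: float = 0.0
    shared_baseline: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_serum_conc", "n_serum_pct", "n_csf", "n_species"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be non-negative")
        for name in ("frac_mci", "missing_rate", "frac_bcaa_flagged", "dropout_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DataError(f"{name} must lie in [0, 1]")
        # CSF planting is capped at the panel size; serum and stool must fit
        if self.n_diet_affected > min(self.n_serum_conc, self.n_species):
            raise DataError("n_diet_affected exceeds an omic's feature count")
        if self.n_dx_affected > self.n_serum_conc:
            raise DataError("n_dx_affected exceeds the serum panel's feature count")


@dataclass
class GroundTruth:
    """Bookkeeping of every planted effect, for confusion-matrix evaluation."""

    affected: dict[str, pd.DataFrame]  # omic -> (feature, term, true_lfc)
    subject_effects: pd.Series
    planted_factors: dict | None
    bcaa_flags: pd.Series
    planted_edges: list | None = None


def _feature_names(prefix: str, n: int, start: int = 1) -> list[str]:
    return [f"{prefix}{i:03d}" for i in range(start, start + n)]


def _subject_table(design: SimulationDesign, rng: np.random.Generator) -> pd.DataFrame:
    n = design.n_subjects
    ids = [f"S{i:02d}" for i in range(1, n + 1)]
    n_mci = int(round(design.frac_mci * n))
    dx = np.array(["MCI"] * n_mci + ["CN"] * (n - n_mci))
    rng.shuffle(dx)
    seq = np.where(rng.random(n) < 0.5, "MMKD_first", "AHAD_first")
    age = rng.uniform(55, 85, n)
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    return pd.DataFrame(
        {"diagnosis": dx, "sequence": seq, "age": age, "sex": sex},
        index=pd.Index(ids, name="subject_id"),
    )


def _log_signal(
    design, rng, subjects, features, omic, diet_idx, dx_idx,
    baselines, subj_eff, beta_age, beta_sex, coupled, g_factor, g_load,
):
    """Per-(subject, condition, feature) log-scale signal matrix (no noise)."""
    S, F = len(subjects), len(features)
    out = np.zeros((S, len(CONDITIONS), F))
    mci = (subjects["diagnosis"] == "MCI").to_numpy(float)
    age_c = subjects["age"].to_numpy() - 70.0
    sex_m = (subjects["sex"] == "M").to_numpy(float)
    for c, (diet, tp) in enumerate(CONDITIONS):
        v = (
            baselines[None, :]
            + subj_eff[:, None]
            + age_c[:, None] * beta_age[None, :]
            + sex_m[:, None] * beta_sex[None, :]
            + mci[:, None] * dx_idx[None, :] * design.dx_effect_lfc
        )
        if diet == "MMKD" and tp == "post":
            v = v + diet_idx[None, :] * design.diet_effect_lfc
        if design.carryover != 0.0 and tp == "pre":
            # residual effect of the preceding diet period for second-period pre draws
            first = subjects["sequence"].to_numpy()
            prev_mmkd = (diet == "AHAD") & (first == "MMKD_first")
            prev_mask = np.where(
                prev_mmkd if diet == "AHAD" else np.zeros(S, bool), 1.0, 0.0
            )
            v = v + design.carryover * prev_mask[:, None] * diet_idx[None, :] * design.diet_effect_lfc
        if coupled is not None:
            A, B, C = coupled
            v = v + design.coupling_scale * (A * C[c]) @ B.T
        if g_factor is not None and g_load is not None:
            v = v + g_factor[:, c, None] * g_load[None, :]
        out[:, c, :] = v
    return out


def generate_study(design: SimulationDesign) -> tuple[StudyDataset, GroundTruth]:
    """Generate one synthetic crossover study dataset and its ground truth.

    Returns raw-scale tables: serum/CSF concentration features are 2**(log2
    signal), the percentage block is a positive latent normalized to sum 100
    per sample, and stool counts are negative-binomial draws around
    depth x relative abundance.
    """
    rng = np.random.default_rng(design.seed)
    subjects = _subject_table(design, rng)
    S = design.n_subjects

    serum_conc = _feature_names("ser_c", design.n_serum_conc)
    if serum_conc:
        serum_conc[0] = "total_bcaa"  # designated serum total-BCAA biomarker
    serum_pct = _feature_names("ser_p", design.n_serum_pct)
    csf_feats = _feature_names("csf_", design.n_csf)
    species = _feature_names("sp", design.n_species)

    subj_eff = rng.normal(0.0, design.sigma_subject, S)

    # which features carry planted effects (per omic, leading features)
    def _mask(n_feat, n_aff, offset=0):
        m = np.zeros(n_feat)
        m[offset : offset + min(n_aff, n_feat - offset)] = 1.0
        return m

    # diet- and diagnosis-affected sets are disjoint so each term is identifiable
    diet_serum = _mask(design.n_serum_conc, design.n_diet_affected)
    dx_serum = _mask(design.n_serum_conc, design.n_dx_affected, design.n_diet_affected)
    diet_csf = _mask(design.n_csf, min(design.n_diet_affected, design.n_csf))
    dx_csf = _mask(design.n_csf, design.n_dx_affected, min(design.n_diet_affected, design.n_csf))
    diet_species = _mask(design.n_species, design.n_diet_affected)

    # optional coupled low-rank structure with a shared subject matrix
    planted = None
    coupled = {}
    if design.coupling_rank > 0:
        R = design.coupling_rank
        A = rng.normal(size=(S, R))
        planted = {"A": A, "B": {}, "C": {}}
        for omic, F in (("serum", design.n_serum_conc), ("csf", design.n_csf), ("stool", design.n_species)):
            B = rng.normal(size=(F, R)) / np.sqrt(F)
            C = rng.normal(size=(len(CONDITIONS), R))
            planted["B"][omic], planted["C"][omic] = B, C
            coupled[omic] = (A, B, C)
    else:
        coupled = {"serum": None, "csf": None, "stool": None}

    # BCAA latent: flagged species and the serum total-BCAA feature co-vary
    n_flag = int(round(design.frac_bcaa_flagged * design.n_species))
    bcaa_flags = pd.Series(
        [True] * n_flag + [False] * (design.n_species - n_flag), index=species, name="bcaa_biosynthesis"
    )
    g_factor = rng.normal(size=(S, len(CONDITIONS))) if design.bcaa_loading != 0.0 else None
    g_serum = np.zeros(design.n_serum_conc)
    if design.n_serum_conc:
        g_serum[0] = design.bcaa_loading
    g_species = np.where(bcaa_flags.to_numpy(), design.bcaa_loading, 0.0)

    def base(n, mu, sd):
        return rng.normal(mu, sd, n)

    signals = {}
    signals["serum_conc"] = _log_signal(
        design, rng, subjects, serum_conc, "serum", diet_serum, dx_serum,
        base(design.n_serum_conc, 5.0, 2.0), subj_eff,
        rng.normal(0, 0.005, design.n_serum_conc), rng.normal(0, 0.1, design.n_serum_conc),
        coupled["serum"], g_factor, g_serum if design.bcaa_loading else None,
    )
    signals["serum_pct"] = _log_signal(
        design, rng, subjects, serum_pct, "serum",
        np.zeros(design.n_serum_pct), np.zeros(design.n_serum_pct),
        base(design.n_serum_pct, 0.0, 1.0), subj_eff,
        rng.normal(0, 0.005, design.n_serum_pct), rng.normal(0, 0.1, design.n_serum_pct),
        None, None, None,
    )
    signals["csf"] = _log_signal(
        design, rng, subjects, csf_feats, "csf", diet_csf, dx_csf,
        base(design.n_csf, 3.0, 1.5), subj_eff,
        rng.normal(0, 0.005, design.n_csf), rng.normal(0, 0.1, design.n_csf),
        coupled["csf"], None, None,
    )
    signals["stool"] = _log_signal(
        design, rng, subjects, species, "stool", diet_species, np.zeros(design.n_species),
        base(design.n_species, 0.0, 2.0), subj_eff,
        np.zeros(design.n_species), np.zeros(design.n_species),
        coupled["stool"], g_factor, g_species if design.bcaa_loading else None,
    )

    for key in signals:
        signals[key] = signals[key] + rng.normal(0.0, design.sigma_noise, signals[key].shape)

    # assemble per-fluid sample tables over the condition grid
    meta_rows, tables = [], {}
    sample_ids = {}
    for fluid in ("serum", "csf", "stool"):
        ids = []
        for si, subj in enumerate(subjects.index):
            for diet, tp in CONDITIONS:
                sid = f"{subj}_{fluid}_{diet}_{tp}"
                ids.append(sid)
                meta_rows.append(
                    dict(
                        sample_id=sid, subject_id=subj, fluid=fluid, diet=diet,
                        timepoint=tp, sequence=subjects.loc[subj, "sequence"],
                        diagnosis=subjects.loc[subj, "diagnosis"],
                        age=subjects.loc[subj, "age"], sex=subjects.loc[subj, "sex"],
                    )
                )
        sample_ids[fluid] = ids

    def flat(sig):  # (S, C, F) -> (S*C, F) in sample-id order
        return sig.reshape(sig.shape[0] * sig.shape[1], sig.shape[2])

    conc_log = flat(signals["serum_conc"])
    pct_lat = flat(signals["serum_pct"])

    # outlier samples: all serum features shifted by outlier_scale x feature sd
    # on the log scale with a random sign per feature; the percentage block is
    # shifted on its latent scale before compositional closure
    if design.n_outlier_samples > 0 and (conc_log.shape[1] + pct_lat.shape[1]):
        out_rows = rng.choice(conc_log.shape[0], design.n_outlier_samples, replace=False)
        for blk in (conc_log, pct_lat):
            if blk.shape[1] == 0:
                continue
            sd = blk.std(axis=0, ddof=1)
            sign = rng.choice([-1.0, 1.0], blk.shape[1])
            blk[out_rows, :] += design.outlier_scale * sd * sign

    serum_vals = np.concatenate(
        [2.0 ** conc_log, _to_percent(pct_lat)], axis=1
    ) if design.n_serum_conc + design.n_serum_pct else np.zeros((S * 4, 0))
    serum_cols = serum_conc + serum_pct
    serum_meta = pd.DataFrame(
        {
            "fluid": "serum",
            "value_kind": ["concentration"] * design.n_serum_conc + ["percentage"] * design.n_serum_pct,
            "group": ["metabolite"] * design.n_serum_conc + ["lipoprotein_pct"] * design.n_serum_pct,
        },
        index=pd.Index(serum_cols, name="feature"),
    )

    csf_vals = 2.0 ** flat(signals["csf"])
    csf_meta = pd.DataFrame(
        {"fluid": "csf", "value_kind": "concentration", "group": "metabolite"},
        index=pd.Index(csf_feats, name="feature"),
    )

    # stool: NB counts around depth x softmax(latent log-abundance)
    lat = flat(signals["stool"])
    rel = np.exp(lat - lat.max(axis=1, keepdims=True))
    rel /= rel.sum(axis=1, keepdims=True)
    mu_d, sd_d = design.depth_lognormal_params
    depths = rng.lognormal(mu_d, sd_d, S * 4)
    mean = depths[:, None] * rel
    phi = design.nb_dispersion
    counts = rng.negative_binomial(phi, phi / (phi + np.maximum(mean, 1e-12))).astype(float)
    stool_meta = pd.DataFrame(
        {"fluid": "stool", "value_kind": "count", "group": "species"},
        index=pd.Index(species, name="feature"),
    )

    # MCAR missingness on the metabolite panels (after compositional closure)
    if design.missing_rate > 0:
        serum_vals[rng.random(serum_vals.shape) < design.missing_rate] = np.nan
        csf_vals[rng.random(csf_vals.shape) < design.missing_rate] = np.nan

    tables["serum"] = FeatureMatrix(
        pd.DataFrame(serum_vals, index=pd.Index(sample_ids["serum"], name="sample_id"), columns=serum_cols),
        serum_meta,
    )
    tables["csf"] = FeatureMatrix(
        pd.DataFrame(csf_vals, index=pd.Index(sample_ids["csf"], name="sample_id"), columns=csf_feats),
        csf_meta,
    )
    tables["stool"] = FeatureMatrix(
        pd.DataFrame(counts, index=pd.Index(sample_ids["stool"], name="sample_id"), columns=species),
        stool_meta,
    )

    meta = pd.DataFrame(meta_rows).set_index("sample_id")

    # optional 3-draw CSF scheme: the second diet period has no separate
    # pre draw (the study-baseline draw doubles as the first period's pre)
    if design.shared_baseline:
        drop = []
        for subj in subjects.index:
            second = "AHAD" if subjects.loc[subj, "sequence"] == "MMKD_first" else "MMKD"
            drop.append(f"{subj}_csf_{second}_pre")
        keep = [s for s in tables["csf"].sample_ids if s not in set(drop)]
        tables["csf"] = tables["csf"].subset_samples(keep)
        meta = meta.drop(index=[s for s in drop if s in meta.index])

    # optional dropout (CSF draws are the scarce fluid in practice)
    if design.dropout_rate > 0:
        keep = rng.random(len(sample_ids["csf"])) >= design.dropout_rate
        kept = [s for s, k in zip(sample_ids["csf"], keep) if k]
        tables["csf"] = tables["csf"].subset_samples(kept)
        meta = meta.drop(index=[s for s, k in zip(sample_ids["csf"], keep) if not k])

    affected = {
        "serum": _truth_frame(serum_conc, diet_serum, dx_serum, design),
        "csf": _truth_frame(csf_feats, diet_csf, dx_csf, design),
        "stool": _truth_frame(species, diet_species, np.zeros(design.n_species), design),
    }
    truth = GroundTruth(
        affected=affected,
        subject_effects=pd.Series(subj_eff, index=subjects.index, name="subject_effect"),
        planted_factors=planted,
        bcaa_flags=bcaa_flags,
    )
    ds = StudyDataset(meta, tables, truth=truth)
    log.info(
        "generate_study: seed=%d, %d subjects, tables %s",
        design.seed, S, {k: v.values.shape for k, v in tables.items()},
    )
    return ds, truth


def _to_percent(lat_log2: np.ndarray) -> np.ndarray:
    """Close a positive latent block to percentages summing to 100 per sample."""
    if lat_log2.shape[1] == 0:
        return lat_log2
    pos = 2.0 ** lat_log2
    return 100.0 * pos / pos.sum(axis=1, keepdims=True)


def _truth_frame(features, diet_mask, dx_mask, design) -> pd.DataFrame:
    rows = []
    for f, m in zip(features, diet_mask):
        if m:
            rows.append((f, "timepoint", design.diet_effect_lfc))
    for f, m in zip(features, dx_mask):
        if m:
            rows.append((f, "diagnosis", design.dx_effect_lfc))
    return pd.DataFrame(rows, columns=["feature", "term", "true_lfc"])


def truth_confusion(
    truth: GroundTruth, results: pd.DataFrame, fdr: float, omic: str = "serum"
) -> dict[str, dict]:
    """Confusion counts of a DA result table against the planted truth.

    Significance is re-derived as ``adj_p <= fdr``; counts are computed per
    model term. ``power`` is None when nothing was planted for a term.
    """
    planted = truth.affected[omic]
    out = {}
    for term, sub in results.groupby("term"):
        tested = set(sub["feature"])
        true_set = set(planted.loc[planted["term"] == term, "feature"])
        if true_set - tested:
            raise DataError(
                f"truth features missing from results for term {term!r}: "
                f"{sorted(true_set - tested)[:5]}"
            )
        rejected = set(sub.loc[sub["adj_p"] <= fdr, "feature"])
        tp = len(rejected & true_set)
        fp = len(rejected - true_set)
        fn = len(true_set - rejected)
        tn = len(tested) - tp - fp - fn
        out[term] = {
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "fdp": fp / max(1, tp + fp),
            "power": (tp / len(true_set)) if true_set else None,
        }
    return out
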