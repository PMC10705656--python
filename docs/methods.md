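# Methods

`crossomics` implements the statistical pipeline of a two-diet randomized
crossover multi-omics study: each subject completes two 6-week diet periods
(a modified Mediterranean-ketogenic diet, MMKD, and a low-fat control diet,
AHAD) separated by a washout, with serum metabolites, CSF metabolites and
stool metagenomic counts drawn pre and post of each diet. Cognitive status
(cognitively normal, CN, vs mild cognitive impairment, MCI) is a
between-subject factor. This note records the models, the defaults and the
design decisions; every empirical number it refers to is computed by the
test suite or by `scripts/acceptance.py`, never asserted from memory.

## Synthetic study generator (`simulate`)

Because participant-level data of such studies are access-controlled, all
development and testing runs on a generator that emulates the design's
statistical structure:

- **Cohort.** `n_subjects` (default 20) with `frac_mci` (default 0.45)
  labeled MCI, diet order randomized per subject; age uniform on [55, 85]
  years and sex Bernoulli(1/2), since no demographics table is available
  to emulate.
- **Metabolite panels.** Serum: 165 concentration-valued biomarkers plus a
  77-feature percentage block; CSF: 28 concentration biomarkers. Log2
  abundance of a feature is
  `baseline + subject intercept (sd sigma_subject, default 0.5)
  + diet_effect_lfc * [MMKD post, affected] + dx_effect_lfc * [MCI, affected]
  + small age/sex slopes + noise (sd sigma_noise, default 0.5)`.
  Diet- and diagnosis-affected feature sets are disjoint so each term is
  identifiable. Percentage features are a positive latent block closed to
  sum 100 per sample; closure happens before missingness so the
  compositional invariant is exact.
- **Counts.** Species relative abundances are a softmax of latent log
  abundances (with diet effects on affected species); library size is
  lognormal (default median 5x10^4, sigma 0.5) and counts are negative
  binomial with dispersion `nb_dispersion` (default 5).
- **Corruption.** MCAR missingness (default 2%) on the metabolite panels;
  `n_outlier_samples` serum samples (default 2) shifted on the log scale by
  `outlier_scale` (default 6) feature standard deviations with a random
  sign per feature — percentage outliers are shifted before closure.
- **Structure for multi-omics stages.** An optional rank-`coupling_rank`
  signal shares one subject-score matrix across omics (off by default so
  the differential-abundance stages see exchangeable replicates; switched
  on when exercising the tensor stage), and a latent factor couples
  BCAA-biosynthesis-flagged species with the serum `total_bcaa` feature at
  loading `bcaa_loading` (also off by default, for the same reason).
- **What it does not emulate.** Physiology (effects are phenomenological
  log shifts), carryover (washout is perfect unless a carryover coefficient
  is set), the real study's exact dropout pattern (a `dropout_rate` stands
  in), batch or drift artifacts, and realistic inter-feature correlation
  beyond the planted structure. Passing tests therefore demonstrate
  statistical correctness of the machinery under the design's sampling
  structure, not robustness to every artifact of real NMR or sequencing
  data.

CSF is generated at explicit pre/post per diet; a `shared_baseline` flag
can reuse the study-baseline draw as the first diet's pre to mimic a
3-draw scheme, since downstream models need pre/post pairs either way.

## Preprocessing (`preprocess`)

Fixed order: transform, filter features, impute, remove outlier samples,
re-impute extremes. Concentration features are log2-transformed (zeros
anchored at half the feature's minimum positive value, common metabolomics
practice); percentage features are clr-transformed per sample
(`y_j = ln(x_j + pc) - mean ln(x + pc)`), with pseudocount 0 by default for
platform percentages and 1 for tensor inputs. Features with missing
fraction strictly greater than 40% are removed ("over" is strict).
Imputation is k-nearest-neighbor (k = 10): distances are root mean squared
differences over columns observed in both rows on z-scored values; donors
lacking the target column are skipped in favor of the next nearest, with
the column mean as last resort. Outlier samples are flagged by the local
outlier factor (k = 10, threshold 1.5 — the method's parameters are not
published, these are conventional); reachability uses
max(k-distance, distance) so duplicate neighborhoods degenerate to
LOF = 1. Finally, values with robust z (median/MAD) above 4 are masked and
re-imputed. Transforming before imputation is a deliberate choice (the
published order is ambiguous); the pipeline is idempotent on its own
output.

## Differential abundance (`diffabund`)

Per feature, per diet, per fluid:
`y ~ timepoint * diagnosis + age + sex + (1 | subject)` with pre = 0 /
post = 1, CN = 0 / MCI = 1, F = 0 / M = 1, age centered. REML is profiled
to one dimension over `lambda = sigma_u^2 / sigma_e^2`; the optimum is
located by root-finding the analytic derivative of the profiled criterion
on `lambda in [e^-12, e^12]` (falling back to the `sigma_u^2 = 0` boundary
when the derivative is positive at the origin), which reproduces the
closed-form paired t-test to ~1e-14 in the reduced paired design. Wald t
statistics use `df = n_obs - rank(X) - (n_subjects - 1)`, which equals the
paired t's `n_subjects - 1` in that design; Satterthwaite/Kenward-Roger df
are deliberately out of scope in favor of exact oracle testability. The df
rule is mildly conservative for between-subject terms, which keeps the
type-I error at or below nominal (checked by simulation). BH adjustment is
applied within each term family (timepoint, diagnosis, interaction) across
features — consistent with reporting separate diet- and
cognition-associated counts — with a `joint_adjust` flag for a single
family. Significance thresholds default to FDR 20% for serum (many
features, few subjects) and 5% for CSF. Aliased columns (e.g. a constant
diagnosis) are dropped with a logged warning; subjects missing one draw
contribute their available observations.

## Cross-compartment network (`crossnet`)

Deltas are post minus pre per subject on the transformed scale, for the
MMKD-significant serum (FDR 20%) and CSF (FDR 5%) feature sets. Every
serum x CSF pair is scored by Pearson correlation over pairwise-complete
subjects (minimum 5 pairs; Spearman available by flag), p from the
t transform, BH across the cross-compartment family only, edge kept at
adjusted p < 5%. Within-fluid pairs are excluded from the family because
the displayed result is a bipartite graph; a flag widens the family for
sensitivity analyses.

## Coupled CP factorization (`tensorfact`)

Each omic's raw table is clr-transformed with pseudocount 1 and folded
into a subjects x features x conditions tensor; the "time" mode is the
ordered condition grid (MMKD_pre, MMKD_post, AHAD_pre, AHAD_post), which
is the natural within-subject temporal axis of a crossover design. The
model is CP with the subject loading matrix `A` shared across omics:
`T_o[s,f,t] ~ sum_r A[s,r] B_o[f,r] C_o[t,r]`. Fitting minimizes the
mask-weighted squared error `sum_o w_o ||M_o o (T_o - [[A, B_o, C_o]])||^2`
by alternating least squares: `B_o`/`C_o` solve per-omic Khatri-Rao
systems, the `A` update stacks all omics into one weighted normal-equation
system, and missing cells are refilled from the current reconstruction
once per sweep (EM), which provably keeps the observed-data objective
non-increasing. Defaults: `w_o = 1 / ||T_o||^2` so omics contribute
equally regardless of size; 10 seeded orthonormal random restarts keeping
the best objective; convergence at relative objective change below 1e-8;
ridge fallback (1e-10 x trace) on rank-deficient Gram matrices; rank
selection by a 2% elbow over ranks 1–5 (the 2–4-point time mode bounds the
useful rank). Columns are unit-normalized at the end with magnitudes in
per-omic scale vectors. Cross-omic feature correlations are Pearson
correlations of denoised profiles (the low-rank reconstruction over the
shared subject x condition grid); zero-variance profiles are reported
missing. Temporal smoothing and tensor completion per se are out of scope.

## Microbiome counts (`microbiome`)

Per species: `y_ij ~ NB(mu_ij, phi)` with
`log mu_ij = x_ij' beta + log depth_ij + u_i`, `u_i ~ N(0, sigma_u^2)`,
fixed effects time, diet sequence, cognitive status and current diet. The
scalar random effect is integrated by adaptive Gauss-Hermite quadrature
(15 nodes; the one-node rule is analytically the Laplace approximation,
which the tests exploit as an identity check), with the per-subject mode
found by damped Newton. `(beta, log sigma_u, log phi)` are maximized by
L-BFGS-B started from a Poisson GLM; standard errors come from the
numerical Hessian and Wald tests use the normal reference. This
maximum-likelihood formulation replaces posterior sampling deliberately:
the model structure is identical and every estimate is checkable against
small-sample oracles. Ranking scores each species by
`ln(mean relative abundance group1 + pc) - ln(... group2 + pc)`
(pc = 1e-6), flagging the top and bottom ten; the score is invariant to
per-sample depth rescaling. BCAA association is the Spearman correlation
between clr relative abundance and the serum total-BCAA value over samples
matched by (subject, diet, timepoint); the enrichment comparison of
flagged vs unflagged species is a two-sided Mann-Whitney U, exact for
combined n <= 20 without ties and tie-corrected normal otherwise.

## Numerical and evaluation choices

- Component comparisons across factorizations use Tucker congruence after
  Hungarian matching and sign alignment (CP is defined only up to
  permutation and sign).
- Degenerate fits are well-defined: constant responses give a zero-variance
  boundary fit with p = 1; `sigma_u^2 = 0` is a valid REML solution, not an
  error; all-zero count features are skipped and logged.
- Confusion-matrix evaluation against simulation truth uses
  `fdp = fp / max(1, tp + fp)`; power is reported missing when nothing was
  planted.
- Problem sizes in the acceptance computations (e.g. 500 null replicates of
  20 subjects x 100 features for FDR control; 200 replicates for recovery
  and coverage; 50 random instances for ALS monotonicity; 100-subject
  NB-LMM replicates) were chosen to give Monte-Carlo standard errors well
  inside the tested bands while keeping a full run in minutes on one core.

## Known limitations

- Wald-t inference with the subtractive df rule is approximate for
  unbalanced designs; it is exact in the paired case and conservative
  otherwise.
- The NB-LMM's normal-reference Wald p-values are asymptotic; no
  small-sample correction is applied.
- The coupled factorization assumes a shared subject ordering and a common
  condition grid; subjects missing an entire omic are handled by masking,
  not by omic-specific subject sets.
- The network stage tests marginal correlations only; no partial
  correlations or graphical models.
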