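# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `diatraj`. It states no
empirical result beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Study design the package targets

A three-exam prospective cohort: a baseline examination (participants aged
35–56), and two follow-ups roughly ten years apart. Incident type-2
diabetes arises between exams; subtype classification requires recent
diagnosis, so each case is classified at the first exam no more than five
years after the diagnosis ("classification exam"). All of a case's exams
are then re-indexed relative to that exam: a case classified at exam 3
contributes 20y-pre, 10y-pre and classification observations; one
classified at exam 2 contributes 10y-pre, classification and 10y-post.
Controls — participants never ascertained as diabetic by fasting glucose
≥ 126 mg/dL, 2-h post-load glucose ≥ 200 mg/dL, or a registry code — keep
their calendar exams, anchored at exam 2 so both groups share one axis.
The anchor choice is a package convention: it centres the controls on the
densest part of the case axis; any constant shift would only relabel their
cells.

## Subtype classification

Assignment is nearest-centroid in standardised feature space. Features are
age at onset [years], BMI [kg/m²], a glycemia measure, HOMA2-B [%] and
HOMA2-IR [a.u.]; the glycemia feature is HbA1c [%] in the original scheme,
fasting plasma glucose [mg/dL] in the `fpg` variant (for cohorts without
HbA1c), or absent in the `glycemia_free` variant. FPG is used raw, at the
classification exam, standardised with its own training mean/SD — no
pseudo-HbA1c conversion. GADA positivity gates assignment to SAID before
any distance is computed; insulin-based (not C-peptide-based) HOMA indices
are the accepted inputs.

Centroids can be loaded from a YAML file (for published centroid sets,
which this package does not bundle) or fitted by k-means (k = 4, Euclidean,
best of `k_means_restarts` seeded runs) on a training cohort. Fitted
clusters are mapped to names by their centres: lowest HOMA2-B → SIDD,
highest HOMA2-IR among the rest → SIRD, highest BMI among the rest → MOD,
remainder → MARD. This labelling rule is the package's own device —
reference implementations assign to *predefined* centroids — and follows
the clinical subtype definitions (beta-cell failure, insulin resistance,
obesity, mild age-related disease). Exact distance ties break in the fixed
order SIDD < SIRD < MOD < MARD so results cannot be platform-dependent;
ties are measure-zero on continuous data.

`concordance(a, b)` is the percent of identical labels in two aligned
assignments, reported to one decimal with the confusion table. The package
reports concordance per variant pair and makes no claim about which
published accuracy figure corresponds to which pair.

## HOMA indices

Glucose is converted at 18.016 mg/dL per mmol/L. The HOMA1 closed forms

    HOMA-IR = G·I / 22.5,    HOMA-B = 20·I / (G − 3.5)

(G in mmol/L, I in µU/mL ≡ mIE/L) are the internal default; HOMA-B is
undefined at G ≤ 3.5 mmol/L and such rows are flagged (NaN), never
clamped. The HOMA2 structural model is a closed-source calculator, so the
package instead (a) accepts precomputed HOMA2-B/HOMA2-IR columns in
`exams.csv` as first-class inputs that take precedence, and (b) exposes
`register_homa2_solver()` for plugging in an external implementation.
HOMA1 and HOMA2 values differ systematically (HOMA1-B runs higher in the
normal range), which matters only for comparability of absolute levels,
not for the within-cohort contrasts the pipeline estimates.

## Exclusion cascade

Rules run in the configured order; each participant is removed at most
once, and `n_input = n_clean + Σ n_removed` holds by construction.

- `missing_required_fields`: cases lacking any classification variable at
  the classification exam. Controls are not screened here; their missing
  covariates are handled complete-case at modelling time with the dropped
  count reported.
- `fpg_below_70`: hypoglycemia, FPG < 70 mg/dL — at the classification
  exam for cases, at any attended exam for controls.
- `outlier_5sd`: any outcome strictly more than 5 SD from the mean. The
  reference mean/SD is computed per outcome and exam cycle over the current
  analysis sample, *leaving the candidate out*: with the candidate
  included, the largest attainable deviation in a sample of n is
  (n−1)/√n SDs (≈ 4.25 at n = 20), so small-sample outliers could mask
  themselves. At cohort scale the two conventions are indistinguishable.
  The boundary is strict: a value at exactly 5 SD is retained.

When a diagnosis falls within five years of both exam 2 and exam 3
(possible only under irregular attendance), the earlier exam wins.

## Trajectory model

For each outcome, a linear mixed model fitted by REML (statsmodels
`MixedLM`): participant-level random intercept, homoscedastic residuals.
With at most three observations per person, random slopes are weakly
identified and are therefore opt-in (`ModelSpec(random_slope=True)`).

The group × relative-time mean structure uses **cell-means coding**: one
fixed effect per observed cell. This keeps the design full-rank despite the
structurally empty (control, 20y-pre) cell and makes the estimated marginal
means direct linear functions of the coefficients. Covariates enter with
treatment coding: examination cycle as a categorical term distinct from
relative time (it absorbs assay changes between exams — fasting glucose
platforms changed at the third exam in the kind of cohort emulated), age as
the time-varying age at observation (baseline age is collinear with exam
cycle and relative time; a baseline-age coding is available), and sex;
"model 2" adds education, smoking, family history, physical activity, BMI
(except when BMI is the outcome) and blood-pressure medication (blood
pressure outcomes only). A categorical covariate with fewer than two
observed levels is dropped with a warning and recorded in the fit. A
rank-deficient design raises an error listing the aliased columns
(identified by pivoted QR). Non-convergence is flagged on the result, not
raised. A continuous-time coding (per-group linear slopes on relative
years) is available; it cannot represent the slope break and is intended
for sensitivity checks.

**Estimated marginal means.** EMM(group, label) is the model prediction
with the cell indicator set and every covariate column at its observed
sample mean — for dummy columns that is the observed category weight, i.e.
categoricals are averaged over their empirical distribution. SEs are
delta-method: √(r'Σr) with Σ the REML fixed-effects covariance.

**Contrasts.** All C(g, 2) group pairs, per shared relative label (family =
the pairs within one label) or pooled over the labels shared by each pair —
both are implemented because discrete-time EMM comparisons can reasonably
be reported either way; output records which was used. p-values use a
normal approximation (cluster counts in the hundreds make the df refinement
immaterial; Satterthwaite df are not computed). Adjustment: Tukey via the
studentized-range distribution on q = |z|·√2 (default), Bonferroni, or
none; raw and adjusted p are always both reported, since whether published
pairwise comparisons of this kind were multiplicity-adjusted is typically
unstated.

## Descriptive tables

Continuous variables default to median [Q1, Q3] (the biomarkers are
right-skewed; mean ± SD is available), categoricals to n (%). Tests:
Mann–Whitney U (or Student/Welch t) for cases vs controls, chi-square
(Fisher's exact for sparse 2×2) for categoricals, Kruskal–Wallis across
subtypes with Dunn's post-hoc z-tests (pooled ranks, tie-corrected,
Bonferroni-adjusted; implemented in-package), and one-way ANOVA with
Dunnett's comparisons against the controls (`scipy.stats.dunnett`).

## Synthetic cohort generator

The generator emulates the *design*, not any real cohort's parameter
values. Per case group and outcome, the latent mean is piecewise linear
with the break at the classification exam:

    μ(t) = a + s_pre·(t + 20)           t ≤ 0   (t in years from classification)
    μ(t) = a + 20·s_pre + s_post·t      t > 0

with the intercept `a` anchored 20 years pre-classification; controls
follow a single calendar-time line. Each participant has one shared random
intercept per outcome, observations add iid Gaussian noise, and an SD of 0
yields the deterministic profile exactly — the basis of the noise-free
oracle tests.

Defaults follow the emulated study's printed design: subtype sizes
20/33/29/133 and 2,531 controls; exams at 0/10/20 years; baseline ages
uniform on 35–56; family-history prevalence 81.4 % (cases) and 56.3 %
(controls); 79/215 of cases classified at exam 2; diagnosis lag uniform on
[0, 5] years before the classification exam (so the five-year eligibility
rule holds at generation time); monotone dropout at 0.30 per follow-up
exam, with cases guaranteed to attend every exam up to and including their
classification exam, since that attendance is how a case enters the
analysis sample. The per-exam dropout of 0.30 matches the follow-up
non-response of the emulated design's order of magnitude; no single rate
can reproduce both full control attendance and the sparser post-
classification case data reported there.

The default trajectory profiles (in `data/default_profiles.yaml`) are
illustrative: they reproduce the qualitative orderings — SIDD highest
glucose with a post-diagnosis plateau, SIRD highest insulin and HOMA2-IR,
MOD highest BMI with an inverse-U shape, MARD mildest among cases,
controls flattest — and roughly the printed classification-exam medians
(case FPG ≈ 130 mg/dL against ≈ 83 in controls). Between- and
within-person variances are free parameters chosen at plausible
physiological magnitudes (e.g. FPG: 4 and 5 mg/dL); no real cohort states
them. Diagnoses are assigned explicitly (drawn lag) so subtype sizes are
controlled; a `threshold` mode instead triggers diagnosis at the first
exam with simulated FPG ≥ 126 mg/dL for stress-testing ascertainment.
2-h glucose is generated as a group-specific multiple of fasting glucose
plus noise; GADA positivity defaults to zero (the autoimmune cluster is
out of analysis scope) but can be raised to exercise the SAID gate.

What the generator does **not** emulate — so what passing tests do not
show about real data: skewed/lognormal biomarker distributions (Gaussian
noise means the simulated hypoglycemia exclusion fires more often than a
real right-skewed glucose distribution would), medication effects after
diagnosis, mortality and non-monotone attrition, assay drift between
exams, correlated measurement error across outcomes, and GADA titres.

## Determinism and reproducibility

All randomness flows through `numpy.random.default_rng(seed)`; draws occur
in a fixed order, so identical config + seed gives bit-identical cohorts
and, through the pipeline, a byte-identical `run_summary.json`. Replicated
experiments derive child seeds from a `SeedSequence`. The pipeline echoes
the full configuration — every threshold and toggle — into the run summary
and logs every exclusion; nothing is dropped silently.

## Validation experiment sizes

The self-validation experiments (shared by the test suite and
`scripts/acceptance.py`) use: 1,000 random vectors against random centroid
sets for the classifier-vs-oracle check; 4 × 25 noise-free blobs at 6-SD
separation for cluster recovery; 200 replicate cohorts of 400 participants
(4 × 50 cases + 200 controls, no dropout, fasting glucose, unadjusted
cell-means model) for CI coverage; 50 replicates of 200 participants for
the zero-variance check; and a quarter-scale cohort for the byte-level
determinism run. These sizes give stable Monte-Carlo estimates (coverage
SE ≈ 0.35 percentage points at 200 × 19 cells) while keeping a full run in
minutes on one core.

## Known limitations

- The bundled HOMA route is HOMA1; HOMA2 requires an external solver or
  precomputed columns.
- No imputation: covariate missingness is complete-case with logging.
- Exclusions are applied once, at cohort construction; post-classification
  exams of retained cases are not re-screened.
- The continuous-time coding cannot represent the pre/post slope break.
- Published centroid sets and standardisation constants are not bundled;
  fitted k-means centroids on the analysed cases are a stand-in whose
  labels need not match an external scheme's assignments on overlapping
  clusters.
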