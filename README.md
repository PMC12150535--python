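# diatraj

Subtype classification and diagnosis-anchored trajectory modelling of
diabetes-related health parameters in longitudinal cohorts.

## The scientific problem

Type 2 diabetes (T2D) is heterogeneous. Cluster analyses of newly diagnosed
patients distinguish four non-autoimmune subtypes — severe insulin-deficient
(SIDD), severe insulin-resistant (SIRD), mild obesity-related (MOD) and mild
age-related (MARD) diabetes — plus the GADA-positive autoimmune cluster
(SAID). A central epidemiological question is whether these subtypes already
diverge in fasting glucose, insulin, HOMA indices, BMI, waist-to-hip ratio
and blood pressure *years before* the clinical diagnosis, and how their
trajectories bend after it.

`diatraj` is a library (plus a thin `diatraj` command-line wrapper) for
researchers running that analysis on three-exam prospective cohort data —
exams roughly a decade apart, incident diagnoses arising between exams —
and for methodologists who need a fully synthetic, seeded stand-in cohort
to develop and validate against, since the real screening cohorts are
access-restricted.

## What it computes

**Classification.** A newly diagnosed individual with feature vector
x = (age at onset, BMI, glycemia, HOMA2-B, HOMA2-IR) is assigned to the
subtype k minimising the Euclidean distance in z-space,

    k* = argmin_k || (x − μ) / σ − c_k ||,

where μ, σ are standardisation constants frozen from a training cohort and
c_k the four cluster centroids; GADA-positive individuals go to SAID
outright. Three glycemia variants are supported: HbA1c (the original
scheme), fasting plasma glucose (for cohorts without HbA1c), and
glycemia-free; `concordance()` quantifies agreement between variants.
Centroids are fitted by k-means (k = 4) or loaded from file.

**Cohort construction.** OGTT/registry case ascertainment (FPG ≥ 126 mg/dL,
2-h glucose ≥ 200 mg/dL, or a registry code), the ≤ 5-year
diagnosis-to-classification-exam eligibility window, an ordered, fully
logged exclusion cascade (missing classification variables, FPG < 70 mg/dL,
outliers > 5 SD), and projection of every exam onto the relative axis
{20y-pre, 10y-pre, classification, 10y-post}.

**Trajectories.** For each outcome y, a linear mixed model fitted by REML:

    y_ij = μ(group_i, t_ij) + z_ij'γ + b_i + ε_ij,
    b_i ~ N(0, τ²),  ε_ij ~ N(0, σ²),

with a parameter per observed group × relative-time cell, covariate sets
"model 1" (exam cycle, age, sex) or "model 2" (+ education, smoking, family
history, physical activity, BMI, blood-pressure medication where relevant),
estimated marginal means per cell, and pairwise between-group contrasts
with Tukey, Bonferroni or no multiplicity adjustment. Descriptive baseline
tables come with Kruskal–Wallis/Dunn, ANOVA/Dunnett, t/Welch/Mann–Whitney
and chi-square/Fisher tests.

**Synthetic cohorts.** `simulate_cohort()` generates seeded cohorts with
piecewise-linear latent trajectories (slope break at the classification
exam), per-participant random intercepts, subtype-specific profiles,
family-history enrichment, dropout and registry flags — bit-identical under
a fixed seed.

## Worked example

```python
from diatraj import ModelSpec, SimulationConfig, fit_trajectory, \
    pairwise_contrasts, simulate_cohort
from diatraj.cohort import align_timeline_from_truth

cfg = SimulationConfig(
    n_per_subtype={"SIDD": 30, "SIRD": 30, "MOD": 30, "MARD": 30},
    n_controls=150, dropout_prob_per_exam=0.0, seed=8,
)
participants, exams = simulate_cohort(cfg)
obs = align_timeline_from_truth(participants, exams)
fit = fit_trajectory(obs, ModelSpec(outcome="fpg", adjustment="model1"))
print(fit.emm.pivot(index="group", columns="relative_label", values="emm").round(1))
```

prints the estimated marginal mean fasting glucose (mg/dL) per group and
relative time point:

```
relative_label  20y-pre  10y-pre  classification  10y-post
group
MARD               96.4    109.9           123.8     132.8
MOD                96.8    113.5           127.0     137.0
SIDD              110.7    136.2           160.7     160.5
SIRD              103.4    116.2           130.3     142.7
control             NaN     82.6            84.2      85.1
```

The insulin-deficient subtype (SIDD) already runs ~14 mg/dL above the other
subtypes twenty years before classification and flattens after it, while
controls stay near-normoglycemic throughout — the qualitative pattern the
generator encodes and the model recovers. `pairwise_contrasts(fit)` then
tests every between-group difference (e.g. SIDD − MARD at classification:
+36.9 mg/dL, SE 1.7, Tukey-adjusted p < 0.001 on this cohort).

The `examples/` directory holds one short script per capability
(simulation, HOMA indices, classification, cohort construction, trajectory
modelling, full pipeline); each prints what it computes and what the
numbers mean. The same pipeline is scriptable from the shell:

```bash
diatraj run-all --seed 42 --outdir out/       # or: simulate / classify / build / fit
diatraj validate-config --config pipeline.yaml
```

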