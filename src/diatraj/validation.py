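"""Self-validation experiments for the pipeline.

Each function runs one end-to-end check of a pipeline component against an
independent computation (brute force, generator ground truth, or an
accounting identity) on synthetic inputs, and returns plain numbers.  They
back both the test suite and the reproduction script, and are useful as
smoke checks after local modifications.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import (
    TIE_BREAK_ORDER,
    VARIANT_FEATURES,
    SubtypeCentroids,
    assign_subtype,
    classify_cohort,
    concordance,
    fit_centroids,
    separated_feature_cohort,
)
from .cohort import align_timeline_from_truth, apply_exclusions
from .simulate import SimulationConfig, case_mean, control_mean, simulate_cohort
from .trajectory import LABEL_TIMES, ModelSpec, fit_trajectory

__all__ = [
    "classifier_oracle_agreement",
    "cluster_recovery",
    "emm_coverage",
    "zero_variance_ratio",
    "exclusion_cascade_demo",
    "cell_truth",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def classifier_oracle_agreement(n_vectors: int = 1000, seed: int = 0) -> float:
    """Percent agreement between :func:`assign_subtype` and a brute-force
    nearest-centroid oracle on random feature vectors and random centroids.

    For each draw, a fresh random centroid set is built and a random
    GADA-negative feature vector assigned; the oracle recomputes all four
    z-space distances directly and takes the arg-min with the documented
    tie-break.  Returns 100.0 when the implementation is exact.
    """
    rng = np.random.default_rng(seed)
    feats = VARIANT_FEATURES["fpg"]
    p = len(feats)
    agree = 0
    for _ in range(n_vectors):
        means = rng.uniform(10, 150, p)
        sds = rng.uniform(0.5, 20, p)
        centroids = {s: rng.normal(0, 2, p) for s in TIE_BREAK_ORDER}
        cen = SubtypeCentroids(
            variant="fpg", feature_names=feats, means=means, sds=sds, centroids=centroids
        )
        x = np.abs(rng.normal(50, 40, p)) + 0.1
        res = assign_subtype(dict(zip(feats, x)), cen)
        z = (x - means) / sds
        d = {s: float(np.sqrt(((z - c) ** 2).sum())) for s, c in centroids.items()}
        best = min(d.values())
        oracle = next(s for s in TIE_BREAK_ORDER if d[s] == best)
        agree += res.subtype == oracle
    return 100.0 * agree / n_vectors


def cluster_recovery(
    n_per_subtype: int = 25,
    separation: float = 6.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[str, float]:
    """Centroid fitting + assignment on well-separated synthetic blobs.

    Returns per-variant accuracy against the generator's labels (percent)
    and the concordance between the fasting-glucose and glycemia-free
    variants on the same cohort.
    """
    feats = separated_feature_cohort(
        n_per_subtype=n_per_subtype, separation=separation, noise_sd=noise_sd, seed=seed
    )
    labels = {}
    out: dict[str, float] = {}
    for variant in ("fpg", "glycemia_free"):
        cen = fit_centroids(feats, variant=variant, seed=seed)
        assigned = classify_cohort(feats, cen)["subtype"]
        labels[variant] = assigned
        acc = 100.0 * (assigned.to_numpy() == feats["true_subtype"].to_numpy()).mean()
        out[f"accuracy_{variant}"] = float(acc)
    out["concordance_fpg_vs_glycemia_free"] = concordance(
        labels["fpg"], labels["glycemia_free"]
    )[0]
    return out


def cell_truth(cfg: SimulationConfig, group: str, outcome: str, label: str) -> float:
    """The generator's configured latent mean for one group x time cell."""
    prof = cfg.subtype_profiles[group][outcome]
    if group == "control":
        idx = {"10y-pre": 0, "classification": 1, "10y-post": 2}[label]
        return float(control_mean(prof, cfg.exam_schedule[idx]))
    return float(case_mean(prof, LABEL_TIMES[label]))


def _recovery_config(seed: int, n_per_subtype: int, n_controls: int, **kwargs):
    return SimulationConfig(
        n_per_subtype={s: n_per_subtype for s in ("SIDD", "SIRD", "MOD", "MARD")},
        n_controls=n_controls,
        dropout_prob_per_exam=0.0,
        seed=int(seed),
        **kwargs,
    )


def emm_coverage(
    n_replicates: int = 200,
    seed: int = 0,
    n_per_subtype: int = 50,
    n_controls: int = 200,
    outcome: str = "fpg",
) -> dict[str, float]:
    """Empirical 95% CI coverage of the group x time cell means.

    Each replicate simulates a cohort from known piecewise-linear profiles,
    fits the matching mixed model, and checks whether each cell's normal
    95% interval covers the generator's configured mean.  Returns the
    aggregate coverage percent and the cell count.
    """
    from scipy.stats import norm

    zcrit = float(norm.ppf(0.975))
    covered = total = 0
    for s in _child_seeds(seed, n_replicates):
        cfg = _recovery_config(s, n_per_subtype, n_controls)
        participants, exams = simulate_cohort(cfg)
        obs = align_timeline_from_truth(participants, exams)
        fit = fit_trajectory(obs, ModelSpec(outcome=outcome, adjustment="none"))
        for _, row in fit.emm.iterrows():
            truth = cell_truth(cfg, row["group"], outcome, row["relative_label"])
            covered += abs(row["emm"] - truth) <= zcrit * row["se"]
            total += 1
    return {"coverage_pct": 100.0 * covered / total, "n_cells": float(total),
            "n_replicates": float(n_replicates)}


def zero_variance_ratio(
    n_replicates: int = 50,
    seed: int = 0,
    n_per_subtype: int = 25,
    n_controls: int = 100,
    outcome: str = "fpg",
) -> float:
    """Median estimated random-intercept/residual variance ratio when the
    generator has no between-person variance (should approach zero)."""
    ratios = []
    for s in _child_seeds(seed, n_replicates):
        cfg = _recovery_config(s, n_per_subtype, n_controls)
        cfg.random_intercept_sd = {o: 0.0 for o in cfg.random_intercept_sd}
        participants, exams = simulate_cohort(cfg)
        obs = align_timeline_from_truth(participants, exams)
        fit = fit_trajectory(obs, ModelSpec(outcome=outcome, adjustment="none"))
        ratios.append(fit.vc_random / fit.vc_residual)
    return float(np.median(ratios))


def exclusion_cascade_demo() -> dict[str, float]:
    """The 20-participant worked example of the exclusion cascade.

    Twenty participants with three exams each; by construction exactly one
    violates each rule: one case is missing fasting insulin at the
    classification exam, one participant has FPG 60 mg/dL (hypoglycemia),
    and one has a BMI placed beyond 5 leave-one-out SDs of the exam-1
    sample.  Returns the accounting of the cascade.
    """
    rng = np.random.default_rng(0)
    pids = [f"C{i:02d}" for i in range(20)]
    rows = []
    for pid in pids:
        for e, t in ((1, 0.0), (2, 10.0), (3, 20.0)):
            rows.append(
                {
                    "participant_id": pid, "exam_index": e, "exam_time": t,
                    "age": 45.0 + t, "fpg": 85.0 + rng.normal(0, 3),
                    "glucose_2h": 80.0, "fasting_insulin": 10.0,
                    "bmi": 25.0 + rng.normal(0, 0.5), "whr": 0.85,
                    "sbp": 120.0 + rng.normal(0, 2), "dbp": 75.0,
                    "smoking": "never", "education": "white_collar_lower",
                    "physical_activity": "light", "bp_medication": False,
                }
            )
    exams = pd.DataFrame(rows)
    exams.loc[(exams["participant_id"] == "C01") & (exams["exam_index"] == 2),
              "fasting_insulin"] = np.nan
    exams.loc[(exams["participant_id"] == "C02") & (exams["exam_index"] == 1),
              "fpg"] = 60.0
    bmi1 = exams.loc[(exams["exam_index"] == 1) & (exams["participant_id"] != "C03"), "bmi"]
    exams.loc[(exams["participant_id"] == "C03") & (exams["exam_index"] == 1),
              "bmi"] = bmi1.mean() + 6.0 * bmi1.std(ddof=1)
    sample = pd.DataFrame(
        {"participant_id": pids, "classification_exam": [0] * 20}
    )
    sample.loc[sample["participant_id"] == "C01", "classification_exam"] = 2
    clean, log = apply_exclusions(sample, exams)
    out: dict[str, float] = {
        "n_input": float(len(sample)),
        "n_clean": float(len(clean)),
        "n_removed_total": float(log.total_removed),
        "conserved": float(len(sample) == len(clean) + log.total_removed),
    }
    for rule, n, _ in log.entries:
        out[f"removed_{rule}"] = float(n)
    return out
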