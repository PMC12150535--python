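"""End-to-end pipeline: cohort -> HOMA -> classification -> exclusions ->
timeline alignment -> trajectory models -> report.

A single :class:`PipelineConfig` (YAML-serialisable) parameterises a run;
every threshold (5-year eligibility window, 70 mg/dL hypoglycemia cut-off,
5-SD outlier rule, classifier variant) is echoed into the run summary so a
run is auditable from its outputs alone.  Identical config + seed produces a
byte-identical ``run_summary.json``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._errors import ConfigurationError, DiatrajError
from . import io as io_mod
from .classify import (
    SubtypeCentroids,
    classify_cohort,
    fit_centroids,
    load_centroids,
    save_centroids,
)
from .cohort import EXCLUSION_RULES, ExclusionLog, align_timeline, apply_exclusions, \
    select_controls, select_incident_cases
from .descriptives import descriptive_table
from .homa import homa_columns
from .simulate import SimulationConfig, simulate_cohort
from .trajectory import SUPPORTED_OUTCOMES, ModelSpec, fit_trajectory, pairwise_contrasts

logger = logging.getLogger("diatraj")

CONTINUOUS_TABLE_VARS = (
    "age", "bmi", "whr", "fpg", "glucose_2h", "fasting_insulin", "homa_b", "homa_ir",
)
CATEGORICAL_TABLE_VARS = ("fhd", "sex", "smoking", "education", "physical_activity")


@dataclass
class PipelineConfig:
    """Full parameterisation of one pipeline run."""

    mode: str = "simulate"                     # "simulate" | "files"
    cohort_path: str | None = None             # required in files mode
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    variant: str = "fpg"
    centroid_file: str | None = None           # None -> fit k-means on the cases
    k_means_restarts: int = 10
    exclusion_rules: tuple[str, ...] = EXCLUSION_RULES
    exclude_fhd: bool = False
    outcomes: tuple[str, ...] = SUPPORTED_OUTCOMES
    adjustments: tuple[str, ...] = ("model1", "model2")
    contrast_adjustment: str = "tukey"
    time_coding: str = "categorical_label"
    out_dir: str = "diatraj_output"
    seed: int = 0
    log_level: str = "INFO"
    make_plots: bool = True

    def validate(self) -> list[str]:
        """Full schema check; returns a list of human-readable errors."""
        errors: list[str] = []
        if self.mode not in ("simulate", "files"):
            errors.append(f"mode: must be 'simulate' or 'files', got {self.mode!r}")
        if self.mode == "files":
            if not self.cohort_path:
                errors.append("cohort_path: required in files mode")
            else:
                p = Path(self.cohort_path)
                for f in ("participants.csv", "exams.csv"):
                    if not (p / f).exists():
                        errors.append(f"cohort_path: missing {p / f}")
        if self.mode == "simulate":
            try:
                self.simulation.validate()
            except ConfigurationError as exc:
                errors.append(f"simulation: {exc}")
        if self.variant not in ("hba1c", "fpg", "glycemia_free"):
            errors.append(f"variant: unknown variant {self.variant!r}")
        if self.centroid_file and not Path(self.centroid_file).exists():
            errors.append(f"centroid_file: no such file {self.centroid_file!r}")
        bad = [r for r in self.exclusion_rules if r not in EXCLUSION_RULES]
        if bad:
            errors.append(f"exclusion_rules: unknown rule(s) {bad}; allowed {list(EXCLUSION_RULES)}")
        bad = [o for o in self.outcomes if o not in SUPPORTED_OUTCOMES]
        if bad:
            errors.append(f"outcomes: unsupported {bad}; allowed {list(SUPPORTED_OUTCOMES)}")
        bad = [a for a in self.adjustments if a not in ("model1", "model2")]
        if bad:
            errors.append(f"adjustments: unknown {bad}; allowed ['model1', 'model2']")
        if self.contrast_adjustment not in ("tukey", "bonferroni", "none"):
            errors.append(f"contrast_adjustment: unknown {self.contrast_adjustment!r}")
        if self.time_coding not in ("categorical_label", "continuous_years"):
            errors.append(f"time_coding: unknown {self.time_coding!r}")
        if not isinstance(self.seed, int) or self.seed < 0:
            errors.append(f"seed: must be a non-negative integer, got {self.seed!r}")
        return errors


def _config_to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _config_to_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _config_to_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_config_to_dict(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config from YAML (missing keys take defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    sim_raw = raw.pop("simulation", None)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown config key(s): {sorted(unknown)}")
    cfg = PipelineConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
    if sim_raw:
        sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
        unknown = set(sim_raw) - sim_known
        if unknown:
            raise ConfigurationError(f"{path}: unknown simulation key(s): {sorted(unknown)}")
        from .simulate import OutcomeProfile

        if "subtype_profiles" in sim_raw:
            sim_raw["subtype_profiles"] = {
                g: {o: OutcomeProfile(**p) for o, p in outs.items()}
                for g, outs in sim_raw["subtype_profiles"].items()
            }
        for key in ("exam_schedule", "baseline_age_range", "diagnosis_lag_range"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        cfg.simulation = SimulationConfig(**sim_raw)
    return cfg


def validate_config(path: str | Path) -> list[str]:
    """Schema-check a YAML config without executing; [] means OK."""
    try:
        cfg = load_config(path)
    except (ConfigurationError, OSError, yaml.YAMLError) as exc:
        return [str(exc)]
    return cfg.validate()


def with_homa(exams: pd.DataFrame) -> pd.DataFrame:
    """Exam table with ``homa_b``/``homa_ir`` columns.

    Precomputed columns (e.g. from the structural-model calculator) are kept
    as-is; otherwise the HOMA1 closed forms fill them in, with out-of-domain
    rows left as NaN (flagged, never clamped).
    """
    out = exams.copy()
    if "homa_b" in out.columns and "homa_ir" in out.columns:
        return out
    hb, hir = homa_columns(out["fpg"], out["fasting_insulin"])
    out["homa_b"], out["homa_ir"] = hb, hir
    return out


def classification_features(
    cases: pd.DataFrame, exams: pd.DataFrame
) -> pd.DataFrame:
    """Feature table for the classifier, one row per eligible case.

    Features are taken at the classification exam; age at onset is the age
    at the diagnosis date (baseline age + diagnosis time).
    """
    ex = exams.set_index(["participant_id", "exam_index"])
    rows = []
    for _, c in cases.iterrows():
        key = (c["participant_id"], int(c["classification_exam"]))
        if key not in ex.index:
            continue
        r = ex.loc[key]
        rows.append(
            {
                "participant_id": c["participant_id"],
                "gada_positive": bool(c.get("gada_positive", False)),
                "classification_exam": int(c["classification_exam"]),
                "diagnosis_to_exam_years": float(c["diagnosis_to_exam_years"]),
                "age_at_onset": float(c["baseline_age"]) + float(c["diagnosis_time"]),
                "bmi": float(r["bmi"]),
                "fpg": float(r["fpg"]),
                "homa_b": float(r["homa_b"]),
                "homa_ir": float(r["homa_ir"]),
            }
        )
    return pd.DataFrame(rows)


def build_analysis_cohort(
    participants: pd.DataFrame,
    exams: pd.DataFrame,
    variant: str = "fpg",
    centroids: SubtypeCentroids | None = None,
    exclusion_rules=EXCLUSION_RULES,
    exclude_fhd: bool = False,
    k_means_restarts: int = 10,
    seed: int = 0,
) -> dict:
    """Run ascertainment, exclusions, classification and timeline alignment.

    Returns a dict with ``cases`` (classified), ``controls``, ``observations``
    (aligned, with HOMA columns), ``centroids``, ``exclusion_log`` and
    ``n_said`` (GADA-positive cases set aside before trajectory modelling).
    """
    exams = with_homa(exams)
    cases, elig_log = select_incident_cases(participants, exams)
    controls = select_controls(participants, exams, exclude_fhd=exclude_fhd)
    logger.info("eligible cases: %d; controls: %d", len(cases), len(controls))

    controls = controls.copy()
    controls["classification_exam"] = 0
    sample = pd.concat([cases, controls], ignore_index=True)
    clean, excl_log = apply_exclusions(sample, exams, rules=exclusion_rules)
    log = ExclusionLog(entries=elig_log.entries + excl_log.entries)
    for rule, n, _ in log.entries:
        logger.info("excluded %d participant(s) under rule %s", n, rule)

    clean_class = clean["classification_exam"].fillna(0).astype(int)
    clean_cases = clean[clean_class > 0]
    clean_controls = clean[clean_class == 0]

    feats = classification_features(clean_cases, exams)
    gada_neg = feats[~feats["gada_positive"]]
    if centroids is None:
        centroids = fit_centroids(
            gada_neg, variant=variant, k_means_restarts=k_means_restarts, seed=seed
        )
    classified = classify_cohort(feats, centroids)
    n_said = int((classified["subtype"] == "SAID").sum())
    classified_t2d = classified[classified["subtype"] != "SAID"]

    cases_final = clean_cases.merge(
        classified_t2d[["participant_id", "subtype"]], on="participant_id", how="inner"
    )
    obs = align_timeline(cases_final, clean_controls, exams)
    return {
        "cases": cases_final,
        "controls": clean_controls,
        "classified": classified,
        "features": feats,
        "observations": obs,
        "centroids": centroids,
        "exclusion_log": log,
        "n_said": n_said,
    }


def _baseline_table_input(result: dict, exams: pd.DataFrame) -> pd.DataFrame:
    """One row per participant: cases at their classification exam, controls
    at the baseline exam (the conventional descriptive-table anchors)."""
    exams = with_homa(exams)
    ex = exams.set_index(["participant_id", "exam_index"])
    rows = []
    for df, exam_of in (
        (result["cases"], lambda c: int(c["classification_exam"])),
        (result["controls"], lambda c: 1),
    ):
        for _, p in df.iterrows():
            key = (p["participant_id"], exam_of(p))
            if key not in ex.index:
                continue
            r = ex.loc[key].to_dict()
            r["participant_id"] = p["participant_id"]
            r["group"] = p.get("subtype", "control") if "subtype" in df.columns else "control"
            r["fhd"] = p["fhd"]
            r["sex"] = p["sex"]
            rows.append(r)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all outputs under ``config.out_dir``.

    Returns the machine-readable run summary (also written as
    ``run_summary.json``).  Any stage failure is logged with its stage name
    and re-raised.
    """
    errors = config.validate()
    if errors:
        raise ConfigurationError("; ".join(errors))
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "input"
    try:
        if config.mode == "simulate":
            sim = replace(config.simulation, seed=config.seed)
            participants, exams = simulate_cohort(sim)
        else:
            participants, exams = io_mod.read_cohort(config.cohort_path)
        io_mod.write_cohort(participants, exams, out / "cohort")

        stage = "cohort_build"
        centroids = load_centroids(config.centroid_file) if config.centroid_file else None
        result = build_analysis_cohort(
            participants,
            exams,
            variant=config.variant,
            centroids=centroids,
            exclusion_rules=config.exclusion_rules,
            exclude_fhd=config.exclude_fhd,
            k_means_restarts=config.k_means_restarts,
            seed=config.seed,
        )
        save_centroids(result["centroids"], out / "centroids.yaml")
        result["classified"].to_csv(out / "classification.csv", index=False, na_rep="NA")
        result["exclusion_log"].to_frame().to_csv(out / "exclusions.csv", index=False)
        result["observations"].to_csv(out / "observations.csv", index=False, na_rep="NA")

        stage = "descriptives"
        baseline = _baseline_table_input(result, exams)
        desc = descriptive_table(
            baseline, continuous=CONTINUOUS_TABLE_VARS, categorical=CATEGORICAL_TABLE_VARS
        )
        desc["summary"].to_csv(out / "descriptive_table.csv", index=False)
        desc["tests"].to_csv(out / "descriptive_tests.csv", index=False)

        stage = "trajectories"
        obs = result["observations"]
        convergence: dict[str, bool] = {}
        for outcome in config.outcomes:
            for adj in config.adjustments:
                spec = ModelSpec(outcome=outcome, adjustment=adj, time_coding=config.time_coding)
                fit = fit_trajectory(obs, spec)
                convergence[f"{outcome}:{adj}"] = fit.converged
                tag = f"{outcome}_{adj}"
                coef = pd.DataFrame({"term": fit.params.index, "estimate": fit.params.values,
                                     "se": fit.bse.values})
                coef.to_csv(out / f"coefficients_{tag}.csv", index=False)
                fit.emm.to_csv(out / f"emm_{tag}.csv", index=False)
                contrasts = pairwise_contrasts(fit, config.contrast_adjustment)
                contrasts.to_csv(out / f"contrasts_{tag}.csv", index=False)
                if config.make_plots and adj == config.adjustments[-1]:
                    _plot_emm(fit, out / f"trajectory_{tag}.svg")

        stage = "summary"
        subtype_counts = result["cases"]["subtype"].value_counts().to_dict()
        summary = {
            "config": _config_to_dict(config),
            "n_participants_input": int(len(participants)),
            "n_eligible_cases": int(len(result["cases"])),
            "n_controls": int(len(result["controls"])),
            "n_said_set_aside": result["n_said"],
            "subtype_counts": {k: int(subtype_counts.get(k, 0)) for k in
                               ("SIDD", "SIRD", "MOD", "MARD")},
            "exclusions": [
                {"rule": r, "n_removed": int(n)} for r, n, _ in result["exclusion_log"].entries
            ],
            "n_observations": int(len(obs)),
            "model_convergence": convergence,
            "contrast_adjustment": config.contrast_adjustment,
        }
        (out / "run_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        return summary
    except DiatrajError:
        logger.error("pipeline failed at stage %r", stage)
        raise


def _plot_emm(fit, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .cohort import RELATIVE_LABELS

    fig, ax = plt.subplots(figsize=(6, 4))
    for g, sub in fit.emm.groupby("group"):
        sub = sub.set_index("relative_label").reindex(
            [l for l in RELATIVE_LABELS if l in set(sub["relative_label"])]
        )
        x = [RELATIVE_LABELS.index(l) for l in sub.index]
        ax.errorbar(x, sub["emm"], yerr=sub["se"], marker="o", capsize=3, label=g)
    ax.set_xticks(range(len(RELATIVE_LABELS)))
    ax.set_xticklabels(RELATIVE_LABELS, rotation=20)
    ax.set_ylabel(fit.spec.outcome)
    ax.set_title(f"{fit.spec.outcome} ({fit.spec.adjustment}) — estimated marginal means")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
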