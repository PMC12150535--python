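"""Seeded synthetic longitudinal cohort generator.

Emulates the design of a three-exam prospective diabetes-prevention cohort:
participants aged 35–56 at baseline, re-examined roughly every ten years,
enriched for family history of diabetes, with incident type-2-diabetes
diagnoses arising between exams and attrition over follow-up.

Latent biomarker trajectories are piecewise linear.  For a case, each
outcome's mean is

    mu(t) = intercept + slope_pre * (t_rel + 20)          for t_rel <= 0
    mu(t) = mu(0)     + slope_post * t_rel                for t_rel > 0

where ``t_rel`` is time relative to the classification exam (the first exam
at or after diagnosis) and the intercept is anchored 20 years before it.
Controls follow a single line on calendar time.  Each participant carries one
shared random intercept per outcome; observations add iid Gaussian residual
noise.  Identical config + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from ._errors import ConfigurationError

#: Directly simulated outcomes (HOMA indices are derived downstream).
OUTCOMES = ("fpg", "fasting_insulin", "bmi", "whr", "sbp", "dbp")

#: The four non-autoimmune diabetes subtypes.
SUBTYPES = ("SIDD", "SIRD", "MOD", "MARD")

GROUPS = SUBTYPES + ("control",)

SMOKING_LEVELS = ("current", "former", "never")
EDUCATION_LEVELS = (
    "blue_collar_unskilled",
    "blue_collar_skilled",
    "white_collar_lower",
    "white_collar_middle",
    "white_collar_higher",
    "self_employed",
    "other",
)
ACTIVITY_LEVELS = ("sedentary", "light", "moderate", "moderate_vigorous")

# Marginal covariate distributions for cases vs controls (approximate
# frequencies for a middle-aged Scandinavian screening cohort).
_COVARIATE_PROBS = {
    "case": {
        "female": 0.437,
        "smoking": (0.084, 0.549, 0.367),
        "education": (0.144, 0.144, 0.302, 0.167, 0.149, 0.093, 0.001),
        "physical_activity": (0.116, 0.516, 0.247, 0.121),
        "bp_medication": 0.30,
    },
    "control": {
        "female": 0.609,
        "smoking": (0.195, 0.378, 0.427),
        "education": (0.045, 0.093, 0.295, 0.175, 0.187, 0.197, 0.008),
        "physical_activity": (0.090, 0.503, 0.320, 0.087),
        "bp_medication": 0.12,
    },
}


@dataclass(frozen=True)
class OutcomeProfile:
    """Piecewise-linear latent mean for one outcome in one group."""

    intercept: float
    slope_pre: float
    slope_post: float

    def mean_at(self, t_rel: float) -> float:
        """Latent mean at time ``t_rel`` relative to classification (cases)."""
        if t_rel <= 0:
            return self.intercept + self.slope_pre * (t_rel + 20.0)
        return self.intercept + self.slope_pre * 20.0 + self.slope_post * t_rel


from functools import lru_cache


@lru_cache(maxsize=1)
def _load_defaults() -> dict:
    with resources.files("diatraj.data").joinpath("default_profiles.yaml").open() as fh:
        return yaml.safe_load(fh)


def default_profiles() -> dict[str, dict[str, OutcomeProfile]]:
    """The packaged default latent profiles, as ``{group: {outcome: profile}}``."""
    raw = _load_defaults()["profiles"]
    return {
        g: {o: OutcomeProfile(**raw[g][o]) for o in OUTCOMES} for g in GROUPS
    }


@dataclass
class SimulationConfig:
    """Full parameterisation of one synthetic cohort.

    Defaults reproduce the study design the generator emulates: subtype
    sample sizes 20/33/29/133, 2531 controls, exams at 0/10/20 years,
    baseline ages 35–56, family-history prevalence 81.4% in cases and 56.3%
    in controls, and ~37% of cases reaching their classification exam at the
    second examination cycle.
    """

    n_per_subtype: dict[str, int] = field(
        default_factory=lambda: {"SIDD": 20, "SIRD": 33, "MOD": 29, "MARD": 133}
    )
    n_controls: int = 2531
    fhd_prevalence_cases: float = 0.814
    fhd_prevalence_controls: float = 0.563
    exam_schedule: tuple[float, float, float] = (0.0, 10.0, 20.0)
    baseline_age_range: tuple[float, float] = (35.0, 56.0)
    subtype_profiles: dict[str, dict[str, OutcomeProfile]] = field(
        default_factory=default_profiles
    )
    random_intercept_sd: dict[str, float] = field(
        default_factory=lambda: dict(_load_defaults()["random_intercept_sd"])
    )
    residual_sd: dict[str, float] = field(
        default_factory=lambda: dict(_load_defaults()["residual_sd"])
    )
    dropout_prob_per_exam: float = 0.30
    diagnosis_lag_range: tuple[float, float] = (0.0, 5.0)
    seed: int = 0
    # fraction of cases whose classification exam is exam 2 (vs exam 3)
    p_classified_exam2: float = 79.0 / 215.0
    # fraction of case diagnoses carrying a registry flag
    registry_fraction: float = 0.2
    gada_positive_rate: float = 0.0
    monotone_dropout: bool = True
    # "explicit": diagnosis drawn from diagnosis_lag_range;
    # "threshold": diagnosis at the first exam with simulated FPG >= 126 mg/dL
    diagnosis_mode: str = "explicit"
    glucose_2h_missing_prob: float = 0.0

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the first invalid field."""
        for name, p in [
            ("fhd_prevalence_cases", self.fhd_prevalence_cases),
            ("fhd_prevalence_controls", self.fhd_prevalence_controls),
            ("dropout_prob_per_exam", self.dropout_prob_per_exam),
            ("p_classified_exam2", self.p_classified_exam2),
            ("registry_fraction", self.registry_fraction),
            ("gada_positive_rate", self.gada_positive_rate),
            ("glucose_2h_missing_prob", self.glucose_2h_missing_prob),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")
        if set(self.n_per_subtype) != set(SUBTYPES):
            raise ConfigurationError(
                f"n_per_subtype must have keys {SUBTYPES}, got {sorted(self.n_per_subtype)}"
            )
        for s, n in self.n_per_subtype.items():
            if n < 0 or int(n) != n:
                raise ConfigurationError(f"n_per_subtype[{s}] must be a count >= 0, got {n}")
        if self.n_controls < 0 or int(self.n_controls) != self.n_controls:
            raise ConfigurationError(f"n_controls must be a count >= 0, got {self.n_controls}")
        sched = tuple(self.exam_schedule)
        if len(sched) != 3 or any(b <= a for a, b in zip(sched, sched[1:])):
            raise ConfigurationError(
                f"exam_schedule must be three strictly increasing offsets, got {sched}"
            )
        lo, hi = self.baseline_age_range
        if not lo < hi:
            raise ConfigurationError(f"baseline_age_range must be increasing, got {self.baseline_age_range}")
        llo, lhi = self.diagnosis_lag_range
        if not (0.0 <= llo <= lhi <= 5.0):
            raise ConfigurationError(
                f"diagnosis_lag_range must be within [0, 5], got {self.diagnosis_lag_range}"
            )
        if sched[1] - lhi <= sched[0]:
            raise ConfigurationError(
                "diagnosis_lag_range upper bound reaches back to or before the baseline "
                "exam; diagnoses must fall strictly after exam 1"
            )
        for g in GROUPS:
            if g not in self.subtype_profiles:
                raise ConfigurationError(f"subtype_profiles missing group {g!r}")
            for o in OUTCOMES:
                if o not in self.subtype_profiles[g]:
                    raise ConfigurationError(f"subtype_profiles[{g!r}] missing outcome {o!r}")
        for o in OUTCOMES:
            if self.residual_sd.get(o, -1.0) < 0:
                raise ConfigurationError(f"residual_sd[{o!r}] must be >= 0")
            if self.random_intercept_sd.get(o, -1.0) < 0:
                raise ConfigurationError(f"random_intercept_sd[{o!r}] must be >= 0")
        if self.diagnosis_mode not in ("explicit", "threshold"):
            raise ConfigurationError(
                f"diagnosis_mode must be 'explicit' or 'threshold', got {self.diagnosis_mode!r}"
            )
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ConfigurationError(f"seed must be a non-negative integer, got {self.seed!r}")

    def scaled(self, factor: float) -> "SimulationConfig":
        """A copy with all sample sizes multiplied by ``factor`` (min 2 per group)."""
        return replace(
            self,
            n_per_subtype={s: max(2, round(n * factor)) for s, n in self.n_per_subtype.items()},
            n_controls=max(2, round(self.n_controls * factor)),
        )


def noise_free(config: SimulationConfig) -> SimulationConfig:
    """A copy of ``config`` with all between/within-person noise removed.

    With zero SDs the generator emits the deterministic latent mean profiles
    exactly (an SD of 0 produces exact zeros, not tiny Gaussian draws).
    """
    return replace(
        config,
        residual_sd={o: 0.0 for o in OUTCOMES},
        random_intercept_sd={o: 0.0 for o in OUTCOMES},
    )


def _normal(rng: np.random.Generator, sd: float, size) -> np.ndarray:
    # rng.normal(scale=0) is valid and returns zeros, but skipping the draw
    # would change the stream; always draw to keep seed alignment comparable
    # across noise settings of the same shape.
    return rng.normal(0.0, sd, size) if sd > 0 else np.zeros(size)


def case_mean(profile: OutcomeProfile, t_rel) -> np.ndarray:
    """Vectorised piecewise-linear case mean at relative time ``t_rel``."""
    t = np.asarray(t_rel, dtype=float)
    at_class = profile.intercept + profile.slope_pre * 20.0
    return np.where(
        t <= 0,
        profile.intercept + profile.slope_pre * (t + 20.0),
        at_class + profile.slope_post * t,
    )


def control_mean(profile: OutcomeProfile, t) -> np.ndarray:
    """Control latent mean on calendar time (baseline anchor, single slope)."""
    return profile.intercept + profile.slope_pre * np.asarray(t, dtype=float)


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic cohort.

    Returns
    -------
    participants : DataFrame
        One row per participant: ``participant_id, group (generator truth),
        sex, fhd, gada_positive, baseline_age, diagnosis_time,
        diagnosed_via_registry, classification_exam, exams_attended``.
        ``diagnosis_time`` is NaN for controls; ``exams_attended`` is a
        string such as ``"1|2|3"``.
    exams : DataFrame
        One row per attended participant-exam with the biomarkers and
        covariates (see :data:`OUTCOMES`, plus ``glucose_2h``, ``smoking``,
        ``education``, ``physical_activity``, ``bp_medication``).

    Cases are guaranteed to attend every exam up to and including their
    classification exam (that attendance is how an incident case enters the
    analysis sample); dropout applies to later exams and to controls from
    the second exam on.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sched = np.asarray(config.exam_schedule, dtype=float)

    part_frames: list[pd.DataFrame] = []
    exam_frames: list[pd.DataFrame] = []
    counter = 0

    for group in GROUPS:
        is_case = group != "control"
        n = config.n_per_subtype[group] if is_case else config.n_controls
        if n == 0:
            continue
        ids = [f"P{counter + i:06d}" for i in range(n)]
        counter += n
        probs = _COVARIATE_PROBS["case" if is_case else "control"]

        baseline_age = rng.uniform(*config.baseline_age_range, n)
        sex = np.where(rng.random(n) < probs["female"], "female", "male")
        fhd_p = config.fhd_prevalence_cases if is_case else config.fhd_prevalence_controls
        fhd = np.where(rng.random(n) < fhd_p, "yes", "no")
        gada = rng.random(n) < (config.gada_positive_rate if is_case else 0.0)

        if is_case:
            class_exam = np.where(rng.random(n) < config.p_classified_exam2, 2, 3)
            lag = rng.uniform(*config.diagnosis_lag_range, n)
            diagnosis_time = sched[class_exam - 1] - lag
            registry = rng.random(n) < config.registry_fraction
        else:
            class_exam = np.zeros(n, dtype=int)
            diagnosis_time = np.full(n, np.nan)
            registry = np.zeros(n, dtype=bool)

        # attendance: exam 1 always; dropout draws for exams 2 and 3
        drop = config.dropout_prob_per_exam
        miss2 = rng.random(n) < drop
        miss3 = rng.random(n) < drop
        if config.monotone_dropout:
            miss3 = miss3 | miss2
        attend = np.column_stack([np.ones(n, bool), ~miss2, ~miss3])
        if is_case:
            # classification exam (and everything before it) is attended
            for e in (2, 3):
                attend[:, :e] |= (class_exam == e)[:, None]
            if config.monotone_dropout:
                attend[:, 2] &= attend[:, 1]

        smoking = rng.choice(SMOKING_LEVELS, n, p=probs["smoking"])
        education = rng.choice(EDUCATION_LEVELS, n, p=np.asarray(probs["education"]) / sum(probs["education"]))
        activity = rng.choice(ACTIVITY_LEVELS, n, p=probs["physical_activity"])
        bp_med = rng.random(n) < probs["bp_medication"]

        # latent means: (n, 3) per outcome
        if is_case:
            t_rel = sched[None, :] - sched[class_exam - 1][:, None]
        else:
            t_rel = np.broadcast_to(sched, (n, 3))
        values: dict[str, np.ndarray] = {}
        for o in OUTCOMES:
            prof = config.subtype_profiles[group][o]
            mean = case_mean(prof, t_rel) if is_case else control_mean(prof, t_rel)
            b = _normal(rng, config.random_intercept_sd[o], n)[:, None]
            eps = _normal(rng, config.residual_sd[o], (n, 3))
            values[o] = mean + b + eps
        # physiological floors keep the invariants fpg>0, whr in (0,2), etc.
        values["fpg"] = np.maximum(values["fpg"], 1.0)
        values["fasting_insulin"] = np.maximum(values["fasting_insulin"], 0.1)
        values["bmi"] = np.maximum(values["bmi"], 10.0)
        values["whr"] = np.clip(values["whr"], 0.3, 1.9)
        values["dbp"] = np.maximum(values["dbp"], 30.0)
        values["sbp"] = np.maximum(values["sbp"], values["dbp"] + 5.0)

        g2h_cfg = _load_defaults()["glucose_2h"]
        g2h = g2h_cfg["factor"][group] * values["fpg"] + _normal(rng, g2h_cfg["sd"], (n, 3))
        g2h = np.maximum(g2h, 1.0)
        if config.glucose_2h_missing_prob > 0:
            g2h = np.where(rng.random((n, 3)) < config.glucose_2h_missing_prob, np.nan, g2h)

        if config.diagnosis_mode == "threshold":
            # diagnosis at the first attended exam whose FPG crosses the
            # diagnostic threshold; participants who never cross stay undiagnosed
            hit = (values["fpg"] >= 126.0) & attend
            any_hit = hit.any(axis=1)
            first = np.argmax(hit, axis=1)
            diagnosis_time = np.where(any_hit, sched[first], np.nan)
            registry = registry & any_hit
            class_exam = np.where(any_hit, first + 1, 0)

        attended_str = ["|".join(str(e + 1) for e in range(3) if attend[i, e]) for i in range(n)]
        part_frames.append(
            pd.DataFrame(
                {
                    "participant_id": ids,
                    "group": group,
                    "sex": sex,
                    "fhd": fhd,
                    "gada_positive": gada,
                    "baseline_age": baseline_age,
                    "diagnosis_time": diagnosis_time,
                    "diagnosed_via_registry": registry,
                    "classification_exam": class_exam,
                    "exams_attended": attended_str,
                }
            )
        )

        rows_i, rows_e = np.nonzero(attend)
        exam_frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.asarray(ids)[rows_i],
                    "exam_index": rows_e + 1,
                    "exam_time": sched[rows_e],
                    "age": baseline_age[rows_i] + sched[rows_e],
                    "fpg": values["fpg"][rows_i, rows_e],
                    "glucose_2h": g2h[rows_i, rows_e],
                    "fasting_insulin": values["fasting_insulin"][rows_i, rows_e],
                    "bmi": values["bmi"][rows_i, rows_e],
                    "whr": values["whr"][rows_i, rows_e],
                    "sbp": values["sbp"][rows_i, rows_e],
                    "dbp": values["dbp"][rows_i, rows_e],
                    "smoking": smoking[rows_i],
                    "education": education[rows_i],
                    "physical_activity": activity[rows_i],
                    "bp_medication": bp_med[rows_i],
                }
            )
        )

    if not part_frames:
        return _empty_participants(), _empty_exams()
    participants = pd.concat(part_frames, ignore_index=True)
    exams = pd.concat(exam_frames, ignore_index=True)
    return participants, exams


def _empty_participants() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "participant_id", "group", "sex", "fhd", "gada_positive", "baseline_age",
            "diagnosis_time", "diagnosed_via_registry", "classification_exam", "exams_attended",
        ]
    )


def _empty_exams() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "participant_id", "exam_index", "exam_time", "age", "fpg", "glucose_2h",
            "fasting_insulin", "bmi", "whr", "sbp", "dbp", "smoking", "education",
            "physical_activity", "bp_medication",
        ]
    )
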