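"""Case ascertainment, eligibility and exclusion cascade, control selection,
and diagnosis-anchored timeline alignment.

The analysis sample consists of incident type-2-diabetes cases diagnosed
after the baseline exam and at most five years before the study exam used
for subtype classification, plus participants who remained diabetes-free
throughout follow-up (controls).  Every removal is logged in an ordered
:class:`ExclusionLog`, so the accounting identity
``n_input == n_clean + sum(n_removed)`` holds for every run.

For trajectory modelling, each case's exams are re-labelled on an axis
relative to the classification exam (``20y-pre``, ``10y-pre``,
``classification``, ``10y-post``); controls keep their original calendar
exams, anchored at the second exam so both groups share one axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, ContractError, DomainError

#: Diagnostic thresholds (mg/dL) for the oral glucose tolerance test.
FPG_DIAGNOSTIC_THRESHOLD = 126.0
GLUCOSE_2H_DIAGNOSTIC_THRESHOLD = 200.0

#: Hypoglycemia exclusion threshold (mg/dL) and outlier rule width (SDs).
FPG_HYPOGLYCEMIA_THRESHOLD = 70.0
OUTLIER_SD_LIMIT = 5.0

#: Maximum years between diagnosis and the classification exam.
MAX_DIAGNOSIS_TO_EXAM_YEARS = 5.0

RELATIVE_LABELS = ("20y-pre", "10y-pre", "classification", "10y-post")

#: Case exam-index -> relative label, by classification exam.
_CASE_LABELS = {
    2: {1: "10y-pre", 2: "classification", 3: "10y-post"},
    3: {1: "20y-pre", 2: "10y-pre", 3: "classification"},
}
#: Controls retain their calendar exams; the fixed reference labels anchor
#: exam 2 at the classification point of the shared axis.
_CONTROL_LABELS = {1: "10y-pre", 2: "classification", 3: "10y-post"}

OUTCOME_COLUMNS = ("fpg", "glucose_2h", "fasting_insulin", "bmi", "whr", "sbp", "dbp")

EXCLUSION_RULES = ("missing_required_fields", "fpg_below_70", "outlier_5sd")


def ascertain_t2d(fpg, glucose_2h, registry_flag) -> bool:
    """Type-2-diabetes ascertainment from one examination.

    True iff fasting glucose >= 126 mg/dL, or 2-h post-load glucose
    >= 200 mg/dL, or the registry carries a diabetes code for the
    participant.  Missing values are ignored; all-missing input is a
    contract violation.
    """
    fpg_known = fpg is not None and not (isinstance(fpg, float) and math.isnan(fpg))
    g2h_known = glucose_2h is not None and not (
        isinstance(glucose_2h, float) and math.isnan(glucose_2h)
    )
    reg_known = registry_flag is not None
    if not (fpg_known or g2h_known or reg_known):
        raise ContractError("ascertain_t2d needs at least one non-missing input")
    if fpg_known and fpg >= FPG_DIAGNOSTIC_THRESHOLD:
        return True
    if g2h_known and glucose_2h >= GLUCOSE_2H_DIAGNOSTIC_THRESHOLD:
        return True
    return bool(registry_flag) if reg_known else False


def has_fhd(first_degree_with_t2d: int, second_degree_with_t2d: int) -> bool:
    """Family history of diabetes: >=1 first-degree or >=2 second-degree
    relatives with type 2 diabetes."""
    if first_degree_with_t2d < 0 or second_degree_with_t2d < 0:
        raise DomainError("relative counts must be non-negative")
    return first_degree_with_t2d >= 1 or second_degree_with_t2d >= 2


@dataclass
class ExclusionLog:
    """Ordered record of every removal, one entry per rule application."""

    entries: list[tuple[str, int, tuple[str, ...]]] = field(default_factory=list)

    def add(self, rule: str, ids) -> None:
        ids = tuple(ids)
        self.entries.append((rule, len(ids), ids))

    @property
    def total_removed(self) -> int:
        return sum(n for _, n, _ in self.entries)

    def removed_ids(self) -> set[str]:
        return {pid for _, _, ids in self.entries for pid in ids}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r, n, "|".join(ids)) for r, n, ids in self.entries],
            columns=["rule", "n_removed", "participant_ids"],
        )


def _exam_lookup(exams: pd.DataFrame) -> dict[str, dict[int, float]]:
    out: dict[str, dict[int, float]] = {}
    for pid, e, t in zip(exams["participant_id"], exams["exam_index"], exams["exam_time"]):
        out.setdefault(pid, {})[int(e)] = float(t)
    return out


def select_incident_cases(
    participants: pd.DataFrame, exams: pd.DataFrame
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Identify eligible incident cases and their classification exam.

    A diagnosed participant is eligible when the diagnosis falls strictly
    after the baseline exam and some attended exam 2 or 3 lies at or after
    the diagnosis with a lag of at most five years; the earliest such exam
    is the classification exam.  Diagnoses more than five years before any
    attended later exam, or after the last attended exam, are excluded and
    logged.

    Returns the eligible cases (``participant_id``, ``classification_exam``,
    ``classification_time``, ``diagnosis_to_exam_years`` plus the original
    participant columns) and the exclusion log.
    """
    attended = _exam_lookup(exams)
    log = ExclusionLog()
    diagnosed = participants[participants["diagnosis_time"].notna()]

    not_after_baseline: list[str] = []
    no_window_exam: list[str] = []
    rows = []
    for _, p in diagnosed.iterrows():
        pid = p["participant_id"]
        times = attended.get(pid, {})
        t_dx = float(p["diagnosis_time"])
        t_baseline = times.get(1, 0.0)
        if t_dx <= t_baseline:
            not_after_baseline.append(pid)
            continue
        chosen = None
        for e in (2, 3):
            if e in times and 0.0 <= times[e] - t_dx <= MAX_DIAGNOSIS_TO_EXAM_YEARS:
                chosen = e
                break
        if chosen is None:
            no_window_exam.append(pid)
            continue
        row = p.to_dict()
        row["classification_exam"] = chosen
        row["classification_time"] = times[chosen]
        row["diagnosis_to_exam_years"] = times[chosen] - t_dx
        rows.append(row)
    if not_after_baseline:
        log.add("diagnosis_not_after_baseline", not_after_baseline)
    if no_window_exam:
        log.add("no_exam_within_5y_of_diagnosis", no_window_exam)
    cases = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=list(participants.columns)
        + ["classification_exam", "classification_time", "diagnosis_to_exam_years"]
    )
    return cases, log


def select_controls(
    participants: pd.DataFrame, exams: pd.DataFrame, exclude_fhd: bool = False
) -> pd.DataFrame:
    """Participants never ascertained as diabetic across all exams and the
    registry; with ``exclude_fhd`` additionally restricted to those without
    a family history of diabetes (sensitivity-analysis toggle)."""
    ascertained: set[str] = set(
        participants.loc[participants["diagnosis_time"].notna(), "participant_id"]
    )
    if "diagnosed_via_registry" in participants.columns:
        ascertained |= set(
            participants.loc[
                participants["diagnosed_via_registry"].fillna(False).astype(bool),
                "participant_id",
            ]
        )
    fpg_hit = exams["fpg"] >= FPG_DIAGNOSTIC_THRESHOLD
    g2h_hit = exams["glucose_2h"].notna() & (
        exams["glucose_2h"] >= GLUCOSE_2H_DIAGNOSTIC_THRESHOLD
    )
    ascertained |= set(exams.loc[fpg_hit | g2h_hit, "participant_id"])
    controls = participants[~participants["participant_id"].isin(ascertained)].copy()
    if exclude_fhd:
        controls = controls[controls["fhd"] == "no"]
    return controls


def apply_exclusions(
    sample: pd.DataFrame,
    exams: pd.DataFrame,
    rules=EXCLUSION_RULES,
    required_fields=("fpg", "fasting_insulin", "bmi"),
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the exclusion cascade to the analysis sample.

    ``sample`` holds one row per retained participant with a
    ``classification_exam`` column (cases) or none/0 (controls).  Rules run
    in the listed order and each participant is removed at most once:

    - ``missing_required_fields``: cases lacking any classification variable
      at the classification exam (controls are handled complete-case at
      modelling time);
    - ``fpg_below_70``: hypoglycemia, FPG < 70 mg/dL — evaluated at the
      classification exam for cases and at every attended exam for controls;
    - ``outlier_5sd``: any outcome strictly more than 5 SDs from that
      outcome's mean; the reference mean/SD is computed over the current
      sample's records at the same exam cycle, leaving the candidate value
      out so it cannot mask itself.
    """
    unknown = [r for r in rules if r not in EXCLUSION_RULES]
    if unknown:
        raise ConfigurationError(
            f"unknown exclusion rule(s) {unknown}; allowed: {list(EXCLUSION_RULES)}"
        )
    log = ExclusionLog()
    kept = sample.copy()
    has_class = (
        kept["classification_exam"].fillna(0).astype(int)
        if "classification_exam" in kept.columns
        else pd.Series(0, index=kept.index)
    )
    is_case = pd.Series(has_class.to_numpy() > 0, index=kept.index)

    for rule in rules:
        ex = exams[exams["participant_id"].isin(kept["participant_id"])]
        if rule == "missing_required_fields":
            bad = []
            for pid, ce in zip(kept.loc[is_case, "participant_id"], has_class[is_case]):
                row = ex[(ex["participant_id"] == pid) & (ex["exam_index"] == ce)]
                if row.empty or row[list(required_fields)].isna().any(axis=None):
                    bad.append(pid)
        elif rule == "fpg_below_70":
            ce_map = dict(zip(kept["participant_id"], has_class))
            hypo = ex[ex["fpg"] < FPG_HYPOGLYCEMIA_THRESHOLD]
            bad = sorted(
                {
                    pid
                    for pid, e in zip(hypo["participant_id"], hypo["exam_index"])
                    if ce_map.get(pid, 0) in (0, int(e))
                }
            )
        else:  # outlier_5sd
            # leave-one-out mean/SD: a candidate must not mask itself by
            # inflating the reference spread (matters at small n, negligible
            # at cohort scale)
            bad_set: set[str] = set()
            for _, cycle in ex.groupby("exam_index"):
                for col in OUTCOME_COLUMNS:
                    v = cycle[col].astype(float).to_numpy()
                    ok = np.isfinite(v)
                    n = int(ok.sum())
                    if n < 3:
                        continue
                    s_sum, s_sq = v[ok].sum(), (v[ok] ** 2).sum()
                    loo_mean = (s_sum - v) / (n - 1)
                    loo_var = (s_sq - v**2 - (n - 1) * loo_mean**2) / (n - 2)
                    loo_sd = np.sqrt(np.maximum(loo_var, 0.0))
                    with np.errstate(invalid="ignore"):
                        flag = ok & (loo_sd > 0) & (
                            np.abs(v - loo_mean) > OUTLIER_SD_LIMIT * loo_sd
                        )
                    bad_set |= set(cycle.loc[flag, "participant_id"])
            bad = sorted(bad_set)
        if bad:
            log.add(rule, bad)
            keep_mask = ~kept["participant_id"].isin(bad)
            kept = kept[keep_mask]
            is_case = is_case[keep_mask]
            has_class = has_class[keep_mask]
    return kept.reset_index(drop=True), log


def align_timeline_from_truth(
    participants: pd.DataFrame, exams: pd.DataFrame
) -> pd.DataFrame:
    """Align a synthetic cohort on the generator's own ground truth.

    Bypasses ascertainment, classification and exclusions: the generator's
    ``group`` and ``classification_exam`` columns define the anchor directly.
    Intended for parameter-recovery simulations, where selection effects
    must not contaminate the comparison against the configured profiles.
    """
    times = _exam_lookup(exams)
    cases = participants[participants["group"] != "control"].copy()
    cases["subtype"] = cases["group"]
    cases["classification_time"] = [
        times.get(pid, {}).get(int(ce), float("nan"))
        for pid, ce in zip(cases["participant_id"], cases["classification_exam"])
    ]
    controls = participants[participants["group"] == "control"]
    return align_timeline(cases, controls, exams)


def align_timeline(
    cases: pd.DataFrame, controls: pd.DataFrame, exams: pd.DataFrame
) -> pd.DataFrame:
    """Project every retained observation onto the shared relative time axis.

    ``cases`` must carry ``classification_exam``, ``classification_time`` and
    a ``subtype`` (or ``group``) column; ``controls`` only needs
    ``participant_id``.  Returns one row per attended exam of every retained
    participant with ``group``, ``relative_label``, ``relative_time`` and the
    outcome/covariate columns.  Controls are anchored at the cohort's exam-2
    time so both groups share the plotted axis.
    """
    group_col = "subtype" if "subtype" in cases.columns else "group"
    if len(cases) and (
        group_col not in cases.columns or cases["classification_exam"].isna().any()
    ):
        raise ContractError("every case needs a subtype and a classification_exam")

    exam2_times = exams.loc[exams["exam_index"] == 2, "exam_time"]
    control_anchor = float(exam2_times.median()) if len(exam2_times) else 10.0

    meta: dict[str, tuple[str, int, float]] = {}
    for _, c in cases.iterrows():
        meta[c["participant_id"]] = (
            str(c[group_col]),
            int(c["classification_exam"]),
            float(c["classification_time"]),
        )
    for pid in controls["participant_id"]:
        meta[pid] = ("control", 0, control_anchor)

    obs = exams[exams["participant_id"].isin(meta)].copy()
    groups, labels, rel_times = [], [], []
    for pid, e, t in zip(obs["participant_id"], obs["exam_index"], obs["exam_time"]):
        g, ce, anchor = meta[pid]
        e = int(e)
        label = _CASE_LABELS[ce][e] if ce else _CONTROL_LABELS[e]
        groups.append(g)
        labels.append(label)
        rel_times.append(float(t) - anchor)
    obs.insert(1, "group", groups)
    obs.insert(2, "relative_label", labels)
    obs.insert(3, "relative_time", rel_times)
    return obs.reset_index(drop=True)
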