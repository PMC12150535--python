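"""Multilevel mixed-effects trajectory models with estimated marginal means.

For each outcome, a linear mixed model with a participant-level random
intercept is fitted by REML on the diagnosis-anchored observations:

    y_ij = mu(group_i, reltime_ij) + covariates_ij * gamma + b_i + e_ij,
    b_i ~ N(0, tau^2),   e_ij ~ N(0, sigma^2)

The group x relative-time mean structure uses cell-means coding: one fixed
effect per *observed* (group, relative label) cell, which keeps the design
full-rank even though controls structurally lack the 20-years-pre cell.
Adjustment set "model1" adds examination cycle, age and sex; "model2"
further adds education, smoking, family history, physical activity, BMI
(except when BMI is the outcome) and blood-pressure medication (only for
blood-pressure outcomes).

Estimated marginal means (EMMs) are model predictions per cell with
continuous covariates held at their sample means and categorical covariates
averaged over their observed distributions; pairwise between-group contrasts
of the EMMs use delta-method standard errors with a normal approximation and
Tukey (default), Bonferroni or no multiplicity adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from ._errors import ConfigurationError, ContractError, ModelError
from .cohort import RELATIVE_LABELS

SUPPORTED_OUTCOMES = (
    "fpg", "bmi", "homa_b", "homa_ir", "fasting_insulin", "whr", "dbp", "sbp"
)

#: Nominal relative-time (years) of each label, used by the continuous coding.
LABEL_TIMES = {"20y-pre": -20.0, "10y-pre": -10.0, "classification": 0.0, "10y-post": 10.0}

GROUP_ORDER = ("SIDD", "SIRD", "MOD", "MARD", "control")


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one trajectory model.

    ``adjustment`` selects the covariate set; ``time_coding`` selects
    categorical relative labels (default, matching the discrete exam-aligned
    axis) or per-group linear slopes on continuous relative years;
    ``age_coding`` uses the age at each observation by default (baseline age
    is collinear with exam cycle and relative time).
    """

    outcome: str
    adjustment: str = "model1"
    time_coding: str = "categorical_label"
    age_coding: str = "time_varying"
    random_slope: bool = False

    def __post_init__(self):
        if self.outcome not in SUPPORTED_OUTCOMES:
            raise ConfigurationError(
                f"outcome must be one of {SUPPORTED_OUTCOMES}, got {self.outcome!r}"
            )
        if self.adjustment not in ("model1", "model2", "none"):
            raise ConfigurationError(f"adjustment must be model1/model2/none, got {self.adjustment!r}")
        if self.time_coding not in ("categorical_label", "continuous_years"):
            raise ConfigurationError(f"unknown time_coding {self.time_coding!r}")
        if self.age_coding not in ("time_varying", "baseline"):
            raise ConfigurationError(f"unknown age_coding {self.age_coding!r}")


@dataclass
class TrajectoryFit:
    """Fitted trajectory model for one outcome."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    vc_random: float
    vc_residual: float
    emm: pd.DataFrame
    n_obs: int
    n_participants: int
    converged: bool
    dropped_terms: list[str] = field(default_factory=list)
    groups_present: tuple[str, ...] = ()
    # per (group, label): the EMM design row, for contrast covariances
    emm_rows: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)


def _dummies(series: pd.Series, prefix: str, drop_first: bool = True) -> pd.DataFrame:
    levels = sorted(series.dropna().astype(str).unique())
    use = levels[1:] if drop_first else levels
    return pd.DataFrame(
        {f"{prefix}[{lv}]": (series.astype(str) == lv).astype(float) for lv in use},
        index=series.index,
    )


def _build_design(obs: pd.DataFrame, spec: ModelSpec):
    """Fixed-effects design matrix, list of dropped terms, cell name map."""
    dropped: list[str] = []
    groups = [g for g in GROUP_ORDER if g in set(obs["group"])] + sorted(
        set(obs["group"]) - set(GROUP_ORDER)
    )
    pieces: list[pd.DataFrame] = []

    if spec.time_coding == "categorical_label":
        cells = []
        for g in groups:
            for lab in RELATIVE_LABELS:
                mask = (obs["group"] == g) & (obs["relative_label"] == lab)
                if mask.any():
                    cells.append((f"cell[{g}|{lab}]", mask.astype(float)))
        pieces.append(pd.DataFrame(dict(cells), index=obs.index))
    else:
        cols = {}
        for g in groups:
            ind = (obs["group"] == g).astype(float)
            cols[f"grp[{g}]"] = ind
            cols[f"grp_time[{g}]"] = ind * obs["relative_time"].astype(float)
        pieces.append(pd.DataFrame(cols, index=obs.index))

    def add_categorical(col: str, prefix: str):
        if col not in obs.columns:
            dropped.append(col)
            return
        d = _dummies(obs[col], prefix)
        if d.shape[1] == 0:
            dropped.append(col)
            warnings.warn(f"covariate {col!r} has fewer than 2 observed levels; dropped")
            return
        pieces.append(d)

    def add_continuous(col: str):
        if col not in obs.columns or obs[col].isna().all():
            dropped.append(col)
            return
        pieces.append(obs[[col]].astype(float))

    if spec.adjustment in ("model1", "model2"):
        add_categorical("exam_index", "exam")
        if spec.age_coding == "time_varying":
            add_continuous("age")
        else:
            add_continuous("baseline_age")
        add_categorical("sex", "sex")
    if spec.adjustment == "model2":
        add_categorical("education", "edu")
        add_categorical("smoking", "smoking")
        add_categorical("fhd", "fhd")
        add_categorical("physical_activity", "pa")
        if spec.outcome != "bmi":
            add_continuous("bmi")
        if spec.outcome in ("sbp", "dbp"):
            add_categorical("bp_medication", "bpmed")
    X = pd.concat(pieces, axis=1)
    return X, dropped, groups


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # identify aliased columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(A, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(A.shape) * np.finfo(float).eps
        aliased = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        aliased += [X.columns[p] for p in piv[len(diag):]]
        raise ModelError(f"singular fixed-effects design; aliased term(s): {sorted(aliased)}")


def fit_trajectory(
    obs: pd.DataFrame,
    spec: ModelSpec,
    require_multiple_groups: bool = True,
) -> TrajectoryFit:
    """REML fit of the mixed model for ``spec.outcome`` on aligned observations.

    ``obs`` is the output of :func:`diatraj.cohort.align_timeline` with the
    outcome column present.  Rows with missing outcome or covariate values
    are dropped (complete case) and the count is reflected in ``n_obs``.
    Non-convergence yields a flagged result, not an exception; a singular
    design raises :class:`ModelError` listing the aliased terms.
    """
    if spec.outcome not in obs.columns:
        raise ContractError(f"observations lack outcome column {spec.outcome!r}")
    groups_present = sorted(set(obs["group"].dropna()))
    if require_multiple_groups and len(groups_present) < 2:
        raise ContractError(
            f"need at least 2 groups to fit trajectories, got {groups_present}"
        )
    X, dropped, groups = _build_design(obs, spec)
    y = obs[spec.outcome].astype(float)
    keep = y.notna() & X.notna().all(axis=1)
    X, y = X[keep], y[keep]
    ids = obs.loc[keep, "participant_id"]
    if len(X) == 0:
        raise ContractError("no complete-case observations to fit")
    _check_rank(X)

    exog_re = None
    if spec.random_slope:
        exog_re = pd.DataFrame(
            {"intercept": 1.0, "rel_time": obs.loc[keep, "relative_time"].astype(float)}
        )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.MixedLM(y.to_numpy(), X.to_numpy(), groups=ids.to_numpy(),
                           exog_re=None if exog_re is None else exog_re.to_numpy())
        try:
            res = model.fit(reml=True)
        except np.linalg.LinAlgError as exc:
            raise ModelError(f"mixed-model fit failed: {exc}") from exc
        if any("onverge" in str(w.message) for w in caught):
            converged = False
    if not getattr(res, "converged", True):
        converged = False

    k = X.shape[1]
    params = pd.Series(res.fe_params, index=X.columns)
    cov_all = np.asarray(res.cov_params())
    cov = pd.DataFrame(cov_all[:k, :k], index=X.columns, columns=X.columns)
    with np.errstate(invalid="ignore"):  # NaN cov in degenerate designs
        bse = pd.Series(np.sqrt(np.diag(cov)), index=X.columns)

    fit = TrajectoryFit(
        spec=spec,
        params=params,
        bse=bse,
        cov=cov,
        vc_random=float(np.asarray(res.cov_re)[0, 0]),
        vc_residual=float(res.scale),
        emm=pd.DataFrame(),
        n_obs=int(len(X)),
        n_participants=int(ids.nunique()),
        converged=converged,
        dropped_terms=dropped,
        groups_present=tuple(groups),
    )
    # covariate reference profile: observed column means of everything that
    # is not part of the group x time mean structure
    mean_cols = [c for c in X.columns if c.startswith(("cell[", "grp[", "grp_time["))]
    fit._covar_means = X.drop(columns=mean_cols).mean()  # type: ignore[attr-defined]
    fit._cells = _observed_cells(obs[keep])  # type: ignore[attr-defined]
    fit.emm = estimate_marginal_means(fit)
    return fit


def _observed_cells(obs: pd.DataFrame) -> list[tuple[str, str]]:
    cells = []
    for g in GROUP_ORDER:
        for lab in RELATIVE_LABELS:
            if ((obs["group"] == g) & (obs["relative_label"] == lab)).any():
                cells.append((g, lab))
    extra = sorted(set(obs["group"]) - set(GROUP_ORDER))
    for g in extra:
        for lab in RELATIVE_LABELS:
            if ((obs["group"] == g) & (obs["relative_label"] == lab)).any():
                cells.append((g, lab))
    return cells


def estimate_marginal_means(fit: TrajectoryFit) -> pd.DataFrame:
    """EMM per observed (group, relative label) cell with delta-method SEs."""
    cols = list(fit.params.index)
    covar_means = getattr(fit, "_covar_means", pd.Series(dtype=float))
    rows = []
    fit.emm_rows = {}
    for g, lab in getattr(fit, "_cells", []):
        r = np.zeros(len(cols))
        if fit.spec.time_coding == "categorical_label":
            name = f"cell[{g}|{lab}]"
            if name not in cols:
                continue
            r[cols.index(name)] = 1.0
        else:
            if f"grp[{g}]" not in cols:
                continue
            r[cols.index(f"grp[{g}]")] = 1.0
            r[cols.index(f"grp_time[{g}]")] = LABEL_TIMES[lab]
        for c, v in covar_means.items():
            r[cols.index(c)] = v
        est = float(r @ fit.params.to_numpy())
        with np.errstate(invalid="ignore"):
            se = float(np.sqrt(r @ fit.cov.to_numpy() @ r))
        fit.emm_rows[(g, lab)] = r
        rows.append({"group": g, "relative_label": lab, "emm": est, "se": se})
    return pd.DataFrame(rows)


def pairwise_contrasts(
    fit: TrajectoryFit,
    adjustment_method: str = "tukey",
    per_label: bool = True,
) -> pd.DataFrame:
    """All pairwise between-group EMM contrasts.

    With ``per_label=True`` each relative label common to both groups gets a
    contrast (the multiplicity family is the set of group pairs within that
    label); with ``per_label=False`` EMMs are first pooled (averaged) over
    the labels shared by each pair.  ``adjustment_method`` is ``tukey``
    (studentized-range), ``bonferroni`` or ``none``; raw and adjusted
    p-values are both reported.
    """
    if adjustment_method not in ("tukey", "bonferroni", "none"):
        raise ConfigurationError(
            f"unknown adjustment method {adjustment_method!r}; use tukey/bonferroni/none"
        )
    if not fit.emm_rows:
        estimate_marginal_means(fit)
    groups = [g for g in fit.groups_present if any(k[0] == g for k in fit.emm_rows)]
    if len(groups) < 2:
        raise ContractError("need at least 2 groups for pairwise contrasts")
    cov = fit.cov.to_numpy()
    beta = fit.params.to_numpy()
    df_resid = max(fit.n_obs - len(beta), 1)

    def one_contrast(ga, gb, label, ra, rb):
        d = ra - rb
        est = float(d @ beta)
        se = float(np.sqrt(d @ cov @ d))
        z = est / se if se > 0 else np.inf * np.sign(est)
        p_raw = float(2 * stats.norm.sf(abs(z)))
        return {
            "group_a": ga, "group_b": gb, "label": label,
            "estimate": est, "se": se, "z": z, "p_raw": p_raw,
        }

    results = []
    pairs = [(groups[i], groups[j]) for i in range(len(groups)) for j in range(i + 1, len(groups))]
    if per_label:
        for lab in RELATIVE_LABELS:
            fam = []
            for ga, gb in pairs:
                if (ga, lab) in fit.emm_rows and (gb, lab) in fit.emm_rows:
                    fam.append(one_contrast(ga, gb, lab, fit.emm_rows[(ga, lab)], fit.emm_rows[(gb, lab)]))
            results.extend(_adjust(fam, adjustment_method, len(groups), df_resid))
    else:
        fam = []
        for ga, gb in pairs:
            labs = [l for l in RELATIVE_LABELS if (ga, l) in fit.emm_rows and (gb, l) in fit.emm_rows]
            if not labs:
                continue
            ra = np.mean([fit.emm_rows[(ga, l)] for l in labs], axis=0)
            rb = np.mean([fit.emm_rows[(gb, l)] for l in labs], axis=0)
            fam.append(one_contrast(ga, gb, "pooled", ra, rb))
        results.extend(_adjust(fam, adjustment_method, len(groups), df_resid))
    out = pd.DataFrame(results)
    if len(out):
        out["adjustment_method"] = adjustment_method
    return out


def _adjust(family: list[dict], method: str, n_groups: int, df_resid: int) -> list[dict]:
    m = len(family)
    for row in family:
        if method == "none" or m <= 1:
            row["p_adjusted"] = row["p_raw"]
        elif method == "bonferroni":
            row["p_adjusted"] = min(1.0, row["p_raw"] * m)
        else:  # tukey: q statistic = |z| * sqrt(2) against studentized range
            q = abs(row["z"]) * np.sqrt(2.0)
            row["p_adjusted"] = float(
                stats.studentized_range.sf(q, k=n_groups, df=df_resid)
            )
        row["p_adjusted"] = float(min(1.0, row["p_adjusted"]))
    return family
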