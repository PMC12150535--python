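"""Mixed-effects trajectory models, EMMs and pairwise contrasts."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from diatraj._errors import ConfigurationError, ContractError, ModelError
from diatraj.cohort import align_timeline_from_truth
from diatraj.simulate import SimulationConfig, noise_free, simulate_cohort
from diatraj.trajectory import (
    LABEL_TIMES,
    ModelSpec,
    estimate_marginal_means,
    fit_trajectory,
    pairwise_contrasts,
)


def _recovery_config(seed=0, **kwargs):
    defaults = dict(
        n_per_subtype={"SIDD": 30, "SIRD": 30, "MOD": 30, "MARD": 30},
        n_controls=120,
        dropout_prob_per_exam=0.0,
        seed=seed,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


def _truth(cfg, group, outcome, label):
    prof = cfg.subtype_profiles[group][outcome]
    if group == "control":
        t = {"10y-pre": 0.0, "classification": 10.0, "10y-post": 20.0}[label]
        return prof.intercept + prof.slope_pre * t
    return prof.mean_at(LABEL_TIMES[label])


@pytest.fixture(scope="module")
def aligned_obs():
    cfg = _recovery_config(seed=21)
    p, e = simulate_cohort(cfg)
    return cfg, align_timeline_from_truth(p, e)


class TestModelSpec:
    def test_unknown_outcome_rejected(self):
        with pytest.raises(ConfigurationError, match="outcome"):
            ModelSpec(outcome="hba1c")

    def test_unknown_adjustment_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelSpec(outcome="fpg", adjustment="model3")


class TestFitTrajectory:
    def test_cell_means_recover_generator_profiles(self, aligned_obs):
        """Fitted group x time cell means sit within 3 SEs of the configured
        latent means when the model matches the generator."""
        cfg, obs = aligned_obs
        fit = fit_trajectory(obs, ModelSpec(outcome="fpg", adjustment="none"))
        assert fit.converged
        for _, row in fit.emm.iterrows():
            truth = _truth(cfg, row["group"], "fpg", row["relative_label"])
            assert abs(row["emm"] - truth) < 3 * row["se"], row

    def test_variance_components_near_truth(self, aligned_obs):
        cfg, obs = aligned_obs
        fit = fit_trajectory(obs, ModelSpec(outcome="fpg", adjustment="none"))
        assert fit.vc_random == pytest.approx(cfg.random_intercept_sd["fpg"] ** 2, rel=0.5)
        assert fit.vc_residual == pytest.approx(cfg.residual_sd["fpg"] ** 2, rel=0.3)

    def test_single_group_rejected(self, aligned_obs):
        _, obs = aligned_obs
        with pytest.raises(ContractError, match="2 groups"):
            fit_trajectory(obs[obs["group"] == "control"], ModelSpec(outcome="fpg"))

    def test_zero_random_variance_matches_ols(self):
        """With no between-person variance the mixed fit agrees with OLS on
        the same fixed design."""
        cfg = noise_free(_recovery_config(seed=5))
        cfg.residual_sd = {o: 1.0 for o in cfg.residual_sd}  # iid noise only
        p, e = simulate_cohort(cfg)
        obs = align_timeline_from_truth(p, e)
        fit = fit_trajectory(obs, ModelSpec(outcome="bmi", adjustment="none"))
        import statsmodels.api as sm

        from diatraj.trajectory import _build_design

        X, _, _ = _build_design(obs, ModelSpec(outcome="bmi", adjustment="none"))
        ols = sm.OLS(obs["bmi"].to_numpy(), X.to_numpy()).fit()
        assert np.allclose(fit.params.to_numpy(), ols.params, rtol=1e-4, atol=1e-6)

    def test_duplicated_rows_leave_point_estimates_stable(self, aligned_obs):
        """Balanced duplication of every row leaves the mean structure nearly
        unchanged (exact invariance holds for OLS; under REML the duplicated
        residuals shift the variance-component estimates, which perturbs the
        GLS weighting at the fourth decimal)."""
        _, obs = aligned_obs
        spec = ModelSpec(outcome="whr", adjustment="none")
        fit1 = fit_trajectory(obs, spec)
        doubled = pd.concat([obs, obs], ignore_index=True)
        fit2 = fit_trajectory(doubled, spec)
        assert np.allclose(fit1.params.to_numpy(), fit2.params.to_numpy(), rtol=1e-3)

    def test_singular_design_lists_aliased_terms(self, aligned_obs):
        _, obs = aligned_obs
        obs = obs.copy()
        obs["bmi"] = obs["age"] * 2.0  # bmi aliased with age in model2
        with pytest.raises(ModelError, match="aliased"):
            fit_trajectory(obs, ModelSpec(outcome="fpg", adjustment="model2"))

    def test_degenerate_covariate_dropped_with_warning(self, aligned_obs):
        _, obs = aligned_obs
        obs = obs.copy()
        obs["sex"] = "female"
        with pytest.warns(UserWarning, match="sex"):
            fit = fit_trajectory(obs, ModelSpec(outcome="fpg", adjustment="model1"))
        assert "sex" in fit.dropped_terms

    def test_continuous_time_coding(self, aligned_obs):
        cfg, obs = aligned_obs
        fit = fit_trajectory(
            obs, ModelSpec(outcome="fpg", adjustment="none", time_coding="continuous_years")
        )
        # a per-group line cannot represent the piecewise break exactly, but
        # slopes should be positive for every case group (glucose rises)
        for g in ("SIDD", "SIRD", "MOD", "MARD"):
            assert fit.params[f"grp_time[{g}]"] > 0


class TestEstimatedMarginalMeans:
    def test_intercept_only_equals_sample_mean(self):
        """One group, one time point, no covariates: the EMM is the mean."""
        rng = np.random.default_rng(3)
        y = rng.normal(50, 5, 40)
        obs = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(40)],
                "group": "MARD",
                "relative_label": "classification",
                "relative_time": 0.0,
                "y": y,
            }
        )
        from diatraj.trajectory import SUPPORTED_OUTCOMES

        obs["fpg"] = y
        fit = fit_trajectory(
            obs, ModelSpec(outcome="fpg", adjustment="none"), require_multiple_groups=False
        )
        assert fit.emm["emm"].iloc[0] == pytest.approx(y.mean(), rel=1e-6)

    def test_balanced_two_group_emm_equals_raw_means(self):
        rng = np.random.default_rng(4)
        rows = []
        for g, mu in (("SIDD", 140.0), ("control", 85.0)):
            for i in range(30):
                rows.append(
                    {
                        "participant_id": f"{g}{i}",
                        "group": g,
                        "relative_label": "classification",
                        "relative_time": 0.0,
                        "fpg": mu + rng.normal(0, 4),
                    }
                )
        obs = pd.DataFrame(rows)
        fit = fit_trajectory(obs, ModelSpec(outcome="fpg", adjustment="none"))
        for g in ("SIDD", "control"):
            raw = obs.loc[obs["group"] == g, "fpg"].mean()
            emm = fit.emm.set_index("group")["emm"][g]
            assert emm == pytest.approx(raw, rel=1e-6)

    def test_adjusted_emm_within_3se_of_direct_effect(self):
        """Covariate adjustment (model2) recovers the generator's group
        effect even though covariates shift individual predictions."""
        cfg = _recovery_config(seed=9)
        p, e = simulate_cohort(cfg)
        obs = align_timeline_from_truth(p, e)
        fit = fit_trajectory(obs, ModelSpec(outcome="fpg", adjustment="model2"))
        emm = fit.emm.set_index(["group", "relative_label"])
        for ga, gb in (("SIDD", "MARD"), ("SIRD", "control")):
            lab = "classification"
            truth = _truth(cfg, ga, "fpg", lab) - _truth(cfg, gb, "fpg", lab)
            est = emm.loc[(ga, lab), "emm"] - emm.loc[(gb, lab), "emm"]
            se = np.hypot(emm.loc[(ga, lab), "se"], emm.loc[(gb, lab), "se"])
            assert abs(est - truth) < 3 * max(se, 1e-9)


class TestPairwiseContrasts:
    def test_contrast_count_is_choose_2(self, aligned_obs):
        _, obs = aligned_obs
        fit = fit_trajectory(obs, ModelSpec(outcome="bmi", adjustment="none"))
        contrasts = pairwise_contrasts(fit, "none")
        per_label = contrasts.groupby("label").size()
        # 5 groups at shared labels -> 10 pairs; 20y-pre lacks controls -> 6
        assert per_label["classification"] == 10
        assert per_label["20y-pre"] == 6

    def test_no_adjustment_passthrough(self, aligned_obs):
        _, obs = aligned_obs
        fit = fit_trajectory(obs, ModelSpec(outcome="bmi", adjustment="none"))
        c = pairwise_contrasts(fit, "none")
        assert np.allclose(c["p_adjusted"], c["p_raw"])

    def test_bonferroni_multiplies_and_caps(self, aligned_obs):
        _, obs = aligned_obs
        fit = fit_trajectory(obs, ModelSpec(outcome="whr", adjustment="none"))
        c = pairwise_contrasts(fit, "bonferroni")
        fam = c[c["label"] == "classification"]
        m = len(fam)
        assert m == 10
        expected = np.minimum(1.0, fam["p_raw"] * m)
        assert np.allclose(fam["p_adjusted"], expected)

    def test_tukey_monotone_in_raw_p(self, aligned_obs):
        _, obs = aligned_obs
        fit = fit_trajectory(obs, ModelSpec(outcome="fpg", adjustment="none"))
        c = pairwise_contrasts(fit, "tukey")
        fam = c[c["label"] == "classification"].sort_values("p_raw")
        assert fam["p_adjusted"].is_monotonic_increasing
        assert ((c["p_adjusted"] >= 0) & (c["p_adjusted"] <= 1)).all()
        assert (c["p_adjusted"] >= c["p_raw"] - 1e-12).all()

    def test_antisymmetry_under_group_relabelling(self, aligned_obs):
        """Swapping the two groups of a pair flips the contrast sign."""
        _, obs = aligned_obs
        fit = fit_trajectory(obs, ModelSpec(outcome="bmi", adjustment="none"))
        c = pairwise_contrasts(fit, "none").set_index(["group_a", "group_b", "label"])
        est = c.loc[("SIDD", "MARD", "classification"), "estimate"]
        ra = fit.emm_rows[("MARD", "classification")] - fit.emm_rows[("SIDD", "classification")]
        flipped = float(ra @ fit.params.to_numpy())
        assert flipped == pytest.approx(-est, rel=1e-12)

    def test_pooled_contrasts(self, aligned_obs):
        _, obs = aligned_obs
        fit = fit_trajectory(obs, ModelSpec(outcome="bmi", adjustment="none"))
        pooled = pairwise_contrasts(fit, "tukey", per_label=False)
        assert len(pooled) == 10
        assert (pooled["label"] == "pooled").all()

    def test_unknown_method_rejected(self, aligned_obs):
        _, obs = aligned_obs
        fit = fit_trajectory(obs, ModelSpec(outcome="bmi", adjustment="none"))
        with pytest.raises(ConfigurationError):
            pairwise_contrasts(fit, "holm")
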