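"""Variance-component estimation and paired-difference distributions."""

import math

import numpy as np
import pandas as pd
import pytest

from tdi import (
    AgreementData,
    ConfigurationError,
    DataError,
    FitError,
    SimulationScenario,
    difference_params,
    fit_balanced_vc,
    fit_reml_general,
    generate_dataset,
)


def anova_oracle(values):
    """Brute-force sums-of-squares ANOVA estimators, coded independently of
    the fitting module (explicit loops, no shared helpers).  Returns the raw
    (untruncated) solutions for the interaction model."""
    n, J, m = values.shape
    grand = values.mean()
    cell = np.array([[values[i, j].mean() for j in range(J)] for i in range(n)])
    subj = cell.mean(axis=1)
    dev = cell.mean(axis=0)
    sse = sum(
        (values[i, j, l] - cell[i, j]) ** 2
        for i in range(n) for j in range(J) for l in range(m)
    )
    ssi = m * sum(
        (cell[i, j] - subj[i] - dev[j] + grand) ** 2
        for i in range(n) for j in range(J)
    )
    ssa = J * m * sum((subj[i] - grand) ** 2 for i in range(n))
    mse = sse / (J * n * (m - 1))
    msi = ssi / ((n - 1) * (J - 1))
    msa = ssa / (n - 1)
    return {
        "beta_diff": dev[1] - dev[0],
        "sigma2_e": mse,
        "sigma2_gamma_raw": (msi - mse) / m,
        "sigma2_alpha_raw": (msa - msi) / (2 * m),
        "sigma2_e_pooled": (ssi + sse) / ((n - 1) + J * n * (m - 1)),
    }


def _to_agreement(values):
    n, _, m = values.shape
    frame = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), 2 * m),
            "device": np.tile(np.repeat(["d1", "d2"], m), n),
            "replicate": np.tile(np.arange(1, m + 1), 2 * n),
            "value": values.reshape(-1),
        }
    )
    return AgreementData.from_frame(frame, device_order=("d1", "d2"))


class TestBalancedClosedForm:
    def test_constant_data_gives_zero_variances(self):
        values = np.full((4, 2, 3), 7.5)
        fit = fit_balanced_vc(_to_agreement(values), include_interaction=True)
        assert fit.beta_diff == 0.0
        assert fit.sigma2_alpha == 0.0
        assert fit.sigma2_gamma == 0.0
        assert fit.sigma2_e == 0.0

    @pytest.mark.parametrize("n,m,seed", [(3, 2, 0), (5, 3, 1), (4, 2, 2)])
    def test_matches_independent_ss_oracle(self, n, m, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(10, 3, size=(n, 2, m)) + rng.normal(0, 2, size=(n, 1, 1))
        oracle = anova_oracle(values)
        data = _to_agreement(values)

        fit = fit_balanced_vc(data, include_interaction=True)
        assert fit.beta_diff == pytest.approx(oracle["beta_diff"], rel=1e-12)
        assert fit.sigma2_e == pytest.approx(oracle["sigma2_e"], rel=1e-10)
        assert fit.sigma2_gamma == pytest.approx(
            max(oracle["sigma2_gamma_raw"], 0.0), abs=1e-10
        )

        pooled = fit_balanced_vc(data, include_interaction=False)
        assert pooled.sigma2_e == pytest.approx(oracle["sigma2_e_pooled"], rel=1e-10)

    def test_parameter_recovery_under_study_conditions(self):
        """Mean estimates across replicated fits sit within 3 MC SE of truth."""
        scenario = SimulationScenario(beta_diff=2.174, sigma2_e=52.867, n=100)
        rng = np.random.default_rng(314159)
        n_rep = 400
        betas, alphas, errs = [], [], []
        for _ in range(n_rep):
            fit = fit_balanced_vc(generate_dataset(scenario, rng))
            betas.append(fit.beta_diff)
            alphas.append(fit.sigma2_alpha)
            errs.append(fit.sigma2_e)
        for est, truth in [(betas, 2.174), (alphas, 380.187), (errs, 52.867)]:
            est = np.asarray(est)
            se = est.std(ddof=1) / math.sqrt(n_rep)
            assert abs(est.mean() - truth) < 3 * se

    def test_negative_interaction_solution_truncated_and_flagged(self):
        rng = np.random.default_rng(5)
        n_flagged = 0
        for _ in range(20):
            values = rng.normal(0, 1, size=(20, 2, 2))  # sigma2_gamma = 0 truth
            oracle = anova_oracle(values)
            fit = fit_balanced_vc(_to_agreement(values), include_interaction=True)
            assert fit.sigma2_gamma >= 0.0
            flagged = "sigma2_gamma" in fit.truncated
            assert flagged == (oracle["sigma2_gamma_raw"] < 0)
            if flagged:
                assert fit.sigma2_gamma == 0.0
                n_flagged += 1
        # under a zero-interaction truth about half the raw solutions go negative
        assert n_flagged > 0

    def test_unbalanced_rejected(self, tiny_frame):
        extra = pd.concat(
            [tiny_frame, pd.DataFrame({"subject": ["s2"], "device": ["a"],
                                       "replicate": [1], "value": [3.0]})],
            ignore_index=True,
        )
        with pytest.raises(DataError):
            fit_balanced_vc(AgreementData.from_frame(extra))

    def test_single_replicate_with_interaction_rejected(self):
        values = np.random.default_rng(0).normal(size=(5, 2, 1))
        with pytest.raises(ConfigurationError):
            fit_balanced_vc(_to_agreement(values), include_interaction=True)

    def test_per_device_error_variances(self):
        rng = np.random.default_rng(8)
        n, m = 200, 2
        values = np.empty((n, 2, m))
        values[:, 0, :] = rng.normal(0, 1.0, size=(n, m))
        values[:, 1, :] = rng.normal(0, 3.0, size=(n, m))
        fit = fit_balanced_vc(_to_agreement(values), equal_error_variances=False)
        assert fit.sigma2_e1 == pytest.approx(1.0, rel=0.25)
        assert fit.sigma2_e2 == pytest.approx(9.0, rel=0.25)
        assert fit.sigma2_e2 > fit.sigma2_e1


class TestGeneralReml:
    def test_agrees_with_closed_form_on_balanced_data(self, bp_like_data):
        closed = fit_balanced_vc(bp_like_data)
        general = fit_reml_general(bp_like_data)
        assert general.beta_diff == pytest.approx(closed.beta_diff, rel=1e-6)
        assert general.sigma2_alpha == pytest.approx(closed.sigma2_alpha, rel=1e-6)
        assert general.sigma2_e == pytest.approx(closed.sigma2_e, rel=1e-6)
        assert general.aic is not None and np.isfinite(general.aic)

    def test_subject_level_covariate_leaves_tdi_parameters_unchanged(self, bp_like_data):
        """Covariates that explain between-subject variation do not move the
        device effect or the error variance the TDI is built from."""
        base = fit_reml_general(bp_like_data)
        frame = bp_like_data.frame.copy()
        rng = np.random.default_rng(21)
        per_subject = dict(
            zip(sorted(frame["subject"].unique()),
                rng.normal(size=frame["subject"].nunique()))
        )
        frame["marker"] = frame["subject"].map(per_subject)
        with_cov = fit_reml_general(
            AgreementData.from_frame(frame, device_order=bp_like_data.devices)
        )
        assert with_cov.beta_diff == pytest.approx(base.beta_diff, abs=1e-6)
        assert with_cov.sigma2_e == pytest.approx(base.sigma2_e, rel=1e-3)
        assert "marker" in with_cov.covariate_effects

    def test_constant_covariate_rejected(self, bp_like_data):
        frame = bp_like_data.frame.copy()
        frame["flat"] = 1.0
        data = AgreementData.from_frame(frame, device_order=bp_like_data.devices)
        with pytest.raises(FitError):
            fit_reml_general(data)


class TestDifferenceParams:
    def test_total_distribution_from_case_estimates(self, case_fit):
        params = difference_params(case_fit, "total")
        assert params.mu_D == pytest.approx(2.174)
        assert params.sigma_D == pytest.approx(10.283, abs=5e-4)
        assert params.N == 2 * 384 * 2
        assert params.df_convention == "no_interaction"

    def test_intra_distribution(self, case_fit):
        params = difference_params(case_fit, "intra")
        assert params.mu_D == 0.0
        assert params.sigma_D == pytest.approx(math.sqrt(2 * 52.867), rel=1e-12)

    def test_inter_distribution(self, case_fit):
        params = difference_params(case_fit, "inter")
        assert params.mu_D == pytest.approx(2.174)
        assert params.sigma_D == pytest.approx(math.sqrt(52.867), rel=1e-12)

    def test_total_spread_at_least_inter(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            values = rng.normal(0, 2, size=(10, 2, 3))
            fit = fit_balanced_vc(_to_agreement(values), include_interaction=True)
            total = difference_params(fit, "total")
            inter = difference_params(fit, "inter")
            assert total.sigma_D >= inter.sigma_D

    def test_degenerate_distribution_rejected(self):
        values = np.full((4, 2, 2), 1.0)
        fit = fit_balanced_vc(_to_agreement(values))
        with pytest.raises(Exception, match="degenerate"):
            difference_params(fit, "total")
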