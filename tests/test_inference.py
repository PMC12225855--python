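import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

import foodmsm as fm
from foodmsm.inference import (
    FitResult,
    _loglik_and_grad,
    _PanelDesign,
    crude_initial_parameters,
    pack_parameters,
    parameter_names,
    unpack_parameters,
)
from foodmsm.panel import COVARIATE_COLUMNS
from foodmsm.selection import TransitionCovariateStructure, predefined_structures


def _single_cov_structure():
    return TransitionCovariateStructure(
        covariate_placements={(1, 2): ("sex_female",)}, label="tiny"
    )


class TestIntensityAt:
    def test_zero_covariates_give_baseline(self):
        params, structure = fm.default_true_parameters()
        z = {c: 0.0 for c in COVARIATE_COLUMNS}
        Q = fm.intensity_at(params, structure, z)
        assert Q.rate(1, 2) == pytest.approx(0.273804)
        assert Q.rate(4, 3) == pytest.approx(0.766246)

    def test_zero_betas_ignore_covariates(self):
        structure = _single_cov_structure()
        params = fm.ModelParameters(
            log_baseline={t: np.log(0.2) for t in structure.allowed_transitions},
            betas={((1, 2), "sex_female"): 0.0},
        )
        Q0 = fm.intensity_at(params, structure, {"sex_female": 0})
        Q1 = fm.intensity_at(params, structure, {"sex_female": 1})
        assert np.allclose(Q0.q, Q1.q)

    def test_proportional_multiplication(self):
        structure = _single_cov_structure()
        params = fm.ModelParameters(
            log_baseline={t: np.log(0.2) for t in structure.allowed_transitions},
            betas={((1, 2), "sex_female"): np.log(2.0)},
        )
        Q = fm.intensity_at(params, structure, {"sex_female": 1})
        assert Q.rate(1, 2) == pytest.approx(0.4)

    def test_missing_covariate_rejected(self):
        structure = _single_cov_structure()
        params = fm.ModelParameters(
            log_baseline={t: np.log(0.2) for t in structure.allowed_transitions},
            betas={((1, 2), "sex_female"): 0.1},
        )
        with pytest.raises(fm.ValidationError):
            fm.intensity_at(params, structure, {})


class TestLogLikelihood:
    def _one_interval_panel(self, dt=1.5, x0=1, x1=2):
        frame = pd.DataFrame(
            [
                {"id": 1, "time": 0.0, "state": x0, **{c: 0 for c in COVARIATE_COLUMNS}},
                {"id": 1, "time": dt, "state": x1, **{c: 0 for c in COVARIATE_COLUMNS}},
            ]
        )
        return fm.PanelDataset(frame)

    def test_single_interval_equals_log_expm_entry(self):
        params, structure = fm.default_true_parameters()
        ds = self._one_interval_panel()
        ll = fm.panel_log_likelihood(params, structure, ds)
        Q = fm.intensity_at(params, structure, {c: 0.0 for c in COVARIATE_COLUMNS})
        expected = np.log(fm.transition_probability_matrix(Q, 1.5).prob(1, 2))
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_additive_over_duplicated_subjects(self, sim_panel):
        params, structure = fm.default_true_parameters()
        ds, _ = fm.drop_single_observation_subjects(sim_panel.dataset)
        base = fm.panel_log_likelihood(params, structure, ds)
        dup = ds.frame.copy()
        dup["id"] = dup["id"].astype(str) + "_copy"
        doubled = fm.PanelDataset(pd.concat([ds.frame, dup], ignore_index=True))
        assert fm.panel_log_likelihood(params, structure, doubled) == pytest.approx(
            2 * base, rel=1e-12
        )

    def test_invariant_to_subject_relabelling(self, sim_panel):
        params, structure = fm.default_true_parameters()
        ds, _ = fm.drop_single_observation_subjects(sim_panel.dataset)
        base = fm.panel_log_likelihood(params, structure, ds)
        ids = ds.frame["id"].unique()
        mapping = dict(zip(ids, np.random.default_rng(1).permutation(ids)))
        shuffled = ds.frame.copy()
        shuffled["id"] = shuffled["id"].map(mapping)
        assert fm.panel_log_likelihood(
            params, structure, fm.PanelDataset(shuffled)
        ) == pytest.approx(base, rel=1e-12)

    def test_brute_force_oracle(self, sim_panel):
        """Group-wise likelihood equals a per-interval loop of log expm
        entries."""
        params, structure = fm.default_true_parameters()
        ds, _ = fm.drop_single_observation_subjects(sim_panel.dataset)
        small = fm.PanelDataset(
            ds.frame[ds.frame["id"].isin(ds.subjects()[:40])]
        )
        ll = fm.panel_log_likelihood(params, structure, small)
        oracle = 0.0
        for _, g in small.frame.groupby("id"):
            g = g.sort_values("time")
            for k in range(len(g) - 1):
                z = {c: float(g.iloc[k][c]) for c in COVARIATE_COLUMNS}
                Q = fm.intensity_at(params, structure, z)
                dt = g.iloc[k + 1]["time"] - g.iloc[k]["time"]
                P = expm(dt * Q.q)
                oracle += np.log(P[int(g.iloc[k]["state"]) - 1, int(g.iloc[k + 1]["state"]) - 1])
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_gradient_matches_finite_differences(self, sim_panel):
        params, structure = fm.default_true_parameters()
        ds, _ = fm.drop_single_observation_subjects(sim_panel.dataset)
        design = _PanelDesign(ds, structure)
        rng = np.random.default_rng(2)
        theta = pack_parameters(params, structure) + rng.normal(0, 0.2, structure.n_parameters())
        _, grad = _loglik_and_grad(theta, design)
        h = 1e-6
        for k in rng.choice(len(theta), size=8, replace=False):
            up, dn = theta.copy(), theta.copy()
            up[k] += h
            dn[k] -= h
            fd = (_loglik_and_grad(up, design)[0] - _loglik_and_grad(dn, design)[0]) / (2 * h)
            assert grad[k] == pytest.approx(fd, rel=1e-4, abs=1e-6)


class TestFit:
    def test_parameter_recovery_within_three_se(self, recovery_fit):
        design, ds, fit = recovery_fit
        params, structure = design.resolved_parameters()
        truth = pack_parameters(params, structure)
        assert fit.converged
        assert np.all(np.abs(fit.theta - truth) < 3 * fit.se)

    def test_refit_from_mle_is_fixed_point(self, recovery_fit):
        design, ds, fit = recovery_fit
        refit = fm.fit_msm(
            ds, fit.structure, init=fit.params, compute_covariance=False
        )
        assert refit.loglik == pytest.approx(fit.loglik, abs=1e-6)

    def test_aic_identity(self, recovery_fit):
        _, _, fit = recovery_fit
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.df, abs=1e-8)

    def test_covariance_symmetric_psd(self, recovery_fit):
        _, _, fit = recovery_fit
        cov = fit.covariance
        assert np.allclose(cov, cov.T)
        assert np.linalg.eigvalsh(cov).min() > 0

    def test_crude_initializer_positive_and_finite(self, sim_panel):
        ds, _ = fm.drop_single_observation_subjects(sim_panel.dataset)
        init = crude_initial_parameters(ds, predefined_structures()["null"])
        vals = np.array(list(init.log_baseline.values()))
        assert np.all(np.isfinite(vals))

    def test_pack_unpack_round_trip(self):
        params, structure = fm.default_true_parameters()
        theta = pack_parameters(params, structure)
        again = pack_parameters(unpack_parameters(theta, structure), structure)
        assert np.allclose(theta, again)
        assert len(theta) == structure.n_parameters() == len(parameter_names(structure))


def _fit_with_se(structure, theta, se):
    """Hand-built converged FitResult with a diagonal covariance."""
    theta = np.asarray(theta, dtype=float)
    return FitResult(
        params=unpack_parameters(theta, structure),
        structure=structure,
        loglik=0.0,
        df=structure.n_parameters(),
        aic=2.0 * structure.n_parameters(),
        covariance=np.diag(np.asarray(se, dtype=float) ** 2),
        converged=True,
        n_subjects=1,
        n_transitions_observed=1,
        theta=theta,
        param_names=tuple(parameter_names(structure)),
    )


class TestWaldIntervals:
    def test_baseline_ci_multiplicatively_symmetric(self):
        """A log-scale interval for rate 0.273804 with se 0.0797
        back-computes the published-style bounds."""
        structure = TransitionCovariateStructure(allowed_transitions=((1, 2),))
        fit = _fit_with_se(structure, [np.log(0.273804)], [0.0797])
        ci = fm.baseline_intensity_cis(fit)
        assert ci.loc["1->2", "estimate"] == pytest.approx(0.273804)
        assert ci.loc["1->2", "lower"] == pytest.approx(0.2342, abs=2e-4)
        assert ci.loc["1->2", "upper"] == pytest.approx(0.3201, abs=2e-4)
        ratio_lo = ci.loc["1->2", "estimate"] / ci.loc["1->2", "lower"]
        ratio_hi = ci.loc["1->2", "upper"] / ci.loc["1->2", "estimate"]
        assert ratio_lo == pytest.approx(ratio_hi, rel=1e-12)

    def test_zero_se_degenerate_interval(self):
        structure = TransitionCovariateStructure(allowed_transitions=((1, 2),))
        fit = _fit_with_se(structure, [np.log(0.5)], [0.0])
        ci = fm.baseline_intensity_cis(fit)
        assert ci.loc["1->2", "lower"] == ci.loc["1->2", "upper"] == pytest.approx(0.5)

    def test_hazard_ratio_back_calculation(self):
        structure = _single_cov_structure()
        theta = [np.log(0.2)] * 12 + [0.21071]
        fit = _fit_with_se(structure, theta, [0.01] * 12 + [0.06589])
        hr = fm.hazard_ratios(fit).iloc[0]
        assert hr["hr"] == pytest.approx(1.2345, abs=1e-4)
        assert hr["lower"] == pytest.approx(1.0848, abs=1e-3)
        assert hr["upper"] == pytest.approx(1.4050, abs=1e-3)
        assert hr["significant"]

    def test_negative_coefficient_hazard_ratio(self):
        structure = _single_cov_structure()
        theta = [np.log(0.2)] * 12 + [-0.3627]
        fit = _fit_with_se(structure, theta, [0.01] * 12 + [0.5])
        hr = fm.hazard_ratios(fit).iloc[0]
        assert hr["hr"] == pytest.approx(0.6958, abs=1e-4)
        assert not hr["significant"]

    def test_zero_beta_straddles_one(self):
        structure = _single_cov_structure()
        theta = [np.log(0.2)] * 12 + [0.0]
        fit = _fit_with_se(structure, theta, [0.01] * 12 + [0.3])
        hr = fm.hazard_ratios(fit).iloc[0]
        assert hr["hr"] == pytest.approx(1.0)
        assert hr["lower"] < 1 < hr["upper"]
        assert not hr["significant"]

    def test_non_converged_fit_refused(self):
        structure = TransitionCovariateStructure(allowed_transitions=((1, 2),))
        fit = _fit_with_se(structure, [np.log(0.5)], [0.1])
        broken = FitResult(**{**fit.__dict__, "converged": False})
        with pytest.raises(fm.ConvergenceError):
            fm.baseline_intensity_cis(broken)
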