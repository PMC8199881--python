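import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from cartqsp import (
    PatientCovariates,
    VariabilityParams,
    classify_subpop,
    fit_population,
    individual_loglik,
    lrt_covariate,
    marginal_loglik,
)
from cartqsp.estimation import FitResult, sir_core
from cartqsp.population import individual_from_eta


def _obs(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "time_days", "species", "value", "censored"]
    )


@pytest.fixture(scope="module")
def toy_patient(params):
    """Rich noise-free synthetic patient simulated at known individual params."""
    sp, vp = params
    cov = PatientCovariates("T1", 0, 1.0, 150.0)
    ind = individual_from_eta(sp, cov, "reference", eta_Vmax1=0.3)
    from cartqsp.dynamics import solve

    times = np.array([3.0, 7.0, 10.0, 14.0, 21.0, 26.0])
    states = solve(ind, sp, times)
    rows = []
    for i, t in enumerate(times):
        for j, s in enumerate(("TN", "TCM", "TEM", "TEFF", "CD19")):
            rows.append(("T1", t, s, states[i, j], False))
    return _obs(rows), ind, cov


class TestIndividualLoglik:
    def test_noise_free_patient_gives_constant_terms_only(self, params, toy_patient):
        sp, vp = params
        obs, ind, cov = toy_patient
        ll = individual_loglik(obs, ind, sp, vp.sigma2, cov=cov)
        const = sum(
            -0.5 * math.log(2 * math.pi * vp.sigma2[s])
            for s in ("TN", "TCM", "TEM", "TEFF", "CD19")
        ) * 6
        assert ll == pytest.approx(const, abs=1e-4)

    def test_truth_is_local_optimum_in_vmax1(self, params, toy_patient):
        sp, vp = params
        obs, ind, cov = toy_patient
        base = individual_loglik(obs, ind, sp, vp.sigma2, cov=cov)
        for factor in (0.5, 0.8, 1.25, 2.0):
            import dataclasses

            perturbed = dataclasses.replace(ind, Vmax1_i=ind.Vmax1_i * factor)
            assert individual_loglik(obs, perturbed, sp, vp.sigma2, cov=cov) < base

    def test_censored_only_patient_with_tiny_predictions(self, params):
        sp, vp = params
        cov = PatientCovariates("C1", 0, 1.0, 50.0)
        # strong expansion and killing drive the tumor far below the LOQ
        ind = individual_from_eta(sp, cov, "reference",
                                  eta_Vmax1=1.5, eta_Vmax5_2=2.5)
        obs = _obs([("C1", 180.0, "CD19", 0.0, True)])
        ll = individual_loglik(obs, ind, sp, vp.sigma2, cov=cov)
        assert -0.05 < ll <= 0.0

    def test_rejects_empty(self, params, toy_patient):
        sp, vp = params
        _, ind, cov = toy_patient
        with pytest.raises(ValueError):
            individual_loglik(_obs([]), ind, sp, vp.sigma2, cov=cov)


class TestMarginalLoglik:
    def test_reduces_to_plugin_likelihood_without_iiv(self, params, toy_patient):
        sp, vp = params
        obs, _, cov = toy_patient
        vp0 = VariabilityParams(0.0, 0.0, dict(vp.sigma2))
        lm = marginal_loglik(obs, sp, vp0, cov, "reference")
        ind0 = individual_from_eta(sp, cov, "reference")
        il = individual_loglik(obs, ind0, sp, vp.sigma2, cov=cov)
        assert lm == pytest.approx(il, abs=1e-10)

    def test_matches_quadrature_on_one_eta_toy(self, params):
        sp, vp = params
        cov = PatientCovariates("Q1", 0, 1.0, 150.0)
        omega2 = 0.2
        vp1 = VariabilityParams(omega2, 0.0, dict(vp.sigma2))
        # naive-cell series at the design days (moderately perturbed from a
        # simulated truth) — a posterior well inside the Laplace regime
        obs = _obs(
            [
                ("Q1", 7.0, "TN", 3.8385, False),
                ("Q1", 14.0, "TN", 2.9897, False),
                ("Q1", 26.0, "TN", 1.0856, False),
            ]
        )
        lm = marginal_loglik(obs, sp, vp1, cov, "reference", hessian="fd")

        def integrand(eta):
            ind = individual_from_eta(sp, cov, "reference", eta_Vmax1=eta)
            ll = individual_loglik(obs, ind, sp, vp1.sigma2, cov=cov)
            prior = -0.5 * math.log(2 * math.pi * omega2) - eta**2 / (2 * omega2)
            return math.exp(ll + prior)

        val, err = quad(integrand, -5.0, 5.0, limit=200)
        assert math.exp(lm) == pytest.approx(val, rel=0.01)

    def test_finite_on_flat_mismatched_data(self, params):
        sp, vp = params
        cov = PatientCovariates("F1", 0, 1.0, 10.0)
        obs = _obs(
            [("F1", t, "TN", 500.0, False) for t in (7.0, 14.0, 26.0)]
        )
        lm = marginal_loglik(obs, sp, vp, cov, "reference")
        assert math.isfinite(lm)


class TestFitPopulation:
    def test_refit_from_truth_does_not_increase_ofv(self, recovery_model):
        assert recovery_model.ofv_ <= recovery_model.ofv_history_[0] + 1e-9

    def test_ofv_history_monotone(self, recovery_model):
        hist = np.asarray(recovery_model.ofv_history_)
        assert (np.diff(hist) <= 1e-12).all()

    def test_vmax1_baselines_recovered(self, recovery_model):
        est = recovery_model.structural_
        assert est.Vmax1_base_ref == pytest.approx(0.00846, rel=0.30)
        assert est.Vmax1_base_low == pytest.approx(0.000700, rel=0.30)

    def test_mixture_proportion_recovered(self, recovery_model):
        assert recovery_model.structural_.MIXP == pytest.approx(0.803, abs=0.12)

    def test_fixed_parameters_untouched(self, params, recovery_model):
        sp, _ = params
        est = recovery_model.structural_
        for name in ("kp1", "kp2", "kp3", "k5", "K0", "ke1", "ke2", "ke3",
                     "Vmax5_1", "Vmax5_3", "Vmax5_4", "KM1", "KM5"):
            assert getattr(est, name) == getattr(sp, name)

    def test_result_json_round_trip(self, recovery_model, tmp_path):
        path = tmp_path / "fit.json"
        recovery_model.result_.to_json(path)
        back = FitResult.from_json(path)
        assert back.ofv == pytest.approx(recovery_model.ofv_)
        assert back.structural.Vmax1_base_ref == pytest.approx(
            recovery_model.structural_.Vmax1_base_ref
        )
        assert len(back.individual_estimates) == 100


class TestClassifySubpop:
    def test_responsibilities_in_unit_interval(self, recovery_model):
        r = recovery_model.individual_estimates_["responsibility_ref"]
        assert ((r >= 0) & (r <= 1)).all()

    def test_classification_accuracy(self, recovery_model, recovery_cohort):
        cls = classify_subpop(recovery_model).set_index("patient_id")
        truth = {p: v["subpop"] for p, v in recovery_cohort.truth.items()}
        acc = np.mean([cls.loc[p, "subpop_label"] == truth[p] for p in truth])
        assert acc >= 0.90

    def test_nonidentifiable_mixture_gives_prior_responsibility(self, params):
        sp, vp = params
        # (numerically) identical subpopulation typical values, no Vmax1 IIV:
        # the data cannot tell the subpopulations apart, so the posterior
        # responsibility must equal the prior mixing proportion
        sp_eq = sp.replace(Vmax1_base_low=sp.Vmax1_base_ref * (1 - 1e-12),
                           CD4CD8_exp=0.0, ASCT_Vmax1=0.0)
        vp_eq = VariabilityParams(0.0, vp.omega2_Vmax5_2, dict(vp.sigma2))
        from cartqsp import generate_cohort

        ds = generate_cohort(5, sp_eq, vp_eq, rng=17)
        fit = fit_population(ds, sp_eq, vp_eq, free=())
        r = fit.individual_estimates["responsibility_ref"]
        assert np.allclose(r, sp_eq.MIXP, atol=1e-6)


class TestLrtCovariate:
    def test_identical_fits_not_significant(self):
        res = lrt_covariate(100.0, 100.0)
        assert res.delta_ofv == 0.0
        assert not res.significant

    def test_threshold_is_3_84(self):
        assert lrt_covariate(100.0, 103.85).significant
        assert not lrt_covariate(100.0, 103.83).significant

    def test_simulated_asct_effect_detected(self, lrt_fits):
        full, reduced = lrt_fits
        res = lrt_covariate(full, reduced)
        assert res.delta_ofv > 3.84
        assert res.significant

    def test_recovered_asct_effect_plausible(self, lrt_fits):
        full, _ = lrt_fits
        assert full.structural.ASCT_Vmax1 == pytest.approx(2.53, rel=0.5)

    def test_negative_delta_warns(self):
        with pytest.warns(UserWarning, match="ΔOFV"):
            lrt_covariate(100.0, 99.0)


class TestSigmaRecovery:
    def test_residual_cvs_recovered(self, sigma_fit):
        from cartqsp import omega2_to_cv

        fit, vp_truth = sigma_fit
        for s in ("TN", "TCM", "TEM", "TEFF", "CD19"):
            est_cv = omega2_to_cv(fit.variability.sigma2[s])
            true_cv = omega2_to_cv(vp_truth.sigma2[s])
            assert est_cv == pytest.approx(true_cv, rel=0.25)


class TestSir:
    def test_zero_variance_proposal_returns_point_estimate(self):
        center = np.array([1.5, -2.0])
        res, ess = sir_core(lambda x: 0.0, center, np.zeros((2, 2)),
                            schedule=((100, 50),), rng=0)
        assert np.allclose(res, center)
        assert res.std(axis=0).max() == 0.0

    def test_conjugate_normal_oracle(self):
        Sigma = np.array([[0.04, 0.01], [0.01, 0.09]])
        center = np.array([1.0, 2.0])
        inv = np.linalg.inv(Sigma)

        def loglik(x):
            d = x - center
            return -0.5 * d @ inv @ d

        res, _ = sir_core(loglik, center, Sigma,
                          schedule=((2000, 500), (2000, 1000)), rng=5)
        sd = res.std(axis=0, ddof=1)
        assert sd == pytest.approx(np.sqrt(np.diag(Sigma)), rel=0.10)
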