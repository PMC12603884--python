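"""Estimation engine: likelihood correctness, recovery, covariate testing."""

import numpy as np
import pandas as pd
import pytest

from sedpkpd import io, models, nlme, trial
from tests.conftest import noise_free_clonidine


def _linear_problem(y, sigma, omega, mu_init=5.0):
    """One observation per subject, y = mu + eta + eps: closed-form marginal."""
    n = y.size
    params = [nlme.Param("mu", mu_init),
              nlme.Param("omega_mu", omega, kind="omega"),
              nlme.Param("sigma_add", sigma, kind="sigma")]

    def predict(values, eta):
        return values["mu"] + eta[..., 0:1] * np.ones(1)

    return nlme.NLMEProblem(
        params=params, eta_names=["mu"],
        error_models={0: nlme.ErrorModel(add="sigma_add")},
        y=y[:, None], mask=np.ones((n, 1), bool),
        obs_class=np.zeros((n, 1), int), predict=predict)


class TestLaplaceExactness:
    def test_matches_closed_form_gaussian_marginal(self):
        """For a linear Gaussian model the Laplace approximation is exact:
        -2logL must equal the analytic N(mu, omega^2+sigma^2) deviance."""
        rng = np.random.default_rng(1)
        y = 5.0 + rng.normal(0, 1.0, 12)
        sigma, omega, mu = 0.7, 1.3, 4.6
        prob = _linear_problem(y, sigma, omega)
        ofv, _, _ = nlme.laplace_ofv(prob, {"mu": mu, "omega_mu": omega,
                                            "sigma_add": sigma})
        var = omega ** 2 + sigma ** 2
        expect = np.sum((y - mu) ** 2 / var + np.log(var) + np.log(2 * np.pi))
        assert ofv == pytest.approx(expect, rel=1e-6)

    def test_ebe_modes_shrink_towards_zero(self):
        rng = np.random.default_rng(2)
        y = 5.0 + rng.normal(0, 1.5, 20)
        prob = _linear_problem(y, 1.0, 1.0)
        _, eta, _ = nlme.laplace_ofv(prob, {"mu": 5.0, "omega_mu": 1.0,
                                            "sigma_add": 1.0})
        # conditional mode of the linear model: (y-mu)*om2/(om2+sig2)
        assert eta[:, 0] == pytest.approx((y - 5.0) / 2.0, abs=1e-3)


class TestFitting:
    def test_noise_free_data_identifies_generating_values(self):
        ds, spar, pk0 = noise_free_clonidine()
        prob = models.clonidine_pk_problem(
            ds, init=dict(cl=20.0, v=150.0, omega_cl=1e-6, omega_v=1e-6,
                          sigma_prop=0.05),
            fixed=("omega_cl", "omega_v", "sigma_prop"))
        fit = nlme.fit_population(prob, n_starts=1, compute_se=False)
        # within optimiser (finite-difference gradient) tolerance
        assert fit.estimates["cl"] == pytest.approx(28.0, rel=1e-2)
        assert fit.estimates["v"] == pytest.approx(202.4, rel=1e-2)

    def test_final_ofv_not_above_initial(self, clon_trial):
        ds, _ = clon_trial
        fit = nlme.fit_population(models.clonidine_pk_problem(ds),
                                  n_starts=1, compute_se=False)
        assert fit.ofv <= fit.ofv_init + 1e-9

    def test_same_seed_reproduces_fit(self):
        ds, _, _ = noise_free_clonidine(n=6)
        kw = dict(n_starts=2, seed=42, compute_se=False)
        f1 = nlme.fit_population(models.clonidine_pk_problem(ds), **kw)
        f2 = nlme.fit_population(models.clonidine_pk_problem(ds), **kw)
        assert f1.estimates == f2.estimates
        assert f1.ofv == f2.ofv

    def test_missing_observations_rejected(self):
        with pytest.raises(ValueError, match="without observations"):
            nlme.NLMEProblem(
                params=[nlme.Param("mu", 1.0),
                        nlme.Param("omega_mu", 1.0, kind="omega"),
                        nlme.Param("sigma_add", 1.0, kind="sigma")],
                eta_names=["mu"],
                error_models={0: nlme.ErrorModel(add="sigma_add")},
                y=np.zeros((2, 1)),
                mask=np.array([[True], [False]]),
                obs_class=np.zeros((2, 1), int), predict=lambda v, e: e)


class TestBLQ:
    def _tiny(self):
        ds, _, _ = noise_free_clonidine(n=3)
        return ds

    def test_blq_set_to_half_loq(self):
        ds = self._tiny()
        cls = io.observation_class(ds)
        idx = ds.index[(ds.EVID == 0) & (cls == io.OBS_CLON_CONC)][0]
        ds.loc[idx, ["DV", "BLQ"]] = [np.nan, 1]
        out = nlme.blq_impute(ds, {io.OBS_CLON_CONC: 0.10})
        assert out.loc[idx, "DV"] == pytest.approx(0.05)
        assert len(out) == len(ds)

    def test_non_blq_untouched(self):
        ds = self._tiny()
        out = nlme.blq_impute(ds, {io.OBS_CLON_CONC: 0.10})
        pd.testing.assert_frame_equal(out, ds)

    def test_missing_loq_raises(self):
        ds = self._tiny()
        cls = io.observation_class(ds)
        idx = ds.index[(ds.EVID == 0) & (cls == io.OBS_CLON_CONC)][0]
        ds.loc[idx, "BLQ"] = 1
        with pytest.raises(ValueError, match="no LOQ"):
            nlme.blq_impute(ds, {})


class TestCovariateTest:
    def test_identical_models_zero_delta(self, clon_trial):
        ds, _ = clon_trial
        fit = nlme.fit_population(models.clonidine_pk_problem(ds),
                                  n_starts=1, compute_se=False)
        res = nlme.covariate_test(fit, fit, df=0)
        assert res.delta_ofv == 0.0
        assert not res.significant

    def test_non_nested_rejected(self, clon_trial):
        ds, _ = clon_trial
        fit = nlme.fit_population(models.clonidine_pk_problem(ds),
                                  n_starts=1, compute_se=False)
        with pytest.raises(ValueError, match="nested"):
            nlme.covariate_test(fit, fit, df=1)

    @staticmethod
    def _simulate_with_creatinine(seed, beta):
        design = trial.TrialDesign(n_subjects=40,
                                   followup_range_h=(24.0, 48.0))
        pop = trial.generate_population(40, design, seed=seed)
        pop = pop.assign(ARM="clonidine")
        rng = np.random.default_rng(seed + 500)
        crea = rng.lognormal(np.log(40.0), 0.5, size=len(pop))  # umol/L
        mult = {int(i): float(np.exp(beta * (c - 40.0)))
                for i, c in zip(pop.ID, crea)}
        ds, _ = trial.simulate_trial(pop, seed=seed + 900, design=design,
                                     cl_multiplier=mult)
        ds = nlme.blq_impute(ds, {io.OBS_CLON_CONC: 0.1})
        cov = ({int(i): float(c) for i, c in zip(pop.ID, crea)}, 40.0)
        return ds, cov

    def test_true_covariate_effect_detected(self):
        """A real exponential creatinine effect on CL should win the LRT in
        the majority of replicates."""
        hits = 0
        for seed in range(3):
            ds, cov = self._simulate_with_creatinine(seed, beta=-0.02)
            base = nlme.fit_population(models.clonidine_pk_problem(ds),
                                       n_starts=1, compute_se=False)
            ext = nlme.fit_population(
                models.clonidine_pk_problem(ds, covariate_on_cl=cov),
                n_starts=1, compute_se=False)
            hits += nlme.covariate_test(base, ext).significant
        assert hits >= 2

    def test_null_covariate_rarely_selected(self):
        hits = 0
        for seed in range(4):
            ds, cov = self._simulate_with_creatinine(seed + 20, beta=0.0)
            base = nlme.fit_population(models.clonidine_pk_problem(ds),
                                       n_starts=1, compute_se=False)
            ext = nlme.fit_population(
                models.clonidine_pk_problem(ds, covariate_on_cl=cov),
                n_starts=1, compute_se=False)
            hits += nlme.covariate_test(base, ext).significant
        assert hits <= 1
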