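"""Structural PK models: maturation, allometry, infusion kinetics."""

import numpy as np
import pytest
from scipy.integrate import quad

from sedpkpd import pk


CLON_MAT = pk.MaturationParams(61.6, 2.42)
MID_MAT = pk.MaturationParams(73.6, 3.0)


class TestMaturation:
    def test_midpoint_is_half(self):
        assert pk.maturation(61.6, CLON_MAT) == pytest.approx(0.5, abs=1e-12)

    def test_saturates_towards_one(self):
        assert pk.maturation(616.0, CLON_MAT) > 0.99

    def test_direct_evaluation(self):
        # independent arithmetic: 40^3 / (73.6^3 + 40^3)
        expect = 40.0 ** 3 / (73.6 ** 3 + 40.0 ** 3)
        assert pk.maturation(40.0, MID_MAT) == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(0.1383, abs=5e-4)

    def test_monotone_in_pma(self):
        pma = np.linspace(25, 400, 200)
        m = pk.maturation(pma, CLON_MAT)
        assert np.all(np.diff(m) > 0)

    def test_nonpositive_pma_rejected(self):
        with pytest.raises(ValueError):
            pk.maturation(0.0, CLON_MAT)


class TestIndividualize:
    def test_reference_size_identity(self):
        cov = pk.CovariateRecord(weight=70.0, pma=1e7)
        p = pk.individualize_clonidine(28.0, 202.4, cov)
        assert p.cl == pytest.approx(28.0, rel=1e-4)
        assert p.v == pytest.approx(202.4, rel=1e-12)

    def test_volume_scales_linearly_with_weight(self):
        cov = pk.CovariateRecord(weight=35.0, pma=50.0)
        p = pk.individualize_clonidine(28.0, 202.4, cov)
        assert p.v == pytest.approx(202.4 * 35.0 / 70.0, rel=1e-12)

    def test_composed_clearance(self):
        # oracle composed by plain arithmetic
        mat = 40.0 ** 2.42 / (61.6 ** 2.42 + 40.0 ** 2.42)
        expect = 28.0 * (3.5 / 70.0) ** 0.75 * mat
        cov = pk.CovariateRecord(weight=3.5, pma=40.0)
        p = pk.individualize_clonidine(28.0, 202.4, cov)
        assert p.cl == pytest.approx(expect, rel=1e-12)

    def test_eta_enters_lognormally(self):
        cov = pk.CovariateRecord(weight=3.5, pma=40.0)
        a = pk.individualize_clonidine(28.0, 202.4, cov)
        b = pk.individualize_clonidine(28.0, 202.4, cov, eta_cl=0.5)
        assert b.cl == pytest.approx(a.cl * np.exp(0.5), rel=1e-12)

    def test_bad_covariates_rejected(self):
        with pytest.raises(ValueError):
            pk.CovariateRecord(weight=-1.0, pma=40.0)
        with pytest.raises(ValueError):
            pk.CovariateRecord(weight=float("nan"), pma=40.0)


class TestClonidineConc:
    params = pk.ClonidinePKParams(cl=28.0, v=202.4)

    def test_no_dose_is_zero(self):
        prof = pk.conc_clonidine(self.params, [], np.linspace(0, 24, 10))
        assert np.all(prof.values == 0.0)

    def test_steady_state_is_rate_over_cl(self):
        doses = [pk.DoseEvent(0.0, 210.0, 1e6)]
        css = pk.conc_clonidine(self.params, doses, [8e5]).values[0]
        assert css == pytest.approx(210.0 / 28.0, rel=1e-9)

    def test_single_infusion_matches_closed_form(self):
        # independent closed form for one zero-order infusion
        rate, dur = 280.0 / 0.25, 0.25
        k = 28.0 / 202.4
        t = np.linspace(0.01, 24.0, 60)
        tin = np.minimum(t, dur)
        expect = (rate / 28.0) * (1 - np.exp(-k * tin)) \
            * np.exp(-k * np.clip(t - dur, 0, None))
        got = pk.conc_clonidine(self.params, [pk.DoseEvent(0.0, rate, dur)],
                                t).values
        assert got == pytest.approx(expect, rel=1e-9)

    def test_analytic_matches_ode(self):
        doses = [pk.DoseEvent(0.0, 1120.0, 0.25), pk.DoseEvent(0.25, 210.0, 48.0)]
        t = np.linspace(0.05, 24.0, 40)
        a = pk.conc_clonidine(self.params, doses, t).values
        o = pk.conc_clonidine_ode(self.params, doses, t).values
        assert a == pytest.approx(o, rel=1e-6)

    def test_negative_params_rejected(self):
        with pytest.raises(ValueError):
            pk.ClonidinePKParams(cl=-1.0, v=10.0)


class TestMidazolamConc:
    params = pk.MidazolamPKParams(v=85.8, clm=33.4, vm=90.8, clom=211.6)

    def test_no_dose_is_zero(self):
        prof = pk.conc_midazolam(self.params, [], [1.0, 5.0])
        assert np.all(prof.values == 0.0) and np.all(prof.metabolite == 0.0)

    def test_steady_state_full_conversion(self):
        doses = [pk.DoseEvent(0.0, 330.0, 1e6, "midazolam")]
        prof = pk.conc_midazolam(self.params, doses, [8e5])
        assert prof.values[0] == pytest.approx(330.0 / 33.4, rel=1e-9)
        assert prof.metabolite[0] == pytest.approx(330.0 / 211.6, rel=1e-9)

    def test_metabolite_auc_is_dose_over_clom(self):
        doses = [pk.DoseEvent(0.0, 400.0, 0.5, "midazolam")]
        auc, err = quad(lambda t: pk.conc_midazolam(
            self.params, doses, [t]).metabolite[0], 0.0, 400.0, limit=400)
        assert auc == pytest.approx(200.0 / 211.6, rel=1e-6)

    def test_mass_balance(self):
        # dose = parent + metabolite amounts + cumulative metabolite output
        doses = [pk.DoseEvent(0.0, 400.0, 0.5, "midazolam")]
        t_end = 6.0
        prof = pk.conc_midazolam(self.params, doses, [t_end])
        a1 = prof.values[0] * self.params.v
        a2 = prof.metabolite[0] * self.params.vm
        k2 = self.params.clom / self.params.vm
        out, _ = quad(lambda t: k2 * pk.conc_midazolam(
            self.params, doses, [t]).metabolite[0] * self.params.vm,
            0.0, t_end, limit=200)
        assert a1 + a2 + out == pytest.approx(200.0, rel=1e-6)

    def test_analytic_matches_ode_random_regimens(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            p = pk.MidazolamPKParams(v=rng.uniform(5, 200),
                                     clm=rng.uniform(1, 60),
                                     vm=rng.uniform(5, 200),
                                     clom=rng.uniform(5, 300))
            doses = [pk.DoseEvent(float(rng.uniform(0, 10)),
                                  float(rng.uniform(10, 2000)),
                                  float(rng.uniform(0.1, 12)), "midazolam")
                     for _ in range(rng.integers(1, 5))]
            t = np.sort(rng.uniform(0.0, 30.0, 25))
            a = pk.conc_midazolam(p, doses, t)
            o = pk.conc_midazolam_ode(p, doses, t)
            scale = max(a.values.max(), 1e-9)
            assert np.allclose(a.values, o.values, rtol=1e-6,
                               atol=1e-6 * scale)
            mscale = max(a.metabolite.max(), 1e-9)
            assert np.allclose(a.metabolite, o.metabolite, rtol=1e-6,
                               atol=1e-6 * mscale)


def test_dose_linearity_superposition():
    """Scaling every rate by a constant scales all concentrations."""
    rng = np.random.default_rng(5)
    t = np.linspace(0.1, 30, 40)
    for _ in range(5):
        cp = pk.ClonidinePKParams(cl=float(rng.uniform(0.5, 40)),
                                  v=float(rng.uniform(2, 300)))
        doses = [pk.DoseEvent(float(rng.uniform(0, 8)),
                              float(rng.uniform(1, 500)),
                              float(rng.uniform(0.1, 10))) for _ in range(3)]
        scaled = [pk.DoseEvent(d.start_time, 3.7 * d.rate, d.duration)
                  for d in doses]
        c1 = pk.conc_clonidine(cp, doses, t).values
        c2 = pk.conc_clonidine(cp, scaled, t).values
        assert c2 == pytest.approx(3.7 * c1, rel=1e-12)
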