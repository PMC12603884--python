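"""Virtual-trial generator: population, dosing, observation scheme."""

import numpy as np
import pandas as pd
import pytest

from sedpkpd import io, pk, trial
from tests.conftest import noise_free_clonidine


class TestPopulation:
    def test_same_seed_identical(self):
        p1 = trial.generate_population(100, seed=3)
        p2 = trial.generate_population(100, seed=3)
        pd.testing.assert_frame_equal(p1, p2)

    def test_weight_monotone_across_pma_deciles(self):
        pop = trial.generate_population(1000, seed=1)
        dec = pd.qcut(pop.PMA, 10)
        med = pop.groupby(dec, observed=True).WT.median()
        assert np.all(np.diff(med.to_numpy()) >= 0)

    def test_weights_within_plausibility_corridor(self):
        pop = trial.generate_population(1000, seed=2)
        assert pop.WT.between(1.0, 25.0).all()
        assert pop.PMA.min() >= 36.0

    def test_pma_consistent_with_ga_plus_pna(self):
        pop = trial.generate_population(200, seed=4)
        assert pop.PMA.to_numpy() == pytest.approx(
            (pop.GA + pop.PNA / 7.0).to_numpy())

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            trial.TrialDesign(ga_range=(40.0, 36.0))


class TestDosing:
    def test_starting_doses_per_protocol(self):
        ev = trial.generate_dosing(4.0, 40.0, trial.CLONIDINE_PROTOCOL,
                                   "clonidine", 24.0, titrate=False)
        ld, inf = ev[0], ev[1]
        assert ld.amount == pytest.approx(8.0)  # 2 ug/kg x 4 kg
        assert ld.duration == pytest.approx(0.25)
        assert inf.rate == pytest.approx(4.0)  # 1 ug/kg/h x 4 kg

    def test_neonatal_halving(self):
        ev = trial.generate_dosing(4.0, 10.0, trial.CLONIDINE_PROTOCOL,
                                   "clonidine", 24.0, titrate=False)
        assert ev[0].amount == pytest.approx(4.0)  # halved loading dose
        assert ev[1].rate == pytest.approx(2.0)

    def test_titration_off_constant_rate(self):
        ev = trial.generate_dosing(3.0, 60.0, trial.MIDAZOLAM_PROTOCOL,
                                   "midazolam", 48.0, titrate=False)
        assert len(ev) == 2
        assert ev[1].duration == pytest.approx(48.0 - 0.25)

    def test_titration_raises_rate_when_undersedated(self):
        # score stuck above the band -> rate ratchets up to the cap
        ev = trial.generate_dosing(
            4.0, 100.0, trial.CLONIDINE_PROTOCOL, "clonidine", 24.0,
            titrate=True, score_fn=lambda t, events: 30.0)
        rates = [e.rate for e in ev[1:]]
        assert rates == sorted(rates)
        assert rates[-1] <= 4.0 * trial.CLONIDINE_PROTOCOL.rate_max_frac * 4.0

    def test_titration_lowers_rate_when_oversedated(self):
        ev = trial.generate_dosing(
            4.0, 100.0, trial.CLONIDINE_PROTOCOL, "clonidine", 24.0,
            titrate=True, score_fn=lambda t, events: 6.0)
        rates = [e.rate for e in ev[1:]]
        assert rates == sorted(rates, reverse=True)


class TestSimulateTrial:
    def test_same_seed_identical_dataset(self):
        design = trial.TrialDesign(n_subjects=6)
        pop = trial.generate_population(6, design, seed=8)
        d1, s1 = trial.simulate_trial(pop, seed=5, design=design)
        d2, s2 = trial.simulate_trial(pop, seed=5, design=design)
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(s1, s2)

    def test_pk_sample_count_in_range(self, clon_trial):
        ds, _ = clon_trial
        cls = io.observation_class(ds)
        counts = ds[(ds.EVID == 0)
                    & (cls == io.OBS_CLON_CONC)].groupby("ID").size()
        assert counts.between(2, 4).all()

    def test_scores_within_scale(self, clon_trial):
        ds, _ = clon_trial
        sc = ds[(ds.EVID == 0) & (ds.CMT == io.CMT_SCORE)].DV
        assert sc.between(6, 31).all()
        assert (sc == sc.round()).all()

    def test_noise_free_observations_equal_predictions(self):
        ds, spar, _ = noise_free_clonidine(n=4, seed=6)
        cls = io.observation_class(ds)
        for sid, grp in ds.groupby("ID"):
            row = spar[spar.ID == sid].iloc[0]
            ipk = pk.ClonidinePKParams(cl=row.CL, v=row.V)
            imp = grp[(grp.EVID == 1) & (grp.CMT == io.CMT_CENTRAL)]
            doses = [pk.DoseEvent(r.TIME, r.RATE, r.AMT / r.RATE)
                     for _, r in imp.iterrows()]
            obs = grp[(grp.EVID == 0) & (cls.loc[grp.index] ==
                                         io.OBS_CLON_CONC)]
            expect = pk.conc_clonidine(ipk, doses,
                                       obs.TIME.to_numpy(float)).values
            assert obs.DV.to_numpy(float) == pytest.approx(expect, rel=1e-9)

    def test_dataset_validates_and_round_trips(self, tmp_path, clon_trial):
        ds, _ = clon_trial
        rep = io.validate_dataset(ds)
        assert rep.ok and not rep.warnings
        path = tmp_path / "ds.csv"
        io.write_dataset(ds, path)
        back, rep2 = io.read_dataset(path)
        assert rep2.ok
        pd.testing.assert_frame_equal(
            back, ds.reset_index(drop=True), check_dtype=False)


def test_genotype_generator_codes_and_effect():
    g, mult = trial.generate_genotypes(200, 4, maf=0.25, seed=9,
                                       effect_snp=0,
                                       effect_per_allele=0.5)
    vals = g.drop(columns="ID").to_numpy().ravel()
    assert set(np.unique(vals[np.isfinite(vals)])) <= {0.0, 1.0, 2.0}
    assert mult == pytest.approx(np.exp(0.5 * g["snp1"].to_numpy()))
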