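#!/usr/bin/env python
"""Simulate one virtual sedation trial with the study's design.

28 ventilated children (1:1 clonidine:midazolam), neonates and infants
with weights tied to postmenstrual age, loading dose + titrated infusion
(halved under 28 days of postnatal age), 2-4 sparse plasma samples per
subject and COMFORT-B scores every 3 h. Concentrations and scores are
generated from the published final population models, so downstream fits
have a known truth to recover.

Writes results/trial/dataset.csv (NONMEM-style records) and
results/trial/subjects.csv (the generating individual parameters).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sedpkpd import io, trial  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "results" / "trial"
SEED = 2026


def main() -> None:
    design = trial.TrialDesign(n_subjects=28)
    pop = trial.generate_population(28, design, seed=SEED)
    ds, spar = trial.simulate_trial(pop, seed=SEED, design=design)
    rep = io.validate_dataset(ds)
    assert rep.ok, rep.errors

    OUT.mkdir(parents=True, exist_ok=True)
    io.write_dataset(ds, OUT / "dataset.csv")
    spar.to_csv(OUT / "subjects.csv", index=False)

    n_arm = pop.groupby("ARM").size()
    n_obs = ds[ds.EVID == 0].groupby(io.observation_class(ds)).size()
    print(f"simulated {len(pop)} subjects "
          f"({n_arm.get('clonidine', 0)} clonidine / "
          f"{n_arm.get('midazolam', 0)} midazolam)")
    print(f"observations by class (0=clon conc, 1=mid conc, 2=metabolite, "
          f"3=COMFORT-B):\n{n_obs.to_string()}")
    print(f"weights {pop.WT.min():.1f}-{pop.WT.max():.1f} kg, "
          f"PMA {pop.PMA.min():.0f}-{pop.PMA.max():.0f} weeks")
    print(f"wrote {OUT / 'dataset.csv'}")


if __name__ == "__main__":
    main()
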