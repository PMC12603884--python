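"""Shared fixtures: small simulated trials reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from sedpkpd import io, nlme, trial


@pytest.fixture(scope="session")
def pk_design():
    return trial.TrialDesign(n_subjects=110, followup_range_h=(24.0, 72.0))


@pytest.fixture(scope="session")
def clon_trial(pk_design):
    """A 50-subject clonidine-arm trial simulated from the final model."""
    pop = trial.generate_population(110, pk_design, seed=11)
    sub = pop[pop.ARM == "clonidine"].head(50).copy()
    ds, spar = trial.simulate_trial(sub, seed=1011, design=pk_design)
    ds = nlme.blq_impute(ds, pk_design.loq)
    return ds, spar


@pytest.fixture(scope="session")
def mid_trial(pk_design):
    """A 50-subject midazolam-arm trial simulated from the final model."""
    pop = trial.generate_population(110, pk_design, seed=12)
    sub = pop[pop.ARM == "midazolam"].head(50).copy()
    ds, spar = trial.simulate_trial(sub, seed=1012, design=pk_design)
    ds = nlme.blq_impute(ds, pk_design.loq)
    return ds, spar


def noise_free_clonidine(n=12, seed=3):
    """Tiny deterministic clonidine trial (no IIV, no residual error)."""
    design = trial.TrialDesign(n_subjects=n, followup_range_h=(24.0, 48.0),
                               titrate=False)
    pop = trial.generate_population(n, design, seed=seed)
    pop = pop.assign(ARM="clonidine")
    pk0 = trial.CLONIDINE_POP_PK.__class__(iiv_cl_cv=1e-6, iiv_v_cv=1e-6,
                                           err_prop=0.0)
    pd0 = trial.CLONIDINE_POP_PD.with_iiv(1e-6)
    ds, spar = trial.simulate_trial(pop, seed=seed, design=design,
                                    clon_pk=pk0, clon_pd=pd0)
    return ds, spar, pk0
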