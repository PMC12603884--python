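"""Published population parameter sets used as defaults and generating truth.

Typical values are standardised to a 70-kg reference; interindividual
variability (IIV) percentages are lognormal coefficients of variation, so
the log-scale standard deviation is omega = sqrt(log(1 + (CV/100)^2)).
Residual 'proportional %' values are 100*sigma of the proportional error;
additive components are in ng/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .pk import MaturationParams, CLONIDINE_MATURATION, MIDAZOLAM_MATURATION
from .pd import PDParams


def cv_to_omega(cv_percent: float) -> float:
    """Log-scale sd from a lognormal CV%: omega = sqrt(log(1+(cv/100)^2))."""
    return float(np.sqrt(np.log1p((cv_percent / 100.0) ** 2)))


def omega_to_cv(omega: float) -> float:
    return float(100.0 * np.sqrt(np.expm1(omega ** 2)))


@dataclass(frozen=True)
class ClonidinePopPK:
    """Final clonidine population PK model (one compartment)."""

    cl: float = 28.0  # L/h/70 kg
    v: float = 202.4  # L/70 kg
    iiv_cl_cv: float = 49.6  # %
    iiv_v_cv: float = 87.7  # %
    err_prop: float = 0.436  # proportional residual sd (fraction)
    maturation: MaturationParams = field(
        default_factory=lambda: MaturationParams(*CLONIDINE_MATURATION))

    @property
    def omega_cl(self) -> float:
        return cv_to_omega(self.iiv_cl_cv)

    @property
    def omega_v(self) -> float:
        return cv_to_omega(self.iiv_v_cv)


@dataclass(frozen=True)
class MidazolamPopPK:
    """Final midazolam population PK model (parent + 1-OH metabolite)."""

    v: float = 85.8  # L/70 kg
    clm: float = 33.4  # L/h/70 kg, metabolite formation clearance
    vm: float = 90.8  # L/70 kg
    clom: float = 211.6  # L/h/70 kg, metabolite elimination clearance
    iiv_clm_cv: float = 91.7  # %
    iiv_v_cv: float = 133.4  # %
    err_prop: float = 0.469  # parent proportional sd
    err_add: float = 1.24  # parent additive sd, ng/mL
    err_prop_m1: float = 0.574  # metabolite proportional sd
    err_add_m1: float = 0.023  # metabolite additive sd, ng/mL
    maturation: MaturationParams = field(
        default_factory=lambda: MaturationParams(*MIDAZOLAM_MATURATION))

    @property
    def omega_clm(self) -> float:
        return cv_to_omega(self.iiv_clm_cv)

    @property
    def omega_v(self) -> float:
        return cv_to_omega(self.iiv_v_cv)


@dataclass(frozen=True)
class PopPD:
    """Joint score-model parameters for one arm."""

    pd: PDParams
    iiv_ec50_cv: float  # %
    err_prop: float  # proportional residual sd on the score

    @property
    def omega_ec50(self) -> float:
        return cv_to_omega(self.iiv_ec50_cv)

    def with_iiv(self, cv_percent: float) -> "PopPD":
        return replace(self, iiv_ec50_cv=cv_percent)


#: final-model estimates: clonidine EC50 2.73 ng/mL, baseline B0 15.6,
#: PAEMAX fixed 11.8, shared TPS50 0.11 h, IIV EC50 525%, Err prop 28.2%
CLONIDINE_POP_PD = PopPD(
    pd=PDParams(ec50=2.73, b0=15.6, paemax=11.8, tps50=0.11),
    iiv_ec50_cv=525.0, err_prop=0.282)

#: midazolam EC50 186 ng/mL, PAEMAX 9.3, IIV EC50 246.6%, Err prop 24.9%;
#: the baseline is the subject's observed value, not a population parameter
MIDAZOLAM_POP_PD = PopPD(
    pd=PDParams(ec50=186.0, b0=15.6, paemax=9.3, tps50=0.11),
    iiv_ec50_cv=246.6, err_prop=0.249)

CLONIDINE_POP_PK = ClonidinePopPK()
MIDAZOLAM_POP_PK = MidazolamPopPK()
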