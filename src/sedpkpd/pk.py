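"""Structural pharmacokinetic models for clonidine and midazolam.

Clonidine follows a one-compartment model with first-order elimination.
Midazolam follows a one-compartment parent model whose entire elimination
flux forms 1-OH midazolam, described by a second (metabolite) compartment
with its own volume and elimination clearance.

Size and age enter the individual parameters through allometric scaling to
a 70-kg reference (exponent 0.75 on clearances, 1 on volumes) and a
postmenstrual-age (PMA) sigmoid maturation function on clearances.

Units used throughout: time h, weight kg, dose amounts ug, infusion rates
ug/h, volumes L, clearances L/h, concentrations ng/mL (1 ug in 1 L is
1 ng/mL, so no conversion factor is needed).

All dosing is by infusion; a bolus/loading dose is represented as a short
infusion (default 15 min), matching how the drugs are administered on the
unit. Concentrations are computed from the exact piecewise-analytic
solution of the linear system (superposition over dose events); an ODE
integrator route is kept as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

REF_WEIGHT_KG = 70.0

#: maturation constants (PMA50 weeks, Hill), fixed a priori per drug
CLONIDINE_MATURATION = (61.6, 2.42)
MIDAZOLAM_MATURATION = (73.6, 3.0)


@dataclass(frozen=True)
class MaturationParams:
    """Sigmoid maturation: fraction of adult clearance at a given PMA."""

    pma50: float  # weeks, PMA at 50% of adult clearance
    hill: float  # dimensionless shape

    def __post_init__(self) -> None:
        if self.pma50 <= 0 or self.hill <= 0:
            raise ValueError("maturation parameters must be strictly positive")


@dataclass(frozen=True)
class CovariateRecord:
    """Covariates driving individual PK parameters."""

    weight: float  # kg
    pma: float  # postmenstrual age, weeks
    pna: float = 0.0  # postnatal age, days
    sex: str = "F"

    def __post_init__(self) -> None:
        if not np.isfinite(self.weight) or self.weight <= 0:
            raise ValueError(f"weight must be positive, got {self.weight}")
        if not np.isfinite(self.pma) or self.pma <= 0:
            raise ValueError(f"pma must be positive, got {self.pma}")
        if self.pna < 0:
            raise ValueError(f"pna must be nonnegative, got {self.pna}")


@dataclass(frozen=True)
class ClonidinePKParams:
    cl: float  # L/h
    v: float  # L

    def __post_init__(self) -> None:
        if self.cl <= 0 or self.v <= 0:
            raise ValueError("clonidine PK parameters must be strictly positive")


@dataclass(frozen=True)
class MidazolamPKParams:
    v: float  # L, parent volume
    clm: float  # L/h, metabolite formation clearance (parent elimination)
    vm: float  # L, metabolite volume
    clom: float  # L/h, metabolite elimination clearance

    def __post_init__(self) -> None:
        if min(self.v, self.clm, self.vm, self.clom) <= 0:
            raise ValueError("midazolam PK parameters must be strictly positive")


@dataclass(frozen=True)
class DoseEvent:
    """A timed zero-order infusion. Loading doses are short infusions."""

    start_time: float  # h
    rate: float  # ug/h
    duration: float  # h
    drug: str = "clonidine"  # clonidine | midazolam | propofol

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("infusion rate must be nonnegative")
        if self.duration <= 0:
            raise ValueError("infusion duration must be positive")

    @property
    def amount(self) -> float:
        return self.rate * self.duration


@dataclass
class ConcProfile:
    times: np.ndarray  # h, ascending
    values: np.ndarray  # ng/mL, parent
    metabolite: np.ndarray | None = None  # ng/mL, when applicable


def maturation(pma, mat: MaturationParams):
    """Fraction of mature clearance at postmenstrual age ``pma`` (weeks).

    pma**hill / (pma50**hill + pma**hill): 0.5 exactly at pma50, strictly
    increasing, tending to 1 as pma grows.
    """
    pma = np.asarray(pma, dtype=float)
    if np.any(pma <= 0):
        raise ValueError("pma must be strictly positive")
    # compute on the log scale to avoid overflow for extreme hill exponents
    r = (pma / mat.pma50) ** mat.hill
    out = r / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def allometric_clearance(cl_std, weight, pma=None, mat: MaturationParams | None = None,
                         eta=0.0):
    """Individual clearance: CL_std*(WT/70)^0.75 * maturation * exp(eta)."""
    weight = np.asarray(weight, dtype=float)
    if np.any(~np.isfinite(weight)) or np.any(weight <= 0):
        raise ValueError("weight must be positive and finite")
    f = cl_std * (weight / REF_WEIGHT_KG) ** 0.75
    if mat is not None:
        if pma is None:
            raise ValueError("pma is required when a maturation function is applied")
        f = f * maturation(pma, mat)
    return f * np.exp(eta)


def allometric_volume(v_std, weight, eta=0.0):
    """Individual volume: V_std*(WT/70) * exp(eta). No maturation on volumes."""
    weight = np.asarray(weight, dtype=float)
    if np.any(~np.isfinite(weight)) or np.any(weight <= 0):
        raise ValueError("weight must be positive and finite")
    return v_std * (weight / REF_WEIGHT_KG) * np.exp(eta)


def individualize_clonidine(cl_std: float, v_std: float, cov: CovariateRecord,
                            eta_cl: float = 0.0, eta_v: float = 0.0,
                            mat: MaturationParams | None = None) -> ClonidinePKParams:
    """Individual clonidine parameters from typical values and covariates."""
    if mat is None:
        mat = MaturationParams(*CLONIDINE_MATURATION)
    return ClonidinePKParams(
        cl=float(allometric_clearance(cl_std, cov.weight, cov.pma, mat, eta_cl)),
        v=float(allometric_volume(v_std, cov.weight, eta_v)),
    )


def individualize_midazolam(v_std: float, clm_std: float, vm_std: float,
                            clom_std: float, cov: CovariateRecord,
                            eta_clm: float = 0.0, eta_v: float = 0.0,
                            mat: MaturationParams | None = None,
                            mature_clom: bool = True) -> MidazolamPKParams:
    """Individual midazolam parameters.

    Maturation applies to the formation clearance CLm and, by default, also
    to the metabolite elimination clearance CLom (``mature_clom=False``
    restricts it to CLm). Random effects are carried on CLm and V, matching
    the variability structure of the population model.
    """
    if mat is None:
        mat = MaturationParams(*MIDAZOLAM_MATURATION)
    clom_mat = mat if mature_clom else None
    return MidazolamPKParams(
        v=float(allometric_volume(v_std, cov.weight, eta_v)),
        clm=float(allometric_clearance(clm_std, cov.weight, cov.pma, mat, eta_clm)),
        vm=float(allometric_volume(vm_std, cov.weight)),
        clom=float(allometric_clearance(clom_std, cov.weight, cov.pma, clom_mat)),
    )


# ---------------------------------------------------------------------------
# analytic piecewise infusion kernels (vectorised; leading subject axis)
# ---------------------------------------------------------------------------

def _infusion_amount_1cpt(t, start, dur, rate, k):
    """Amount in a one-compartment system from zero-order infusion events.

    Broadcasts ``t`` of shape (..., O) against event arrays of shape
    (..., S); returns the superposed amount of shape (..., O). ``k`` has
    shape (...,) (elimination rate constant, 1/h). Events with rate 0 or
    NaN start act as padding.
    """
    t = np.asarray(t, dtype=float)[..., :, None]  # (..., O, 1)
    start = np.asarray(start, dtype=float)[..., None, :]  # (..., 1, S)
    dur = np.asarray(dur, dtype=float)[..., None, :]
    rate = np.asarray(rate, dtype=float)[..., None, :]
    k = np.asarray(k, dtype=float)[..., None, None]

    tau = np.clip(t - start, 0.0, None)  # time since event start
    tin = np.minimum(tau, dur)  # time infusing
    tpost = tau - tin  # time since infusion end
    with np.errstate(invalid="ignore"):
        contrib = (rate / k) * (-np.expm1(-k * tin)) * np.exp(-k * tpost)
    contrib = np.where(np.isfinite(contrib), contrib, 0.0)
    return contrib.sum(axis=-1)


def _infusion_amounts_parent_metabolite(t, start, dur, rate, k1, k2):
    """Amounts (A1, A2) for the parent->metabolite chain under infusions.

    dA1/dt = in(t) - k1*A1 ; dA2/dt = k1*A1 - k2*A2 (full conversion).
    Exact superposition solution; the k1 == k2 degeneracy is lifted by a
    relative 1e-9 nudge (error far below integrator cross-check tolerance).
    """
    t = np.asarray(t, dtype=float)[..., :, None]
    start = np.asarray(start, dtype=float)[..., None, :]
    dur = np.asarray(dur, dtype=float)[..., None, :]
    rate = np.asarray(rate, dtype=float)[..., None, :]
    k1 = np.asarray(k1, dtype=float)[..., None, None]
    k2 = np.asarray(k2, dtype=float)[..., None, None]
    k2 = np.where(np.abs(k2 - k1) < 1e-9 * k1, k1 * (1.0 + 1e-9), k2)

    tau = np.clip(t - start, 0.0, None)
    tin = np.minimum(tau, dur)
    u = tau - tin  # time since infusion end

    e1in = np.exp(-k1 * tin)
    e2in = np.exp(-k2 * tin)
    # state at the end of the infusing phase (duration tin)
    a1_end = (rate / k1) * (1.0 - e1in)
    a2_end = (rate / k2) * (1.0 - e2in) - rate / (k2 - k1) * (e1in - e2in)
    # free decay of the two-compartment chain for time u
    e1 = np.exp(-k1 * u)
    e2 = np.exp(-k2 * u)
    a1 = a1_end * e1
    a2 = a2_end * e2 + a1_end * k1 * (e1 - e2) / (k2 - k1)
    a1 = np.where(np.isfinite(a1), a1, 0.0)
    a2 = np.where(np.isfinite(a2), a2, 0.0)
    return a1.sum(axis=-1), a2.sum(axis=-1)


def _event_arrays(doses: Sequence[DoseEvent], drug: str):
    sel = [d for d in doses if d.drug == drug]
    if not sel:
        return (np.zeros(1), np.ones(1), np.zeros(1))
    return (np.array([d.start_time for d in sel]),
            np.array([d.duration for d in sel]),
            np.array([d.rate for d in sel]))


def conc_clonidine(params: ClonidinePKParams, doses: Sequence[DoseEvent],
                   times) -> ConcProfile:
    """Clonidine plasma concentration (ng/mL) at ``times`` (h, ascending)."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be ascending")
    start, dur, rate = _event_arrays(doses, "clonidine")
    k = params.cl / params.v
    amount = _infusion_amount_1cpt(times, start, dur, rate, k)
    return ConcProfile(times=times, values=amount / params.v)


def conc_midazolam(params: MidazolamPKParams, doses: Sequence[DoseEvent],
                   times) -> ConcProfile:
    """Midazolam parent and 1-OH metabolite concentrations (ng/mL)."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be ascending")
    start, dur, rate = _event_arrays(doses, "midazolam")
    k1 = params.clm / params.v
    k2 = params.clom / params.vm
    a1, a2 = _infusion_amounts_parent_metabolite(times, start, dur, rate, k1, k2)
    return ConcProfile(times=times, values=a1 / params.v, metabolite=a2 / params.vm)


# ---------------------------------------------------------------------------
# ODE cross-check route (independent of the analytic path)
# ---------------------------------------------------------------------------

def _rate_in(t, start, dur, rate):
    active = (t >= start) & (t < start + dur)
    return float(np.sum(rate * active))


def _integrate_piecewise(rhs_factory, n_states, start, dur, rate, times,
                         rtol, atol):
    """Integrate a linear system with piecewise-constant input.

    Integrates segment by segment between infusion on/off boundaries so the
    step controller never straddles a discontinuity; within each segment the
    input rate is constant.
    """
    times = np.asarray(times, dtype=float)
    tend = float(max(times.max(initial=0.0), (start + dur).max()) + 1e-9)
    breaks = np.unique(np.concatenate([[0.0], start, start + dur, [tend]]))
    breaks = breaks[(breaks >= 0.0) & (breaks <= tend)]
    y = np.zeros(n_states)
    out = np.zeros((n_states, times.size))
    out[:, times <= 0.0] = 0.0
    for a, b in zip(breaks[:-1], breaks[1:]):
        if b - a <= 0:
            continue
        rin = _rate_in(0.5 * (a + b), start, dur, rate)
        mask = (times > a) & (times <= b)
        te = times[mask]
        t_eval = te if (te.size and te[-1] == b) else np.append(te, b)
        sol = solve_ivp(rhs_factory(rin), (a, b), y, t_eval=t_eval,
                        rtol=rtol, atol=atol, dense_output=False)
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        out[:, mask] = sol.y[:, :te.size]
        y = sol.y[:, -1]  # state at b, carried into the next segment
    return out


def conc_clonidine_ode(params: ClonidinePKParams, doses: Sequence[DoseEvent],
                       times, rtol=1e-10, atol=1e-12) -> ConcProfile:
    """Clonidine concentration by numerical ODE integration (cross-check)."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    start, dur, rate = _event_arrays(doses, "clonidine")
    k = params.cl / params.v

    def factory(rin):
        return lambda t, y: [rin - k * y[0]]

    out = _integrate_piecewise(factory, 1, start, dur, rate, times, rtol, atol)
    return ConcProfile(times=times, values=out[0] / params.v)


def conc_midazolam_ode(params: MidazolamPKParams, doses: Sequence[DoseEvent],
                       times, rtol=1e-10, atol=1e-12) -> ConcProfile:
    """Midazolam parent + metabolite concentrations by ODE integration."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    start, dur, rate = _event_arrays(doses, "midazolam")
    k1 = params.clm / params.v
    k2 = params.clom / params.vm

    def factory(rin):
        return lambda t, y: [rin - k1 * y[0], k1 * y[0] - k2 * y[1]]

    out = _integrate_piecewise(factory, 2, start, dur, rate, times, rtol, atol)
    return ConcProfile(times=times, values=out[0] / params.v,
                       metabolite=out[1] / params.vm)
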