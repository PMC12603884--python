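"""Fittable population models: dataset -> NLME problem builders.

Each builder turns a trial dataset (the delimited format of
:mod:`sedpkpd.io`) into an :class:`~sedpkpd.nlme.NLMEProblem` whose
``predict`` is fully vectorised across subjects, so the estimation engine's
inner Newton iterations run on whole-population arrays.

Model structure mirrors the final trial models:

* clonidine: one-compartment PK, allometry + maturation on CL, lognormal
  IIV on CL and V, proportional residual error;
* midazolam: parent + 1-OH metabolite PK, maturation on both clearances,
  IIV on CLm and V, combined additive+proportional error per analyte;
* COMFORT-B score: inhibitory Emax (Emax fixed to 6) on the individual
  predicted concentration, postanesthesia washout for surgical subjects,
  IIV on EC50, proportional residual error. The clonidine arm estimates
  the nonsurgical baseline B0; the midazolam arm pins each subject's
  baseline to the observed pre-dose score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io
from .nlme import ErrorModel, NLMEProblem, Param
from .pd import BASE_FIXED, EMAX_FIXED, SCORE_MIN
from .pk import (CLONIDINE_MATURATION, MIDAZOLAM_MATURATION, MaturationParams,
                 REF_WEIGHT_KG, _infusion_amount_1cpt,
                 _infusion_amounts_parent_metabolite, maturation)


@dataclass
class SubjectBatch:
    """Padded per-subject arrays extracted from a dataset."""

    ids: np.ndarray  # (n,)
    wt: np.ndarray  # (n,)
    pma: np.ndarray  # (n,)
    surg: np.ndarray  # (n,) bool
    tsurg: np.ndarray  # (n,)
    dose_start: np.ndarray  # (n, S)
    dose_dur: np.ndarray  # (n, S)
    dose_rate: np.ndarray  # (n, S)
    obs_time: np.ndarray  # (n, O)
    y: np.ndarray  # (n, O)
    mask: np.ndarray  # (n, O) bool
    obs_class: np.ndarray  # (n, O) int


def _pad(rows, fill=0.0):
    width = max((len(r) for r in rows), default=0) or 1
    out = np.full((len(rows), width), fill, dtype=float)
    for i, r in enumerate(rows):
        out[i, :len(r)] = r
    return out


def build_batch(ds: pd.DataFrame, obs_classes, dose_cmt=io.CMT_CENTRAL
                ) -> SubjectBatch:
    """Extract padded arrays for the given observation classes."""
    cls = io.observation_class(ds)
    ids, wt, pma, surg, tsurg = [], [], [], [], []
    dstart, ddur, drate, otime, oval, ocls = [], [], [], [], [], []
    for sid, grp in ds.groupby("ID", sort=False):
        obs = grp[(grp["EVID"] == 0) & cls.loc[grp.index].isin(obs_classes)
                  & grp["DV"].notna()]
        if obs.empty:
            continue
        dose = grp[(grp["EVID"] == 1) & (grp["CMT"] == dose_cmt)]
        ids.append(sid)
        wt.append(float(grp["WT"].iloc[0]))
        pma.append(float(grp["PMA"].iloc[0]))
        surg.append(bool(grp["SURG"].iloc[0]))
        tsurg.append(float(grp["TSURG"].iloc[0]))  # NaN when not surgical
        dstart.append(dose["TIME"].to_numpy(float))
        rate = dose["RATE"].to_numpy(float)
        amt = dose["AMT"].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            dur = np.where(rate > 0, amt / rate, 1.0)
        ddur.append(dur)
        drate.append(rate)
        otime.append(obs["TIME"].to_numpy(float))
        oval.append(obs["DV"].to_numpy(float))
        ocls.append(cls.loc[obs.index].to_numpy(float))
    y = _pad(oval)
    times = _pad(otime)
    mask = _pad([np.ones(len(v)) for v in oval]) > 0.5
    return SubjectBatch(
        ids=np.array(ids), wt=np.array(wt), pma=np.array(pma),
        surg=np.array(surg, dtype=bool), tsurg=np.array(tsurg),
        dose_start=_pad(dstart), dose_dur=_pad(ddur, fill=1.0),
        dose_rate=_pad(drate), obs_time=times, y=y, mask=mask,
        obs_class=_pad(ocls, fill=-1.0).astype(int))


# ---------------------------------------------------------------------------
# clonidine PK
# ---------------------------------------------------------------------------

def clonidine_pk_problem(ds: pd.DataFrame, init: dict | None = None,
                         fixed: tuple = (),
                         covariate_on_cl: tuple | None = None) -> NLMEProblem:
    """One-compartment allometric+maturation clonidine model.

    ``covariate_on_cl=(values_by_id, ref)`` adds an exponential covariate
    term CL * exp(beta_cl * (cov - ref)) with a sign-free coefficient, for
    likelihood-ratio covariate testing.
    """
    init = {**dict(cl=15.0, v=100.0, omega_cl=0.4, omega_v=0.4,
                   sigma_prop=0.3), **(init or {})}
    batch = build_batch(ds, {io.OBS_CLON_CONC})
    mat = maturation(batch.pma, MaturationParams(*CLONIDINE_MATURATION))
    fwt_cl = (batch.wt / REF_WEIGHT_KG) ** 0.75 * mat
    fwt_v = batch.wt / REF_WEIGHT_KG

    params = [Param("cl", init["cl"]), Param("v", init["v"]),
              Param("omega_cl", init["omega_cl"], kind="omega"),
              Param("omega_v", init["omega_v"], kind="omega"),
              Param("sigma_prop", init["sigma_prop"], kind="sigma")]
    cov = None
    if covariate_on_cl is not None:
        values_by_id, ref = covariate_on_cl
        cov = np.array([values_by_id[i] for i in batch.ids]) - ref
        params.append(Param("beta_cl", init.get("beta_cl", 0.0),
                            transform="identity"))
    for p in params:
        if p.name in fixed:
            p.fixed = True

    def predict(values, eta):
        # eta may carry leading stencil axes: (..., n, 2) -> (..., n, O)
        cl = values["cl"] * fwt_cl * np.exp(eta[..., 0])
        if cov is not None:
            cl = cl * np.exp(values["beta_cl"] * cov)
        v = values["v"] * fwt_v * np.exp(eta[..., 1])
        k = cl / v
        amt = _infusion_amount_1cpt(batch.obs_time, batch.dose_start,
                                    batch.dose_dur, batch.dose_rate, k)
        return amt / v[..., None]

    return NLMEProblem(params=params, eta_names=["cl", "v"],
                       error_models={io.OBS_CLON_CONC:
                                     ErrorModel(prop="sigma_prop")},
                       y=batch.y, mask=batch.mask, obs_class=batch.obs_class,
                       predict=predict, ids=batch.ids,
                       obs_time=batch.obs_time)


# ---------------------------------------------------------------------------
# midazolam PK (parent + metabolite)
# ---------------------------------------------------------------------------

def midazolam_pk_problem(ds: pd.DataFrame, init: dict | None = None,
                         fixed: tuple = ()) -> NLMEProblem:
    """Parent + 1-OH metabolite midazolam model, full conversion."""
    init = {**dict(v=50.0, clm=20.0, vm=50.0, clom=100.0, omega_clm=0.5,
                   omega_v=0.5, sigma_prop=0.4, sigma_add=1.0,
                   sigma_prop_m1=0.4, sigma_add_m1=0.05), **(init or {})}
    batch = build_batch(ds, {io.OBS_MID_CONC, io.OBS_M1_CONC})
    mat = maturation(batch.pma, MaturationParams(*MIDAZOLAM_MATURATION))
    fcl = (batch.wt / REF_WEIGHT_KG) ** 0.75 * mat
    fv = batch.wt / REF_WEIGHT_KG

    params = [Param("v", init["v"]), Param("clm", init["clm"]),
              Param("vm", init["vm"]), Param("clom", init["clom"]),
              Param("omega_clm", init["omega_clm"], kind="omega"),
              Param("omega_v", init["omega_v"], kind="omega"),
              Param("sigma_prop", init["sigma_prop"], kind="sigma"),
              Param("sigma_add", init["sigma_add"], kind="sigma"),
              Param("sigma_prop_m1", init["sigma_prop_m1"], kind="sigma"),
              Param("sigma_add_m1", init["sigma_add_m1"], kind="sigma")]
    for p in params:
        if p.name in fixed:
            p.fixed = True
    is_parent = batch.obs_class == io.OBS_MID_CONC

    def predict(values, eta):
        clm = values["clm"] * fcl * np.exp(eta[..., 0])
        v = values["v"] * fv * np.exp(eta[..., 1])
        vm = values["vm"] * fv
        clom = values["clom"] * fcl
        a1, a2 = _infusion_amounts_parent_metabolite(
            batch.obs_time, batch.dose_start, batch.dose_dur, batch.dose_rate,
            clm / v, clom / vm)
        return np.where(is_parent, a1 / v[..., None], a2 / vm[..., None])

    return NLMEProblem(
        params=params, eta_names=["clm", "v"],
        error_models={io.OBS_MID_CONC: ErrorModel(prop="sigma_prop",
                                                  add="sigma_add"),
                      io.OBS_M1_CONC: ErrorModel(prop="sigma_prop_m1",
                                                 add="sigma_add_m1")},
        y=batch.y, mask=batch.mask, obs_class=batch.obs_class,
        predict=predict, ids=batch.ids, obs_time=batch.obs_time)


# ---------------------------------------------------------------------------
# COMFORT-B score model
# ---------------------------------------------------------------------------

def comfortb_problem(ds: pd.DataFrame, arm: str,
                     subject_pk: pd.DataFrame,
                     init: dict | None = None, fixed: tuple = ("paemax",
                                                               "tps50"),
                     gamma: float = 1.0) -> NLMEProblem:
    """Inhibitory Emax score model for one arm, sequential PKPD.

    ``subject_pk`` holds the individual PK parameters that drive the
    concentration (columns ``ID, CL, V`` for clonidine; ``ID, CLM, V`` for
    midazolam) — EBEs in a real analysis, the generating individual values
    in a simulation study. The midazolam arm additionally pins nonsurgical
    baselines to each subject's pre-dose observed score.
    """
    if arm not in io.ARMS:
        raise ValueError(f"unknown arm {arm}")
    defaults = dict(ec50=1.5 if arm == "clonidine" else 100.0, b0=12.0,
                    paemax=11.8 if arm == "clonidine" else 9.3, tps50=0.11,
                    omega_ec50=0.5, sigma_prop=0.2)
    init = {**defaults, **(init or {})}
    batch = build_batch(ds[ds["ARM"] == arm], {io.OBS_SCORE})
    if batch.surg.any() and not np.all(np.isfinite(batch.tsurg[batch.surg])):
        raise ValueError("surgical subject without a surgery end time")

    spk = subject_pk.set_index("ID")
    if arm == "clonidine":
        cl_i = spk.loc[batch.ids, "CL"].to_numpy(float)
        v_i = spk.loc[batch.ids, "V"].to_numpy(float)
    else:
        cl_i = spk.loc[batch.ids, "CLM"].to_numpy(float)
        v_i = spk.loc[batch.ids, "V"].to_numpy(float)
    k_i = cl_i / v_i
    amt = _infusion_amount_1cpt(batch.obs_time, batch.dose_start,
                                batch.dose_dur, batch.dose_rate, k_i)
    conc = amt / v_i[:, None]  # fixed driver: individual predicted conc

    params = [Param("ec50", init["ec50"]),
              Param("paemax", init["paemax"]),
              Param("tps50", init["tps50"]),
              Param("omega_ec50", init["omega_ec50"], kind="omega"),
              Param("sigma_prop", init["sigma_prop"], kind="sigma")]
    estimates_b0 = arm == "clonidine"
    if estimates_b0:
        params.insert(1, Param("b0", init["b0"]))
        obs_baseline = None
    else:
        # per-subject observed baseline: the first (pre-dose) score
        first = np.argmax(batch.mask, axis=1)
        obs_baseline = batch.y[np.arange(batch.y.shape[0]), first]
    for p in params:
        if p.name in fixed:
            p.fixed = True
    surg = batch.surg[:, None]
    tsurg = np.where(batch.surg, batch.tsurg, 0.0)
    tps = np.clip(batch.obs_time - tsurg[:, None], 0.0, None)

    def predict(values, eta):
        ec50 = values["ec50"] * np.exp(eta[..., 0])
        pa = BASE_FIXED + values["paemax"] * tps / (values["tps50"] + tps)
        if estimates_b0:
            b0 = np.broadcast_to(values["b0"], conc.shape)
        else:
            b0 = np.broadcast_to(obs_baseline[:, None], conc.shape)
        baseline = np.where(surg, pa, b0)
        cg = conc ** gamma
        impeff = EMAX_FIXED * cg / (ec50[..., None] ** gamma + cg)
        return np.maximum(baseline - impeff, SCORE_MIN)

    return NLMEProblem(params=params, eta_names=["ec50"],
                       error_models={io.OBS_SCORE:
                                     ErrorModel(prop="sigma_prop")},
                       y=batch.y, mask=batch.mask, obs_class=batch.obs_class,
                       predict=predict, ids=batch.ids,
                       obs_time=batch.obs_time)
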