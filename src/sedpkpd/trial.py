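"""Virtual-trial generator emulating the sedation trial's design.

Produces datasets with the statistical structure the analysis pipeline
assumes: neonates and infants (gestational age >= ~36 weeks at birth, body
weight rising monotonically with postmenstrual age), 1:1 randomisation to
clonidine or midazolam, loading dose + titrated continuous infusion
(halved in neonates younger than 28 days), 2-4 sparse drug/metabolite
plasma samples per subject, COMFORT-B scores every 3 h, residual errors
per observation class, and below-quantification flagging.

The weight-for-PMA curve is a monotone sigmoid with lognormal individual
variability — a stand-in with the right shape for the published
growth-function approach, whose coefficients are not reproduced here. The
nurse-driven dosing algorithm of the trial is replaced by a simple
two-threshold titration band on the simulated latent score. Surgery is
taken to end at the start of study time, so the postanesthesia clock runs
on study time itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import io
from .params import (CLONIDINE_POP_PD, CLONIDINE_POP_PK, MIDAZOLAM_POP_PD,
                     MIDAZOLAM_POP_PK, PopPD)
from .pd import SCORE_MAX, SCORE_MIN, predict_score, emit_score
from .pk import (CovariateRecord, DoseEvent, conc_clonidine, conc_midazolam,
                 individualize_clonidine, individualize_midazolam)

NEONATE_PNA_DAYS = 28.0  # doses are halved below this postnatal age


@dataclass(frozen=True)
class DoseProtocol:
    """Loading dose + continuous infusion with band titration (per kg)."""

    loading_ug_per_kg: float
    rate_ug_per_kg_h: float
    loading_duration_h: float = 0.25
    adjust_interval_h: float = 3.0
    titration_fraction: float = 0.30  # multiplicative step per adjustment
    rate_min_frac: float = 0.25  # of the starting rate
    rate_max_frac: float = 4.0
    target_low: float = 11.0  # adequate-sedation band on COMFORT-B
    target_high: float = 22.0


CLONIDINE_PROTOCOL = DoseProtocol(loading_ug_per_kg=2.0, rate_ug_per_kg_h=1.0)
MIDAZOLAM_PROTOCOL = DoseProtocol(loading_ug_per_kg=200.0,
                                  rate_ug_per_kg_h=100.0)


@dataclass(frozen=True)
class WeightModel:
    """Monotone sigmoid weight-for-PMA with truncated lognormal IIV."""

    wmax: float = 24.0  # kg asymptote
    pma50: float = 180.0  # weeks at half asymptote
    hill: float = 1.4
    cv: float = 0.15  # lognormal sd of individual deviation
    trunc: float = 2.0  # truncation of the log-normal deviate, in sd

    def median(self, pma):
        pma = np.asarray(pma, dtype=float)
        r = (pma / self.pma50) ** self.hill
        return self.wmax * r / (1.0 + r)

    def sample(self, pma, rng: np.random.Generator):
        z = rng.standard_normal(np.shape(pma))
        z = np.clip(z, -self.trunc, self.trunc)
        return self.median(pma) * np.exp(self.cv * z)


@dataclass(frozen=True)
class TrialDesign:
    """Study-design knobs; defaults emulate the trial."""

    n_subjects: int = 28
    ga_range: tuple = (36.3, 40.0)  # weeks (exclusion below 34 wk GA)
    pna_median_days: float = 20.0
    pna_sigma: float = 2.0  # lognormal log-sd of PNA
    pna_min_days: float = 0.0
    pna_max_days: float = 2100.0
    surgery_prob: dict = field(default_factory=lambda: {
        "clonidine": 7 / 15, "midazolam": 11 / 13})
    propofol_prob: dict = field(default_factory=lambda: {
        "clonidine": 10 / 15, "midazolam": 6 / 13})
    n_pk_samples: tuple = (2, 4)  # inclusive range per subject
    score_interval_h: float = 3.0
    followup_range_h: tuple = (13.0, 107.0)
    loq: dict = field(default_factory=lambda: {
        io.OBS_CLON_CONC: 0.1, io.OBS_MID_CONC: 0.5, io.OBS_M1_CONC: 0.1})
    titrate: bool = True
    weight_model: WeightModel = field(default_factory=WeightModel)
    baseline_cv: float = 0.12  # spread of individual (observed) baselines

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.ga_range[0] >= self.ga_range[1]:
            raise ValueError("empty gestational-age range")
        if self.pna_min_days >= self.pna_max_days:
            raise ValueError("empty postnatal-age range")
        for d in (self.surgery_prob, self.propofol_prob):
            if any(not 0 <= v <= 1 for v in d.values()):
                raise ValueError("probabilities must lie in [0, 1]")


def generate_population(n: int, design: TrialDesign | None = None,
                        seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Draw a virtual population (covariates, arm, surgery, follow-up)."""
    design = design or TrialDesign()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ga = rng.uniform(*design.ga_range, size=n)
    lo, hi = design.pna_min_days, design.pna_max_days
    mu = np.log(design.pna_median_days)
    # inverse-CDF sampling of the truncated lognormal PNA
    from scipy.stats import norm
    a = norm.cdf((np.log(max(lo, 1e-3)) - mu) / design.pna_sigma)
    b = norm.cdf((np.log(hi) - mu) / design.pna_sigma)
    u = rng.uniform(a, b, size=n)
    pna = np.exp(mu + design.pna_sigma * norm.ppf(u))
    pna = np.clip(pna, lo, hi)
    pma = ga + pna / 7.0
    wt = design.weight_model.sample(pma, rng)
    # 1:1 block randomisation
    arms = np.array(["clonidine", "midazolam"])[
        rng.permutation(np.arange(n) % 2)]
    surg = rng.random(n) < np.array([design.surgery_prob[a] for a in arms])
    prop = rng.random(n) < np.array([design.propofol_prob[a] for a in arms])
    dur = rng.uniform(*design.followup_range_h, size=n)
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    return pd.DataFrame({
        "ID": np.arange(1, n + 1), "ARM": arms, "SEX": sex, "GA": ga,
        "PNA": pna, "PMA": pma, "WT": wt, "SURG": surg.astype(int),
        "TSURG": np.where(surg, 0.0, np.nan), "PROPOFOL": prop.astype(int),
        "DUR": dur})


def generate_dosing(weight: float, pna_days: float, protocol: DoseProtocol,
                    drug: str, duration_h: float, titrate: bool = True,
                    score_fn=None) -> list[DoseEvent]:
    """Loading infusion + maintenance infusion with band titration.

    ``score_fn(t, events)`` returns the subject's current (latent) score
    given the dosing history; it is consulted at every adjustment interval
    when titration is on. Doses are halved for neonates (PNA < 28 d).
    """
    half = 0.5 if pna_days < NEONATE_PNA_DAYS else 1.0
    ld_rate = protocol.loading_ug_per_kg * weight * half / protocol.loading_duration_h
    events = [DoseEvent(0.0, ld_rate, protocol.loading_duration_h, drug)]
    rate0 = protocol.rate_ug_per_kg_h * weight * half
    if not titrate or score_fn is None:
        if duration_h > protocol.loading_duration_h:
            events.append(DoseEvent(protocol.loading_duration_h, rate0,
                                    duration_h - protocol.loading_duration_h,
                                    drug))
        return events
    rate = rate0
    t = protocol.loading_duration_h
    while t < duration_h:
        t_next = min(t + protocol.adjust_interval_h, duration_h)
        events.append(DoseEvent(t, rate, t_next - t, drug))
        if t_next >= duration_h:
            break
        score = score_fn(t_next, events)
        if score > protocol.target_high:
            rate = min(rate * (1 + protocol.titration_fraction),
                       rate0 * protocol.rate_max_frac)
        elif score < protocol.target_low:
            rate = max(rate * (1 - protocol.titration_fraction),
                       rate0 * protocol.rate_min_frac)
        t = t_next
    return events


def _pk_sample_times(rng, n_range, ld_end, duration):
    n = int(rng.integers(n_range[0], n_range[1] + 1))
    t_first = ld_end + rng.uniform(0.08, 0.75)
    t_last = max(duration - rng.uniform(0.1, 1.0), t_first + 0.5)
    extras = rng.uniform(t_first, t_last, size=max(n - 2, 0))
    return np.sort(np.concatenate([[t_first, t_last], extras]))


def simulate_trial(subjects: pd.DataFrame, seed: int = 0,
                   design: TrialDesign | None = None,
                   clon_pk=CLONIDINE_POP_PK, mid_pk=MIDAZOLAM_POP_PK,
                   clon_pd: PopPD = CLONIDINE_POP_PD,
                   mid_pd: PopPD = MIDAZOLAM_POP_PD,
                   clon_protocol: DoseProtocol = CLONIDINE_PROTOCOL,
                   mid_protocol: DoseProtocol = MIDAZOLAM_PROTOCOL,
                   cl_multiplier: dict | None = None):
    """Simulate one trial: returns (dataset, subject-parameter table).

    The dataset is the delimited-text record set of :mod:`sedpkpd.io`;
    the subject table carries the generating individual PK/PD parameters
    (the simulation analogue of empirical Bayes estimates), used by the
    sequential score-model fits and by recovery checks. ``cl_multiplier``
    maps subject ID to an extra multiplicative factor on the individual
    (formation) clearance — the hook for simulating covariate or genotype
    effects.
    """
    design = design or TrialDesign()
    rng = np.random.default_rng(seed)
    rows = []
    subj_rows = []
    for _, s in subjects.iterrows():
        arm = s["ARM"]
        cov = CovariateRecord(weight=float(s["WT"]), pma=float(s["PMA"]),
                              pna=float(s["PNA"]), sex=str(s["SEX"]))
        mult = float(cl_multiplier.get(int(s["ID"]), 1.0)) if cl_multiplier else 1.0
        if arm == "clonidine":
            pkpop, pdpop, protocol = clon_pk, clon_pd, clon_protocol
            eta_cl = rng.normal(0.0, pkpop.omega_cl)
            eta_v = rng.normal(0.0, pkpop.omega_v)
            ipk = individualize_clonidine(pkpop.cl * mult, pkpop.v, cov,
                                          eta_cl, eta_v)
        else:
            pkpop, pdpop, protocol = mid_pk, mid_pd, mid_protocol
            eta_cl = rng.normal(0.0, pkpop.omega_clm)
            eta_v = rng.normal(0.0, pkpop.omega_v)
            ipk = individualize_midazolam(pkpop.v, pkpop.clm * mult, pkpop.vm,
                                          pkpop.clom, cov, eta_cl, eta_v)
        eta_ec50 = rng.normal(0.0, pdpop.omega_ec50)
        ipd = replace(pdpop.pd, ec50=pdpop.pd.ec50 * float(np.exp(eta_ec50)))
        surgical = bool(s["SURG"])
        if arm == "midazolam" and not surgical:
            # individual observed baseline (pinned, not estimated, in fits)
            b0_i = float(np.clip(pdpop.pd.b0 * np.exp(
                design.baseline_cv * rng.standard_normal()),
                SCORE_MIN + 1.0, SCORE_MAX))
        else:
            b0_i = ipd.b0

        def latent(t, events, _ipk=ipk, _ipd=ipd, _arm=arm,
                   _surg=surgical, _b0=b0_i):
            if _arm == "clonidine":
                c = conc_clonidine(_ipk, events, [t]).values[0]
            else:
                c = conc_midazolam(_ipk, events, [t]).values[0]
            return predict_score(t, _ipd, c, surgical=_surg,
                                 surgery_end=0.0, b0=_b0)

        duration = float(s["DUR"])
        doses = generate_dosing(cov.weight, cov.pna, protocol, arm, duration,
                                titrate=design.titrate, score_fn=latent)
        base = dict(ID=int(s["ID"]), WT=cov.weight, PMA=cov.pma, PNA=cov.pna,
                    SEX=cov.sex, ARM=arm, SURG=int(surgical),
                    TSURG=0.0 if surgical else np.nan)
        for d in doses:
            rows.append(dict(base, TIME=d.start_time, AMT=d.amount,
                             RATE=d.rate, DV=np.nan, CMT=io.CMT_CENTRAL,
                             EVID=1, MDV=1, BLQ=0))
        if bool(s["PROPOFOL"]):
            # bridging propofol during the first 30 min only
            rows.append(dict(base, TIME=0.0, AMT=2000.0 * cov.weight,
                             RATE=4000.0 * cov.weight, DV=np.nan,
                             CMT=io.CMT_PROPOFOL, EVID=1, MDV=1, BLQ=0))

        # sparse PK samples
        tpk = _pk_sample_times(rng, design.n_pk_samples,
                               protocol.loading_duration_h, duration)
        if arm == "clonidine":
            prof = conc_clonidine(ipk, doses, tpk)
            obs = [(io.CMT_CENTRAL, io.OBS_CLON_CONC, prof.values, None)]
        else:
            prof = conc_midazolam(ipk, doses, tpk)
            obs = [(io.CMT_CENTRAL, io.OBS_MID_CONC, prof.values, None),
                   (io.CMT_METABOLITE, io.OBS_M1_CONC, prof.metabolite, None)]
        for cmt, ocls, conc_true, _ in obs:
            if ocls == io.OBS_MID_CONC:
                sd = np.sqrt(pkpop.err_add ** 2
                             + (pkpop.err_prop * conc_true) ** 2)
            elif ocls == io.OBS_M1_CONC:
                sd = np.sqrt(pkpop.err_add_m1 ** 2
                             + (pkpop.err_prop_m1 * conc_true) ** 2)
            else:
                sd = pkpop.err_prop * conc_true
            dv = conc_true + sd * rng.standard_normal(conc_true.shape)
            loq = design.loq[ocls]
            for t, v in zip(tpk, dv):
                blq = v < loq
                rows.append(dict(base, TIME=float(t), AMT=np.nan, RATE=np.nan,
                                 DV=np.nan if blq else float(v), CMT=cmt,
                                 EVID=0, MDV=int(blq), BLQ=int(blq)))

        # COMFORT-B every 3 h from the start of treatment
        tsc = np.arange(0.0, duration + 1e-9, design.score_interval_h)
        if arm == "clonidine":
            csc = conc_clonidine(ipk, doses, tsc).values
        else:
            csc = conc_midazolam(ipk, doses, tsc).values
        lat = predict_score(tsc, ipd, csc, surgical=surgical,
                            surgery_end=0.0, b0=b0_i)
        score = emit_score(lat, pdpop.err_prop, rng)
        for t, v in zip(tsc, score):
            rows.append(dict(base, TIME=float(t), AMT=np.nan, RATE=np.nan,
                             DV=float(v), CMT=io.CMT_SCORE, EVID=0, MDV=0,
                             BLQ=0))

        srow = dict(ID=int(s["ID"]), ARM=arm, WT=cov.weight, PMA=cov.pma,
                    ETA_CL=eta_cl, ETA_V=eta_v, ETA_EC50=eta_ec50,
                    EC50_I=ipd.ec50, B0_I=b0_i)
        if arm == "clonidine":
            srow.update(CL=ipk.cl, V=ipk.v)
        else:
            srow.update(CLM=ipk.clm, V=ipk.v, VM=ipk.vm, CLOM=ipk.clom)
        subj_rows.append(srow)

    ds = pd.DataFrame(rows)
    ds = ds.sort_values(["ID", "TIME", "EVID"],
                        ascending=[True, True, False], kind="stable")
    ds = ds[io.COLUMNS].reset_index(drop=True)
    return ds, pd.DataFrame(subj_rows)


def generate_genotypes(n_subjects: int, n_snps: int, maf=0.3, seed: int = 0,
                       effect_snp: int | None = None,
                       effect_per_allele: float = 0.0,
                       missing_rate: float = 0.0):
    """Additive-coded genotype matrix, binomial at the configured MAF.

    Returns (DataFrame subjects x SNPs with values {0,1,2, NaN}, per-subject
    multiplicative effect on clearance exp(effect_per_allele * count) for
    the designated causal SNP — ones when no effect is configured).
    """
    rng = np.random.default_rng(seed)
    maf = np.broadcast_to(np.asarray(maf, dtype=float), (n_snps,))
    g = rng.binomial(2, maf, size=(n_subjects, n_snps)).astype(float)
    if missing_rate > 0:
        g[rng.random(g.shape) < missing_rate] = np.nan
    cols = [f"snp{j + 1}" for j in range(n_snps)]
    gdf = pd.DataFrame(g, columns=cols)
    gdf.insert(0, "ID", np.arange(1, n_subjects + 1))
    mult = np.ones(n_subjects)
    if effect_snp is not None and effect_per_allele != 0.0:
        counts = np.nan_to_num(g[:, effect_snp])
        mult = np.exp(effect_per_allele * counts)
    return gdf, mult
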