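"""Concentration-effect model for the COMFORT-B sedation score.

The COMFORT-B scale runs from 6 (fully anesthetized / deeply sedated) to 31
(fully awake and distressed). The expected score is composed additively:

    score = PA(tps) - IMPEFF(conc) - CMEFF(propofol)   (surgical subjects)
    score = B0      - IMPEFF(conc) - CMEFF(propofol)   (nonsurgical subjects)

where

* ``PA`` is a postanesthesia washout: at the end of surgery the child is
  fully anesthetized (score BASE = 6) and wakes towards a ceiling
  SMAX = BASE + PAEMAX with an Emax time course of half-time TPS50 in the
  time-post-surgery clock ``tps``;
* ``IMPEFF`` is the inhibitory sigmoid Emax effect of the sedative
  (clonidine or midazolam), with the maximal effect fixed to 6 score
  points for stability;
* ``CMEFF`` is a kinetic-pharmacodynamic (K-PD) effect of bridging
  propofol, driven by the infusion-rate equivalent of a virtual
  compartment because propofol concentrations are not measured.

The composed score is truncated at the scale floor of 6 before residual
error; reported scores are integers clamped to [6, 31] (see
:func:`emit_score`), while the latent model stays continuous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .pk import DoseEvent, _infusion_amount_1cpt, _event_arrays

SCORE_MIN = 6.0
SCORE_MAX = 31.0

#: maximal drug effect, fixed to 6 score points
EMAX_FIXED = 6.0
#: score at the end of surgery (full anesthesia), fixed to the scale floor
BASE_FIXED = 6.0


@dataclass(frozen=True)
class PDParams:
    """Parameters of the score model.

    ``emax`` and ``base`` are fixed constants of the model family (6 each);
    ``gamma`` defaults to 1 (plain Emax). ``paemax`` is the awakening span
    above ``base`` (SMAX = base + paemax); ``tps50`` its half-time.
    """

    ec50: float  # ng/mL
    b0: float = 15.6  # nonsurgical baseline score
    paemax: float = 11.8  # score units
    tps50: float = 0.11  # h
    gamma: float = 1.0
    emax: float = EMAX_FIXED
    base: float = BASE_FIXED

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if not (SCORE_MIN <= self.b0 <= SCORE_MAX):
            raise ValueError(f"b0 must lie on the score scale, got {self.b0}")
        if self.paemax < 0:
            raise ValueError("paemax must be nonnegative")
        if self.tps50 <= 0:
            raise ValueError("tps50 must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @property
    def smax(self) -> float:
        return self.base + self.paemax


@dataclass(frozen=True)
class KPDParams:
    """K-PD propofol effect. The published maximal effect and EC50 are not

    reproduced here; these defaults are synthetic placeholders with the
    right orders of magnitude (kde 1/h; ec50_cm in ug/h of infusion-rate
    equivalent) and are exercised only with synthetic values in tests.
    """

    kde: float = 2.0  # 1/h
    emax_cm: float = 3.0  # score units
    ec50_cm: float = 1000.0  # ug/h (infusion-rate equivalent)

    def __post_init__(self) -> None:
        if min(self.kde, self.emax_cm, self.ec50_cm) <= 0:
            raise ValueError("K-PD parameters must be positive")


def postanesthesia(tps, p: PDParams):
    """Postanesthesia score PA = BASE + PAEMAX*TPS/(TPS50+TPS).

    Equals ``base`` at the end of surgery (tps=0), rises monotonically and
    saturates at SMAX = base + paemax.
    """
    tps = np.asarray(tps, dtype=float)
    if np.any(tps < 0):
        raise ValueError("time post surgery must be nonnegative")
    out = p.base + p.paemax * tps / (p.tps50 + tps)
    return float(out) if out.ndim == 0 else out


def imp_effect(conc, p: PDParams):
    """Inhibitory sigmoid Emax drug effect in score points, in [0, emax)."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be nonnegative")
    cg = conc ** p.gamma
    out = p.emax * cg / (p.ec50 ** p.gamma + cg)
    return float(out) if out.ndim == 0 else out


def kpd_ire(doses: Sequence[DoseEvent], kp: KPDParams, t):
    """Infusion-rate equivalent IRE = kde*A of the virtual compartment."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    start, dur, rate = _event_arrays(doses, "propofol")
    amount = _infusion_amount_1cpt(t, start, dur, rate, kp.kde)
    return kp.kde * amount


def kpd_effect(doses: Sequence[DoseEvent], kp: KPDParams, t):
    """Propofol co-medication effect on the score (CMEFF), in score points.

    Zero whenever no propofol has been given; approaches
    emax_cm*R/(ec50_cm+R) under a constant infusion at rate R.
    """
    ire = kpd_ire(doses, kp, t)
    out = kp.emax_cm * ire / (kp.ec50_cm + ire)
    return out


def predict_score(t, p: PDParams, conc, *, surgical: bool = False,
                  surgery_end: float = 0.0, comed_doses: Sequence[DoseEvent] = (),
                  kp: KPDParams | None = None, b0=None):
    """Expected (latent, continuous) COMFORT-B score at times ``t``.

    ``conc`` is the individual predicted concentration of the assigned
    sedative at ``t``. Surgical subjects wake from ``base`` along the
    postanesthesia curve in the time-post-surgery clock starting at
    ``surgery_end``; nonsurgical subjects sit at baseline ``b0``
    (defaulting to ``p.b0``). The result is floored at the scale minimum 6;
    residual error and integer reporting are applied downstream.
    """
    t = np.asarray(t, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if surgical:
        if surgery_end is None:
            raise ValueError("surgical subject requires a surgery end time")
        tps = t - surgery_end
        if np.any(tps < -1e-9):
            raise ValueError("score time precedes the end of surgery")
        pa = postanesthesia(np.clip(tps, 0.0, None), p)
    else:
        pa = np.broadcast_to(float(p.b0 if b0 is None else b0), t.shape)
    cmeff = kpd_effect(comed_doses, kp, t) if (len(comed_doses) and kp) else 0.0
    score = pa - imp_effect(conc, p) - cmeff
    out = np.maximum(score, SCORE_MIN)
    return float(out) if out.ndim == 0 else out


def emit_score(latent, prop_err, rng: np.random.Generator):
    """Reported score: proportional residual error, integer, clamped [6,31]."""
    latent = np.asarray(latent, dtype=float)
    noisy = latent * (1.0 + prop_err * rng.standard_normal(latent.shape))
    return np.clip(np.rint(noisy), SCORE_MIN, SCORE_MAX)
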