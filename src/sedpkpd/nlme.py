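"""Nonlinear mixed-effects estimation by the Laplace approximation.

The marginal likelihood of a population model with lognormal subject-level
random effects has no closed form; it is approximated subject by subject by
Laplace's method with interaction (the residual variance is evaluated at the
subject's conditional mode, so proportional-error/eta interaction is kept):

    -2 log L_i  ~=  g_i(eta_hat) - k log 2*pi + log det( g_i''(eta_hat)/2 )

where ``g_i`` is the per-subject -2 log joint density of data and random
effects, ``eta_hat`` its minimiser (the empirical Bayes mode) and ``k`` the
number of random effects. The inner mode search is a damped Newton iteration
with finite-difference derivatives, vectorised across all subjects at once;
the outer problem maximises the summed approximate likelihood over
log-transformed population parameters with quasi-Newton (L-BFGS-B on
coarse finite-difference gradients; Nelder-Mead fallback), optionally
multi-started. This is the standard conditional-estimation scheme of
population PK (FOCE-I/Laplace family).

Residual-error models are combined additive + proportional per observation
class; lognormal interindividual variability is diagonal (no eta
correlations).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize, stats

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class Param:
    """One population parameter (theta, omega-sd or sigma).

    Positive parameters are optimised on the log scale (``transform='log'``,
    the default); sign-free parameters such as exponential-covariate
    coefficients use ``transform='identity'``. ``kind`` is informational
    ('theta' | 'omega' | 'sigma'); fixing a parameter removes it from the
    optimisation (FIX semantics).
    """

    name: str
    init: float
    fixed: bool = False
    kind: str = "theta"
    transform: str = "log"

    def __post_init__(self) -> None:
        if self.transform not in ("log", "identity"):
            raise ValueError(f"unknown transform {self.transform}")
        if self.transform == "log" and self.init <= 0:
            raise ValueError(f"{self.name}: parameters are log-transformed and "
                             f"must be positive, got {self.init}")


@dataclass
class ErrorModel:
    """Residual error for one observation class: sd = sqrt(add^2+(prop*f)^2).

    ``prop``/``add`` name sigma parameters of the problem (None -> absent).
    """

    prop: str | None = None
    add: str | None = None


@dataclass
class NLMEProblem:
    """A population model ready for estimation.

    ``predict(values, eta)`` maps a dict of population parameter values and
    an (n_subjects, n_eta) random-effect matrix to an (n_subjects, n_obs)
    prediction array aligned with ``y``/``mask``/``obs_class``.
    """

    params: list[Param]
    eta_names: list[str]  # omega parameter 'omega_<name>' must exist
    error_models: dict[int, ErrorModel]  # by observation-class code
    y: np.ndarray  # (n, O)
    mask: np.ndarray  # (n, O) bool
    obs_class: np.ndarray  # (n, O) int
    predict: Callable[[dict, np.ndarray], np.ndarray] = None
    ids: np.ndarray | None = None  # subject labels, for error messages
    obs_time: np.ndarray | None = None  # (n, O), for diagnostics

    def __post_init__(self) -> None:
        names = {p.name for p in self.params}
        for nm in self.eta_names:
            if f"omega_{nm}" not in names:
                raise ValueError(f"missing omega parameter omega_{nm}")
        if not self.mask.any(axis=1).all():
            bad = np.where(~self.mask.any(axis=1))[0]
            lab = self.ids[bad] if self.ids is not None else bad
            raise ValueError(f"subjects without observations: {lab}")

    @property
    def n_subjects(self) -> int:
        return self.y.shape[0]

    @property
    def n_eta(self) -> int:
        return len(self.eta_names)

    def values_from(self, free: dict) -> dict:
        out = {p.name: p.init for p in self.params}
        out.update(free)
        return out


@dataclass
class FitResult:
    """Estimates, uncertainty and diagnostics of one population fit."""

    estimates: dict
    ofv: float  # -2 log approximate marginal likelihood
    etas: np.ndarray  # (n, k) empirical Bayes modes
    eta_names: list[str]
    converged: bool
    message: str = ""
    se: dict | None = None  # asymptotic SE (natural scale), when available
    rse_percent: dict | None = None
    ofv_init: float = np.nan
    n_starts: int = 1
    ids: np.ndarray | None = None

    def iiv_percent(self, convention: str = "cv") -> dict:
        """IIV in % per random effect: lognormal CV (default) or 100*omega."""
        out = {}
        for nm in self.eta_names:
            om = self.estimates[f"omega_{nm}"]
            out[nm] = (100.0 * np.sqrt(np.expm1(om ** 2))
                       if convention == "cv" else 100.0 * om)
        return out

    def ebe_table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.etas, columns=[f"eta_{n}" for n in self.eta_names])
        if self.ids is not None:
            df.insert(0, "ID", self.ids)
        return df


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

_VAR_FLOOR = 1e-10


def _residual_variance(problem: NLMEProblem, values: dict, pred: np.ndarray):
    # pred may carry leading stencil axes: (..., n, O)
    var = np.zeros_like(pred)
    for code, em in problem.error_models.items():
        sel = problem.obs_class == code
        add2 = values[em.add] ** 2 if em.add is not None else 0.0
        prop = values[em.prop] if em.prop is not None else 0.0
        var = np.where(sel, add2 + (prop * pred) ** 2, var)
    return np.maximum(var, _VAR_FLOOR)


def _joint_m2ll(problem: NLMEProblem, values: dict, omega2: np.ndarray,
                eta: np.ndarray) -> np.ndarray:
    """Per-subject -2 log joint density of (y_i, eta_i).

    ``eta`` may carry leading batch axes, (..., n, k) -> (..., n); the
    inner-mode stencil exploits this to evaluate all finite-difference
    points in a single vectorised pass.
    """
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        pred = problem.predict(values, eta)
        var = _residual_variance(problem, values, pred)
        dev = np.where(problem.mask, (problem.y - pred) ** 2 / var
                       + np.log(var) + _LOG2PI, 0.0)
        out = dev.sum(axis=-1)
        out = out + (eta ** 2 / omega2).sum(axis=-1)
        out = out + np.log(omega2).sum() + problem.n_eta * _LOG2PI
    return out


def _fd_grad_hess(fun, eta, h=1e-4):
    """Central-difference gradient and Hessian, all subjects and stencil
    points in one batched call.

    ``fun`` maps (..., n, k) -> (..., n); returns f0 (n,), g (n,k),
    H (n,k,k).
    """
    n, k = eta.shape
    pts = [eta]
    for i in range(k):
        e = np.zeros((1, k)); e[0, i] = h
        pts += [eta + e, eta - e]
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros((1, k)); ei[0, i] = h
            ej = np.zeros((1, k)); ej[0, j] = h
            pts += [eta + ei + ej, eta + ei - ej, eta - ei + ej, eta - ei - ej]
            pairs.append((i, j))
    f = fun(np.stack(pts))  # (P, n)
    f0 = f[0]
    g = np.zeros((n, k))
    H = np.zeros((n, k, k))
    for i in range(k):
        fp, fm = f[1 + 2 * i], f[2 + 2 * i]
        g[:, i] = (fp - fm) / (2 * h)
        H[:, i, i] = (fp - 2 * f0 + fm) / h ** 2
    base = 1 + 2 * k
    for m, (i, j) in enumerate(pairs):
        fpp, fpm, fmp, fmm = f[base + 4 * m: base + 4 * m + 4]
        H[:, i, j] = H[:, j, i] = (fpp - fpm - fmp + fmm) / (4 * h ** 2)
    return f0, g, H


def _make_pd(H, rel_ridge: float = 0.0):
    """Nudge per-subject (k,k) Hessians to positive definiteness.

    ``rel_ridge`` adds a ridge proportional to the dominant eigenvalue,
    used inside the Newton iteration to keep steps finite when the joint
    is locally indefinite; the final Laplace determinant uses the minimal
    nudge only.
    """
    k = H.shape[-1]
    eye = np.eye(k)
    H = np.where(np.isfinite(H), H, 0.0)
    w = np.linalg.eigvalsh(H)
    lam = np.maximum(0.0, -w[..., 0]) + 1e-8
    if rel_ridge:
        lam = lam + rel_ridge * np.maximum(np.abs(w[..., -1]), 1.0)
    return H + lam[:, None, None] * eye


def _inner_modes(problem: NLMEProblem, values: dict, omega2: np.ndarray,
                 eta0: np.ndarray, max_iter: int = 15, gtol: float = 2e-3,
                 steptol: float = 1e-6):
    """Damped Newton search for all subjects' conditional modes at once.

    Tolerances sit above the finite-difference noise floor; with warm
    starts from the previous outer iterate the loop typically runs 1-3
    Newton steps.
    """
    fun = lambda e: _joint_m2ll(problem, values, omega2, e)
    eta = eta0.copy()
    f0, g, H = _fd_grad_hess(fun, eta)
    for _ in range(max_iter):
        if np.max(np.abs(g)) < gtol:
            break
        Hpd = _make_pd(H, rel_ridge=0.05)
        step = np.linalg.solve(Hpd, g[..., None])[..., 0]
        # cap the step at a couple of random-effect SDs; the line search
        # still guards monotonicity
        norm = np.linalg.norm(step, axis=1, keepdims=True)
        step = step * np.minimum(1.0, 2.0 / np.maximum(norm, 1e-12))
        if np.max(np.abs(step)) < steptol:
            break
        alpha = np.ones(problem.n_subjects)
        improved = np.zeros(problem.n_subjects, dtype=bool)
        f_new = f0.copy()
        eta_new = eta.copy()
        for _ls in range(8):
            trial = np.where(improved[:, None], eta_new,
                             eta - alpha[:, None] * step)
            f_trial = fun(trial)
            better = ~improved & (f_trial <= f0 + 1e-12)
            eta_new[better] = trial[better]
            f_new[better] = f_trial[better]
            improved |= better
            if improved.all():
                break
            alpha = np.where(improved, alpha, alpha * 0.5)
        if not improved.any():
            break
        eta, f0 = eta_new, f_new
        f0, g, H = _fd_grad_hess(fun, eta)
    return eta, f0, _make_pd(H)


def laplace_ofv(problem: NLMEProblem, values: dict,
                eta0: np.ndarray | None = None):
    """OFV = -2 log approximate marginal likelihood, plus modes and Hessians."""
    k = problem.n_eta
    omega2 = np.array([values[f"omega_{nm}"] ** 2 for nm in problem.eta_names])
    if eta0 is None:
        eta0 = np.zeros((problem.n_subjects, k))
    eta, f0, H = _inner_modes(problem, values, omega2, eta0)
    sign, logdet = np.linalg.slogdet(H / 2.0)
    if np.any(sign <= 0):  # pragma: no cover - _make_pd precludes this
        return np.inf, eta, H
    ofv = float(np.sum(f0 - k * _LOG2PI + logdet))
    return ofv, eta, H


# ---------------------------------------------------------------------------
# outer optimisation
# ---------------------------------------------------------------------------

class _Objective:
    def __init__(self, problem: NLMEProblem):
        self.problem = problem
        free = [p for p in problem.params if not p.fixed]
        self.free_names = [p.name for p in free]
        self._log = np.array([p.transform == "log" for p in free], dtype=bool)
        self._inits = np.array([p.init for p in free], dtype=float)
        self.eta_cache = np.zeros((problem.n_subjects, problem.n_eta))

    def x0(self):
        return np.where(self._log, np.log(np.where(self._log, self._inits, 1.0)),
                        self._inits)

    def values(self, x):
        nat = np.where(self._log, np.exp(x), x)
        free = dict(zip(self.free_names, nat))
        return self.problem.values_from(free)

    def __call__(self, x):
        if np.any(~np.isfinite(x)) or np.any(np.abs(x) > 30):
            return 1e12
        values = self.values(x)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            ofv, eta, _ = laplace_ofv(self.problem, values, self.eta_cache)
        if not np.isfinite(ofv):
            return 1e12
        self.eta_cache = eta  # warm start for the next outer iterate
        return ofv


def fit_population(problem: NLMEProblem, n_starts: int = 3, seed: int = 0,
                   maxfev: int | None = None, compute_se: bool = True,
                   method: str = "lbfgs") -> FitResult:
    """Estimate population parameters by maximum approximate likelihood.

    Parameters are optimised on the log scale, by default with L-BFGS-B on
    coarse finite-difference gradients (step 1e-4, well above the inner
    Laplace noise floor); ``method='nelder-mead'`` selects the simplex
    fallback. Multi-start perturbs the initial values lognormally (first
    start unperturbed). The objective at the initial values is checked to
    be finite; a non-finite value raises with the offending subjects named.
    """
    obj = _Objective(problem)
    x0 = obj.x0()
    values0 = obj.values(x0)
    omega2 = np.array([values0[f"omega_{nm}"] ** 2 for nm in problem.eta_names])
    j0 = _joint_m2ll(problem, values0, omega2,
                     np.zeros((problem.n_subjects, problem.n_eta)))
    if np.any(~np.isfinite(j0)):
        bad = np.where(~np.isfinite(j0))[0]
        lab = problem.ids[bad] if problem.ids is not None else bad
        raise ValueError(f"non-finite objective at initial values for "
                         f"subjects {list(lab)}")
    ofv_init = float(obj(x0))

    rng = np.random.default_rng(seed)
    if maxfev is None:
        maxfev = 400 * max(len(x0), 1)
    best = None
    for s in range(max(1, n_starts)):
        xs = x0 if s == 0 else x0 + 0.25 * rng.standard_normal(x0.size)
        obj.eta_cache = np.zeros((problem.n_subjects, problem.n_eta))
        if method == "lbfgs":
            res = optimize.minimize(obj, xs, method="L-BFGS-B",
                                    options=dict(eps=1e-4, maxfun=maxfev,
                                                 maxiter=200, ftol=1e-10,
                                                 gtol=1e-5))
        elif method == "nelder-mead":
            res = optimize.minimize(obj, xs, method="Nelder-Mead",
                                    options=dict(maxfev=maxfev, xatol=2e-4,
                                                 fatol=5e-4,
                                                 adaptive=len(x0) > 4))
        else:
            raise ValueError(f"unknown method {method}")
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success) and best.fun <= ofv_init + 1e-9
    values = obj.values(best.x)
    ofv, etas, _ = laplace_ofv(problem, values)

    se = rse = None
    if compute_se and len(best.x):
        se, rse = _asymptotic_se(obj, best.x)
    return FitResult(estimates=values, ofv=float(min(ofv, best.fun)), etas=etas,
                     eta_names=list(problem.eta_names), converged=converged,
                     message=str(best.message), se=se, rse_percent=rse,
                     ofv_init=ofv_init, n_starts=n_starts, ids=problem.ids)


def _asymptotic_se(obj: _Objective, xhat: np.ndarray, h: float = 1e-3):
    """SEs from the finite-difference curvature of the OFV at the optimum.

    The observed information is half the OFV Hessian; SEs are reported on
    the natural scale (delta method through the log transform). Returns
    (None, None) when the curvature matrix is not positive definite.
    """
    p = xhat.size
    Hm = np.zeros((p, p))
    f0 = obj(xhat)
    fp = np.zeros(p); fm = np.zeros(p)
    for i in range(p):
        e = np.zeros(p); e[i] = h
        fp[i] = obj(xhat + e)
        fm[i] = obj(xhat - e)
        Hm[i, i] = (fp[i] - 2 * f0 + fm[i]) / h ** 2
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p); ei[i] = h
            ej = np.zeros(p); ej[j] = h
            Hm[i, j] = Hm[j, i] = (obj(xhat + ei + ej) - obj(xhat + ei - ej)
                                   - obj(xhat - ei + ej) + obj(xhat - ei - ej)
                                   ) / (4 * h ** 2)
    try:
        w = np.linalg.eigvalsh(Hm / 2.0)
        if w.min() <= 0:
            return None, None
        cov = np.linalg.inv(Hm / 2.0)
    except np.linalg.LinAlgError:  # pragma: no cover
        return None, None
    se_x = np.sqrt(np.diag(cov))
    nat = np.where(obj._log, np.exp(xhat), xhat)
    se_nat = np.where(obj._log, np.abs(nat) * se_x, se_x)  # delta method
    se = dict(zip(obj.free_names, se_nat))
    rse = dict(zip(obj.free_names,
                   100.0 * se_nat / np.maximum(np.abs(nat), 1e-12)))
    return se, rse


# ---------------------------------------------------------------------------
# BLQ handling
# ---------------------------------------------------------------------------

def blq_impute(ds: pd.DataFrame, loq: dict) -> pd.DataFrame:
    """Replace below-quantification observations by LOQ/2.

    ``loq`` maps observation-class codes (see :mod:`sedpkpd.io`) to limits
    of quantification. Non-BLQ records and the record count are untouched.
    """
    from .io import observation_class

    out = ds.copy()
    cls = observation_class(out)
    blq = (out["EVID"] == 0) & (out["BLQ"] == 1)
    for code in sorted(cls[blq].dropna().unique()):
        if code not in loq:
            raise ValueError(f"BLQ flag present for observation class {code} "
                             f"but no LOQ configured")
        if loq[code] <= 0:
            raise ValueError("LOQ must be positive")
        out.loc[blq & (cls == code), "DV"] = loq[code] / 2.0
    return out


# ---------------------------------------------------------------------------
# covariate testing
# ---------------------------------------------------------------------------

@dataclass
class CovariateTestResult:
    delta_ofv: float
    df: int
    p_value: float
    significant: bool
    alpha: float


def covariate_test(fit_base: FitResult, fit_extended: FitResult,
                   df: int = 1, alpha: float = 0.05) -> CovariateTestResult:
    """Likelihood-ratio test between nested fits (extended adds ``df`` terms).

    The covariate enters the extended model as theta*exp(beta*(cov-ref));
    inclusion is judged on the OFV drop against a chi-square with ``df``
    degrees of freedom (3.84 at alpha=0.05, df=1).
    """
    extra = set(fit_extended.estimates) - set(fit_base.estimates)
    if len(extra) != df:
        raise ValueError(f"models not nested with {df} extra parameter(s); "
                         f"extended adds {sorted(extra)}")
    d = fit_base.ofv - fit_extended.ofv
    p = float(stats.chi2.sf(max(d, 0.0), df)) if d > 0 else 1.0
    return CovariateTestResult(delta_ofv=float(d), df=df, p_value=p,
                               significant=bool(d > stats.chi2.isf(alpha, df)),
                               alpha=alpha)
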