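"""Model-evaluation tools: nonparametric bootstrap and pcVPC.

The bootstrap resamples subjects with replacement and refits; parameter
stability is summarised by the median and a 90% percentile interval. The
prediction-corrected visual predictive check (pcVPC) normalises each
observation and each simulated value by its population prediction, scaled
by the bin-median population prediction, before comparing observed
percentiles with simulation-based confidence bands — removing the spread
that dosing and covariate differences would otherwise add within a bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class BootstrapResult:
    samples: pd.DataFrame  # one row per successful resample
    summary: pd.DataFrame  # median + 90% percentile interval per parameter
    n_requested: int
    n_failed: int


def bootstrap(ds: pd.DataFrame, fit_fn, n_resamples: int, seed: int = 0,
              ci: float = 90.0) -> BootstrapResult:
    """Subject-level nonparametric bootstrap of a population fit.

    ``fit_fn(dataset) -> FitResult`` runs the estimation on one resampled
    dataset. Resampling draws subjects with replacement (per arm is the
    caller's concern: pass a single-arm dataset for arm-stratified use) and
    relabels them 1..N so repeated subjects stay distinct.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    ids = ds["ID"].unique()
    rows, failures = [], 0
    for _ in range(n_resamples):
        pick = rng.choice(ids, size=ids.size, replace=True)
        parts = []
        for new, old in enumerate(pick, start=1):
            sub = ds[ds["ID"] == old].copy()
            sub["ID"] = new
            parts.append(sub)
        bds = pd.concat(parts, ignore_index=True)
        try:
            fit = fit_fn(bds)
            if not fit.converged:
                raise RuntimeError("fit did not converge")
            rows.append(fit.estimates)
        except Exception:
            failures += 1
    if not rows:
        raise RuntimeError(f"all {n_resamples} bootstrap resamples failed")
    samples = pd.DataFrame(rows)
    lo, hi = (100 - ci) / 2, 100 - (100 - ci) / 2
    summary = samples.quantile([0.5, lo / 100, hi / 100]).T
    summary.columns = ["median", f"p{lo:g}", f"p{hi:g}"]
    return BootstrapResult(samples=samples, summary=summary,
                           n_requested=n_resamples, n_failed=failures)


@dataclass
class VPCResult:
    table: pd.DataFrame  # per bin: observed and simulated-band percentiles
    pctiles: tuple
    n_sim: int

    def coverage(self) -> float:
        """Fraction of (bin, percentile) cells with the observed value
        inside the simulated 95% band."""
        hits, total = 0, 0
        for q in self.pctiles:
            lo = self.table[f"sim_p{q:g}_lo"]
            hi = self.table[f"sim_p{q:g}_hi"]
            ob = self.table[f"obs_p{q:g}"]
            ok = (ob >= lo) & (ob <= hi)
            hits += int(ok.sum())
            total += int(ok.size)
        return hits / total if total else np.nan


def pc_vpc(times, obs, pred, simulate, n_sim: int = 200, bin_edges=None,
           seed: int = 0, pctiles=(5, 50, 95), band: float = 95.0,
           prediction_corrected: bool = True) -> VPCResult:
    """Prediction-corrected VPC over time bins.

    ``times, obs, pred`` are flat arrays of observation times, observed
    values and population predictions (random effects at zero).
    ``simulate(rng) -> array like obs`` draws one replicate of the
    observations under the fitted model at the same design points. Each
    value y is corrected to y * median(pred in bin) / pred before
    percentile summaries. Empty bins are dropped with a warning.
    """
    times = np.asarray(times, float)
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    if n_sim < 2:
        raise ValueError("n_sim must be >= 2")
    if bin_edges is None:
        bin_edges = np.quantile(times, np.linspace(0, 1, 7))
        bin_edges[-1] += 1e-9
    bin_edges = np.asarray(bin_edges, float)
    which = np.digitize(times, bin_edges) - 1
    nb = bin_edges.size - 1

    rng = np.random.default_rng(seed)
    sims = np.stack([np.asarray(simulate(rng), float) for _ in range(n_sim)])

    rows = []
    alpha = (100 - band) / 2
    for b in range(nb):
        sel = which == b
        if not sel.any():
            warnings.warn(f"empty VPC bin {b}; dropped")
            continue
        if prediction_corrected:
            corr = np.median(pred[sel]) / np.maximum(pred[sel], 1e-12)
        else:
            corr = 1.0
        row = dict(bin=b, t_lo=bin_edges[b], t_hi=bin_edges[b + 1],
                   t_mid=float(np.median(times[sel])), n=int(sel.sum()))
        for q in pctiles:
            row[f"obs_p{q:g}"] = float(np.percentile(obs[sel] * corr, q))
            sim_q = np.percentile(sims[:, sel] * corr, q, axis=1)
            row[f"sim_p{q:g}_lo"] = float(np.percentile(sim_q, alpha))
            row[f"sim_p{q:g}_med"] = float(np.percentile(sim_q, 50))
            row[f"sim_p{q:g}_hi"] = float(np.percentile(sim_q, 100 - alpha))
        rows.append(row)
    return VPCResult(table=pd.DataFrame(rows), pctiles=tuple(pctiles),
                     n_sim=n_sim)
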