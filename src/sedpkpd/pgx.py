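"""Two-step pharmacogenetic screening of SNPs against individual clearances.

Step 1 filters the genotype matrix: SNPs with minor-allele frequency below
5% are excluded, and the rest are checked for Hardy-Weinberg equilibrium
with a 1-df chi-square test on the genotype counts. Step 2 regresses the
log individual clearances (empirical Bayes estimates from the population
fit) on the additive genotype code, SNP by SNP, and selects SNPs at a
Bonferroni-corrected level of 0.2/m. Selected SNPs are then candidates for
inclusion in the population model as a two-category covariate
(heterozygous and homozygous mutant grouped together).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MAF_MIN_DEFAULT = 0.05
BONFERRONI_ALPHA = 0.2


def minor_allele_frequency(g: np.ndarray) -> float:
    """MAF from additive codes {0,1,2}; folds to the minor allele."""
    g = np.asarray(g, dtype=float)
    g = g[np.isfinite(g)]
    if g.size == 0:
        return 0.0
    f = g.sum() / (2.0 * g.size)
    return float(min(f, 1.0 - f))


def hwe_chisq(g: np.ndarray):
    """1-df chi-square Hardy-Weinberg test on genotype counts.

    Returns (chi2, p). Monomorphic SNPs return (0, 1).
    """
    g = np.asarray(g, dtype=float)
    g = g[np.isfinite(g)]
    n = g.size
    obs = np.array([(g == 0).sum(), (g == 1).sum(), (g == 2).sum()], float)
    p = (obs[1] + 2 * obs[2]) / (2.0 * n) if n else 0.0
    if p in (0.0, 1.0):
        return 0.0, 1.0
    exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass
class ScreenResult:
    table: pd.DataFrame  # per SNP: maf, hwe_chi2, hwe_p, beta, p, flags
    maf_min: float
    hwe_alpha: float
    alpha: float
    bonferroni_threshold: float | None

    @property
    def selected(self) -> list:
        return list(self.table.index[self.table["selected"]])


def maf_hwe_filter(genotypes: pd.DataFrame, maf_min: float = MAF_MIN_DEFAULT,
                   hwe_alpha: float = 0.05):
    """Step-1 filter; returns (filtered genotype frame, per-SNP table)."""
    if not 0 < maf_min <= 0.5:
        raise ValueError("maf_min must lie in (0, 0.5]")
    snps = [c for c in genotypes.columns if c != "ID"]
    recs = {}
    for s in snps:
        g = genotypes[s].to_numpy(float)
        maf = minor_allele_frequency(g)
        chi2, p = hwe_chisq(g)
        recs[s] = dict(maf=maf, hwe_chi2=chi2, hwe_p=p,
                       pass_maf=maf >= maf_min,
                       pass_hwe=p >= hwe_alpha)
    tab = pd.DataFrame(recs).T
    keep = ["ID"] + [s for s in snps if tab.loc[s, "pass_maf"]
                     and tab.loc[s, "pass_hwe"]]
    return genotypes[keep], tab


def screen_snps(log_clearances, genotypes: pd.DataFrame,
                maf_min: float = MAF_MIN_DEFAULT, hwe_alpha: float = 0.05,
                alpha: float = BONFERRONI_ALPHA) -> ScreenResult:
    """Full two-step screen of SNPs against log individual clearances.

    ``log_clearances`` is aligned with the rows of ``genotypes`` (one value
    per subject). Missing genotypes drop the subject from that SNP's
    regression (complete-case per SNP). Selection is p < alpha/m across the
    m SNPs surviving step 1.
    """
    y = np.asarray(log_clearances, dtype=float)
    if y.size != len(genotypes):
        raise ValueError("clearances and genotype rows are misaligned")
    filtered, tab = maf_hwe_filter(genotypes, maf_min, hwe_alpha)
    tested = [c for c in filtered.columns if c != "ID"]
    m = len(tested)
    thresh = alpha / m if m else None
    if m == 0:
        warnings.warn("no SNPs survive the MAF/HWE filter; empty screen")
    tab["beta"] = np.nan
    tab["p_value"] = np.nan
    tab["selected"] = False
    for s in tested:
        g = filtered[s].to_numpy(float)
        ok = np.isfinite(g) & np.isfinite(y)
        if ok.sum() < 3 or np.ptp(g[ok]) == 0:
            continue
        res = stats.linregress(g[ok], y[ok])
        tab.loc[s, "beta"] = res.slope
        tab.loc[s, "p_value"] = res.pvalue
        tab.loc[s, "selected"] = bool(res.pvalue < thresh)
    return ScreenResult(table=tab, maf_min=maf_min, hwe_alpha=hwe_alpha,
                        alpha=alpha, bonferroni_threshold=thresh)


def grouped_covariate(genotypes: pd.DataFrame, snp: str) -> pd.Series:
    """Two-category NLME covariate: wild type vs carrier (het + hom grouped)."""
    g = genotypes.set_index("ID")[snp]
    return (g > 0).astype(float)


def read_genotypes(path) -> pd.DataFrame:
    """Read a delimited genotype table (ID + one {0,1,2} column per SNP)."""
    df = pd.read_csv(path, na_values=["."])
    if "ID" not in df.columns:
        raise ValueError(f"{path}: genotype table must have an ID column")
    bad = [c for c in df.columns if c != "ID"
           and not df[c].dropna().isin([0, 1, 2]).all()]
    if bad:
        raise ValueError(f"{path}: non-additive genotype codes in {bad}")
    return df
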