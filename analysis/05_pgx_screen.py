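#!/usr/bin/env python
"""Pharmacogenetic screening demonstration on synthetic genotypes.

Simulates an additive-coded genotype table with one causal variant that
doubles clearance per minor allele, plus null variants, and runs the
two-step screen (MAF >= 5%, Hardy-Weinberg chi-square, per-SNP additive
regression of log individual clearance, Bonferroni at 0.2/m). In the real
trial no variant survived the screen — consistent with the tiny sample;
here the causal variant is planted so the machinery's operating
characteristics are visible.

Writes results/pgx/screen.csv.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sedpkpd import pgx, trial  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "results" / "pgx"
SEED, N, N_SNPS, CAUSAL = 11, 50, 12, 4


def main() -> None:
    g, mult = trial.generate_genotypes(
        N, N_SNPS, maf=0.3, seed=SEED, effect_snp=CAUSAL,
        effect_per_allele=np.log(2.0))
    rng = np.random.default_rng(SEED + 1)
    # individual log clearances around a 5 L/h typical with 30% spread
    log_cl = np.log(5.0) + np.log(mult) + rng.normal(0.0, 0.3, N)
    res = pgx.screen_snps(log_cl, g)
    OUT.mkdir(parents=True, exist_ok=True)
    res.table.to_csv(OUT / "screen.csv")
    print(res.table.round(4).to_string())
    print(f"\nBonferroni threshold 0.2/{len(res.table[res.table.pass_maf & res.table.pass_hwe])} "
          f"= {res.bonferroni_threshold:.4f}")
    print(f"selected: {res.selected} (causal variant snp{CAUSAL + 1})")
    print(f"wrote {OUT / 'screen.csv'}")


if __name__ == "__main__":
    main()
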