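#!/usr/bin/env python
"""Replicate simulation-recovery study for all four population models.

For each arm, simulate replicate 50-subject trials from the published
final models and re-estimate; the replicate medians should sit close to
the generating typical values if the estimation machinery is unbiased.
Score-model recovery reduces the EC50 variability to 50% CV — at the
published 246-525% CVs a 50-subject trial carries almost no information
about the typical EC50.

This driver runs a reduced number of replicates for a quick look;
scripts/acceptance.py runs the full study (20 PK / 10 PD replicates).
Writes results/recovery/medians.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sedpkpd import studies  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "results" / "recovery"
N_PK, N_PD, SEED = 5, 5, 7

TRUTH = {("clonidine_pk", "cl"): 28.0, ("clonidine_pk", "v"): 202.4,
         ("midazolam_pk", "clm"): 33.4, ("midazolam_pk", "clom"): 211.6,
         ("midazolam_pk", "v"): 85.8, ("midazolam_pk", "vm"): 90.8,
         ("clonidine_pd", "ec50"): 2.73, ("clonidine_pd", "b0"): 15.6,
         ("midazolam_pd", "ec50"): 186.0}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    frames = {
        "clonidine_pk": studies.pk_recovery_study("clonidine", N_PK, SEED),
        "midazolam_pk": studies.pk_recovery_study("midazolam", N_PK, SEED),
        "clonidine_pd": studies.pd_recovery_study("clonidine", N_PD, SEED),
        "midazolam_pd": studies.pd_recovery_study("midazolam", N_PD, SEED),
    }
    rows = []
    for (study, parm), truth in TRUTH.items():
        med = float(frames[study][parm].median())
        rows.append(dict(study=study, parameter=parm, generating=truth,
                         replicate_median=round(med, 3),
                         rel_error_pct=round(100 * (med / truth - 1), 1)))
    tab = pd.DataFrame(rows)
    tab.to_csv(OUT / "medians.csv", index=False)
    for name, df in frames.items():
        df.to_csv(OUT / f"{name}_replicates.csv", index=False)
    print(tab.to_string(index=False))
    print(f"\n({N_PK} PK / {N_PD} PD replicates, 50 subjects each; "
          f"wrote {OUT / 'medians.csv'})")


if __name__ == "__main__":
    main()
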