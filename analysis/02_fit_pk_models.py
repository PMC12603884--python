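#!/usr/bin/env python
"""Fit the structural PK models to the simulated trial of step 01.

Clonidine: one-compartment with allometric weight scaling and PMA
maturation on clearance, lognormal between-subject variability on CL and
V, proportional residual error. Midazolam: parent + 1-OH metabolite with
variability on CLm and V and combined additive+proportional error per
analyte. BLQ observations are set to LOQ/2 before fitting.

With only ~14 subjects per arm and 2-4 samples each, single-trial
estimates scatter widely around the generating values — the replicate
study of step 04 is the systematic check. Writes
results/pk_fits/<arm>.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sedpkpd import io, models, nlme  # noqa: E402

ROOT = Path(__file__).resolve().parents[1] / "results"
GENERATING = dict(
    clonidine=dict(cl=28.0, v=202.4),
    midazolam=dict(v=85.8, clm=33.4, vm=90.8, clom=211.6))


def main() -> None:
    ds, _ = io.read_dataset(ROOT / "trial" / "dataset.csv")
    ds = nlme.blq_impute(ds, {io.OBS_CLON_CONC: 0.1, io.OBS_MID_CONC: 0.5,
                              io.OBS_M1_CONC: 0.1})
    out = ROOT / "pk_fits"
    out.mkdir(parents=True, exist_ok=True)
    for arm, build in [("clonidine", models.clonidine_pk_problem),
                       ("midazolam", models.midazolam_pk_problem)]:
        fit = nlme.fit_population(build(ds), n_starts=3, seed=1)
        payload = dict(ofv=fit.ofv, converged=fit.converged,
                       estimates={k: float(v)
                                  for k, v in fit.estimates.items()},
                       rse_percent=fit.rse_percent,
                       iiv_percent_cv=fit.iiv_percent("cv"),
                       generating=GENERATING[arm])
        (out / f"{arm}.json").write_text(json.dumps(payload, indent=2))
        fit.ebe_table().to_csv(out / f"{arm}_ebe.csv", index=False)
        shown = {k: round(float(v), 1) for k, v in fit.estimates.items()
                 if k in GENERATING[arm]}
        print(f"{arm}: OFV {fit.ofv:.1f}; typicals {shown} "
              f"(generating {GENERATING[arm]})")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
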