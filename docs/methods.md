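# Methods

This note documents the models, the estimation machinery, the
synthetic-data generator and the design choices behind `sedpkpd`, in the
package's own terms. It states no empirical result beyond what the test
suite and `scripts/acceptance.py` themselves compute.

## Setting and scope

The package implements the population PKPD analysis of a double-blind
pediatric ICU sedation trial (clonidine vs. midazolam, 1:1, neonates to
six-year-olds, COMFORT-B as the sedation endpoint) whose individual-level
data are not publicly available. Everything downstream of raw data is
implemented: structural PK and score models, mixed-effects estimation,
evaluation diagnostics, a two-step pharmacogenetic screen, and
virtual-population regimen simulation. Because the data cannot be
re-analysed, the package's empirical claims are *simulation-recovery*
claims: data generated from the published final models, under the trial's
design, must be recovered by the package's own estimator.

Out of scope by design: the trial's noninferiority endpoint analysis, the
full nurse-facing dosing algorithm (replaced by a two-threshold titration
band), morphine PK and its score effect (found nonsignificant in the
original analysis), proportional-odds/bounded-integer score models (tested
but not selected there), and adverse-event modelling.

## Structural PK models

Clonidine follows a one-compartment model; midazolam a one-compartment
parent model with complete conversion to 1-OH midazolam, which occupies a
second compartment with its own volume and elimination clearance. All
dosing is intravenous; loading doses are modelled as 15-minute infusions
(the clonidine loading duration is stated trial protocol; the midazolam
loading duration is not stated and defaults to the same 15 minutes,
configurable — the trial's blinding required identical administration
procedures in both arms, which makes a shared duration the natural
default).

Units are fixed package-wide: hours, kg, µg doses, µg/h rates, L volumes,
ng/mL concentrations (1 µg into 1 L = 1 ng/mL), with any conversion at the
I/O boundary.

Individual parameters combine allometric scaling to a 70-kg reference
(0.75 on clearances, 1 on volumes), a sigmoid PMA maturation on clearances
only, and lognormal random effects. Maturation constants are fixed model
inputs per drug (61.6 wk / 2.42 for clonidine; 73.6 wk / 3 for midazolam).
Whether maturation should multiply the metabolite elimination clearance
CLom as well as the formation clearance CLm is not determined by the model
family; the default applies it to both clearances (`mature_clom=False`
restricts it), on the argument that 1-OH elimination is itself a hepatic
clearance process that matures.

Concentrations are computed from the exact piecewise-analytic solution of
the linear system, superposed over dose events and fully vectorised (the
reference path, fast enough for the estimator's inner loops). An
independent ODE-integrator route exists solely as a cross-check; tests
require agreement within 1e-6 relative on random regimens. The parent =
metabolite rate-constant degeneracy in the two-compartment solution is
lifted by a 1e-9 relative nudge, far below that tolerance.

## COMFORT-B score model

The latent expected score composes additively from a baseline, an
inhibitory Emax drug effect, and co-medication effects; surgical subjects
replace the baseline with a postanesthesia washout that starts at the
fully anesthetized scale floor (BASE = 6) and rises with half-time TPS50
toward SMAX = BASE + PAEMAX. The maximal drug effect is fixed to 6 score
points — both constraints are stability devices inherited from the model
family, not estimated quantities. The sigmoid shape γ is not part of the
reported final model; the default is γ = 1 (plain Emax), exposed in the
model builders. The latent score is truncated at the scale floor of 6
(hard truncation; the model family gives no reason to prefer a soft
bound), and *reported* scores add proportional residual error, rounding to
integers, and clamping to [6, 31] — the latent model stays continuous, as
in the selected continuous-Emax analysis.

Random effects in the score model are carried on EC50 only (the reported
final model carries interindividual variability there only). The
clonidine arm estimates the nonsurgical baseline B0; in the midazolam arm
the baseline is pinned per subject to the observed pre-dose score, as in
the original analysis. The 1-OH metabolite contributes no score effect.
Bridging propofol, whose concentrations are never measured, enters as a
K-PD Emax term on the infusion-rate equivalent (IRE = kde·A of a virtual
compartment). The published propofol constants are not reproduced in the
source analysis; the package ships synthetic placeholder defaults (kde
2 /h, maximal effect 3 score points, EC50 1000 µg/h IRE), clearly labelled,
and every quantitative check involving propofol uses synthetic values.

## Estimation

Estimation maximises an approximate marginal likelihood by the Laplace
approximation with interaction — the well-defined counterpart of the
FOCE-I scheme used by the original analysis, asymptotically equivalent
here. Per subject,

    −2 log L_i ≈ g_i(η̂) − k·log 2π + log det(g_i''(η̂)/2),

with g_i the −2 log joint density and η̂ its minimiser. The inner mode
search is a damped Newton iteration with finite-difference derivatives
evaluated for *all* subjects and stencil points in a single vectorised
pass; steps are capped at two random-effect SDs and ridge-regularised
where the joint is locally indefinite. Inner tolerances (gradient 2e-3,
step 1e-6) sit above the finite-difference noise floor; warm starts from
the previous outer iterate make typical inner solves one to three steps.
On a linear Gaussian degenerate case the Laplace value is exact, and the
test suite checks it against the closed-form marginal likelihood at 1e-6.

The outer problem optimises log-transformed population parameters
(sign-free covariate coefficients stay untransformed) with L-BFGS-B on
coarse finite-difference gradients (step 1e-4); a Nelder-Mead fallback is
available. `fit_population` multi-starts from lognormally perturbed
initial values (default 3 starts, first unperturbed). Standard errors come
from the finite-difference curvature of the objective at the optimum
(delta method through the log transform) and are reported only when that
matrix is positive definite, mirroring the usual covariance-step
convention.

Residual models: proportional error for clonidine concentrations and for
scores; combined additive + proportional for midazolam parent and
metabolite, with separate parameters per analyte and per arm's score
stream. Ω is diagonal — the source analysis reports no η covariances.
Interindividual variability percentages are interpreted as lognormal CVs,
ω = sqrt(log(1 + (CV/100)²)); fits report both 100·sqrt(exp(ω²)−1) and
100·ω since the printed convention is not stated. Below-quantification
observations are retained at LOQ/2 (the source analysis's rule; BLQ
fractions are below 5% under the default design). Nested models are
compared by ΔOFV against a χ² reference; forward inclusion of a covariate
(entering as θ·exp(β·(cov−ref))) uses α = 0.05, i.e. ΔOFV > 3.84 for one
parameter — the original threshold is unstated, so the conventional one is
used.

## Model evaluation

The subject-resampling bootstrap refits each resample and summarises the
median and 90% percentile interval per parameter, reproducible by seed.
The prediction-corrected VPC multiplies each observation and simulated
value by (bin-median population prediction)/(own population prediction)
before computing observed 5/50/95th percentiles and simulation-based
confidence bands per time bin; empty bins are dropped with a warning. With
identical designs across subjects the correction is a no-op, which the
tests assert.

## Synthetic-trial generator

The generator is the package's stand-in for the trial and defines the
study conditions used everywhere:

* **Population.** Gestational age uniform on 36.3–40 wk; postnatal age
  lognormal (median 20 d, log-SD 2), truncated to [0, 2100] d; PMA = GA +
  PNA/7. Weight follows a monotone sigmoid of PMA (asymptote 24 kg,
  half-point 180 wk, Hill 1.4) with 15% lognormal individual variability
  truncated at ±2 SD — a stand-in with the right *shape* for the published
  weight-for-age approach, whose coefficients are not reproduced; only the
  covariate structure matters for testing the models. These choices put
  the bulk of subjects at 2–8 kg and 37–60 wk PMA with a tail of older
  children, matching the trial's demographic ranges (weights ~2–17 kg, PMA
  up to ~372 wk).
* **Arms and flags.** 1:1 block randomisation; per-arm surgery
  probabilities 7/15 and 11/13 and bridging-propofol probabilities 10/15
  and 6/13 (the trial's observed frequencies); surgery ends at the start
  of study time, so the postanesthesia clock runs on study time.
* **Dosing.** Clonidine 2 µg/kg loading (15 min) + 1 µg/kg/h; midazolam
  200 µg/kg + 100 µg/kg/h; both halved for PNA < 28 d. Every 3 h a
  two-threshold titration steps the rate ±30% (bounded to 0.25–4× the
  start) when the subject's latent score leaves the 11–22
  adequate-sedation band — a deliberate simplification of the trial's
  nurse-driven algorithm; titration realism, not fidelity, is what the
  models need. Bridging propofol is emitted as a 30-minute infusion dose
  record; its score effect is off by default because its constants are
  synthetic.
* **Observations.** 2–4 PK samples per subject: one shortly after the
  loading dose, one just before the end of treatment, extras uniform in
  between (the real sampling distribution beyond the two mandatory samples
  is unknown). Scores every 3 h from treatment start over a follow-up
  drawn uniform on 13–107 h (the trial's observed range). Residual errors
  per class at the generating values; concentrations below the LOQ
  (defaults 0.1 / 0.5 / 0.1 ng/mL for clonidine / midazolam / metabolite —
  plausible assay limits, not reproduced values) are flagged BLQ.
  Reported scores are integer, clamped to [6, 31].
* **Genotypes.** Additive codes drawn binomially at a configured MAF, with
  an optional planted multiplicative clearance effect.

What the generator does **not** emulate: informative sampling times,
dropout, adverse events, morphine co-medication, assay batch effects,
model misspecification of any kind. Passing recovery tests therefore
demonstrates that the estimator is consistent *under the assumed model*,
not that the model is right for real children.

## Recovery studies and problem sizes

`sedpkpd.studies` defines the replicate recovery designs: 50 subjects per
arm (larger than the real trial, so the checks isolate estimator
correctness rather than small-sample noise), sparse PK sampling with
follow-up 24–72 h, and 3-hourly scores over a fixed 48 h for the score
models. The acceptance script runs 20 PK replicates per drug and 10
score-model replicates per arm — enough for replicate medians to settle
well inside the published bootstrap intervals while keeping the whole run
at minutes on one CPU; the in-suite acceptance tests run reduced replicate
counts of the same designs. Score-model recovery sets the EC50 variability
to 50% CV: at the published 246–525% CVs a 50-subject trial carries almost
no information about the typical EC50, which the original analysis itself
shows as extremely wide bootstrap intervals.

The score-model fits are sequential and condition on the *individual* PK
parameters that generated each subject's concentrations (written alongside
the dataset by the generator), the simulation analogue of driving the
score model with individual predicted concentrations; re-analysing real
data would use the PK empirical Bayes estimates instead.

The regimen study simulates 1000 virtual children with PNA > 28 d (the
headline regimens' population; a neonatal half-dose variant is available
through the protocol objects), individualises PK and EC50 with full
variability, and summarises latent trajectories on a 0.05-h grid;
percentile bands use the continuous latent score (a typical-trajectory
reading; residual reporting noise can be switched on). Time-to-target
interpolates the median concentration linearly between grid points. The
"median reaches the EC50" metric is implemented as the median
*concentration* crossing the typical EC50 (the alternative reading —
median of individual crossing times — is not what a percentile-band figure
displays).

## Numerical choices and degenerate inputs

Residual variances are floored at 1e-10 to keep zero-prediction points
finite; predictions of the score model are floored at the scale minimum
before the error model; the Laplace determinant uses the minimally nudged
Hessian at the mode. Non-finite objectives at the initial values raise
with the offending subject IDs; non-convergence is flagged on the result,
never silent. Monomorphic SNPs are excluded with MAF 0 rather than
erroring; missing genotypes drop the subject from that SNP's regression
only. All random draws flow through seeded `numpy` generators;
identical seed + configuration reproduces identical files.

## Known limitations

* FOCE-I is approximated by Laplace-with-interaction; on very sparse
  designs the two can differ slightly, which the recovery tolerances
  absorb.
* The outer optimiser is a general-purpose quasi-Newton on
  finite-difference gradients; pathological likelihood surfaces (e.g. the
  full 525% CV EC50 problem at small n) can end in local optima — the
  multi-start option and replicate medians are the mitigations.
* The weight-for-PMA curve, propofol K-PD constants and LOQs are
  package-chosen stand-ins (documented above), not reproduced values.
* Bootstrap and pcVPC are provided and tested at small scale; they are
  evaluation tools, not part of the headline recovery pipeline.
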