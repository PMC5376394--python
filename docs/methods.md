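# Methods

## Whole-body model structure

The body is a closed circulatory loop of 13 compartments: venous blood,
arterial blood, lung, and ten parallel systemic tissues (brain, heart, skin,
muscle, adipose, spleen, gut, liver, kidney) plus a lumped "rest"
compartment. The lung sits in series and carries the entire cardiac output;
the parallel tissues share it according to fixed flow fractions. Drug
distribution is perfusion-limited everywhere: tissue *t* with volume `V_t`,
flow `Q_t` and partition coefficient `Kp_t` obeys

    dA_t/dt = Q_t * (C_art - C_t / Kp_t),        C_t = A_t / V_t

so at steady state the total tissue:plasma concentration ratio equals
`Kp_t` — this identity is used as a wiring oracle in the tests. The system
is linear; two independent solution routes (adaptive stiff integration and
piecewise matrix-exponential propagation) are cross-checked to 1e-6
relative, and a fast eigendecomposition-based plasma solver (exact for the
piecewise-constant infusion input) drives the population likelihood.
Blood:plasma concentration ratio is assumed 1 (configurable scalar).

**No active transport or permeability limitation is modelled**; partition
coefficients are clinical/literature quantities, not predicted from tissue
composition.

### Physiology scaling

Organ volumes are fractions of body weight; flows are fractions of cardiac
output; both are sex-specific and read from `data/physiology.yaml`. Cardiac
output scales allometrically, `CO = CO_ref (W/W_ref)^0.75` (exponent
configurable). Blood is split 1:2 arterial:venous (configurable). The
shipped table is a **synthetic stand-in** assembled from standard
reference-man/-woman compilations (the originally used literature tables are
not published); its values were fixed once, with two structural choices
worth noting:

* In this all-parallel topology the gut and spleen drain directly into the
  venous pool, so the liver entry is assigned (most of) total hepatic
  perfusion and the splanchnic direct flows are trimmed to keep the parallel
  circuit summing to the cardiac output.
* "Rest" closes both balances exactly (volume = weight minus named tissues
  and blood; flow = CO minus named flows). It is a slow, high-volume
  aggregate: unlike every named organ it does *not* peak at the end of a 1-h
  infusion, which is why the fast-distribution check is asserted for plasma
  and the ten named tissues only.

### Clearance

    CL   = CL_R + CL_NR
    CL_R = CRCL * 0.06 * fu * (1 + f_secretion)     [l/h; CRCL in ml/min]

with `fu = 0.65`. By default renal elimination is drawn from the kidney
compartment and non-renal elimination from the liver compartment, each
proportional to the emergent tissue outflow concentration `C_t/Kp_t`. This
preserves the whole-body interpretation but makes the emergent total
clearance run *below* the nominal `CL_R + CL_NR`: the eliminating organ's
outflow concentration sits below the arterial concentration by the factor
`Q/(Q + CL)`. At the default parameterization (hepatic `CL_NR` = 13.5 l/h
against ~87 l/h hepatic flow) the measured deficit is ~11 % — a real
property of organ-sited elimination at moderate extraction, not a numerical
error. A `"central"` mode (both clearances acting on venous blood)
reproduces the nominal clearance exactly and is the recommended sensitivity
check when dose/AUC arithmetic must match the two-term clearance model.

### Unbound extracellular conversion

    fue = 1 / (1 + E/P * (1 - fu)/fu)

`E/P` (extracellular-to-plasma albumin ratio) per tissue comes from
`data/extracellular_albumin.yaml`, a **synthetic stand-in** patterned on
rodent interstitial-albumin measurements; lung and brain sit at the
albumin-poor end of their reported ranges (epithelial lining fluid, CSF).
Under these defaults the unbound-exposure ranking is kidney > lung >
(heart, gut, liver) > ... > muscle > brain > skin > adipose.

## Population estimation

Observations are natural-log plasma concentrations. The individual model
applies one log-normal random effect to *total* clearance (renal and
non-renal multiplied together; configurable to non-renal only — the shared
multiplier is a modelling choice, not a data-identified structure) and one
log-normal effect shared by all partition coefficients; `f_secretion`
carries no between-subject variability; the residual error is additive on
the log scale (SD 0.33 by default, the standard equivalence of a ~33 %
proportional error).

The marginal likelihood uses a **Laplace approximation**: per subject the
joint negative log-likelihood is minimized over the two random effects
(BFGS, warm-started between outer iterations) and corrected with
`0.5 log det H` from a central-difference Hessian at the mode. Against
brute-force dense-quadrature integration on a one-compartment toy the
approximation is accurate to a few tenths of a percent for designs with
several observations per subject; it degrades for extremely sparse designs
(1-2 observations with strong nonlinearity), which is the usual behaviour of
conditional-mode approximations. A non-positive-definite inner Hessian is
flagged, the subject's contribution inflated, and a warning logged.

Fixed-effect priors are independent normal penalties on the log scale,
`(log θ − log mode)² / (2 cv²)`, with `cv = 0.25` by default for all eleven
`Kp`, `CL_NR` and `f_secretion`; the rest-compartment prior mode is derived
as the arithmetic mean of the ten tissue priors (2.77 with the packaged
values). This is the fixed-effect reduction of the usual frequentist-prior
machinery; no prior is placed on the variance components. The outer
optimizer is L-BFGS-B over log fixed effects and, optionally, log variance
components, started at the prior modes, bounded at ±4 log units, with
objective history recorded per accepted iteration (descent holds to within
the small noise floor of the warm-started inner optimizations). Standard
errors, on request, come from a finite-difference Hessian of the negative
log-likelihood; relative standard errors on the normal scale equal the
log-scale SEs. A `delta_ofv` utility and the conventional 10.83-point
threshold (chi-square, 1 df, p < 0.001) support manual model comparison; no
automated model search is performed.

The prediction-corrected VPC bins observations by time after the most
recent dose (quantile bins, default 8) and divides each observation and
simulated value by its bin's median population prediction, then reports
median/5th/95th percentiles with 95 % confidence bands across replicates
(default 500; fewer than 200 warns, fewer than 20 is an error).

## Bacterial growth/kill model

Per strain: susceptible `b_s`, less-susceptible `b_r` (EC50 inflated by a
configurable factor, default 10) and filamentous non-countable `b_f`
states. The published description of the in-vitro model fixes the rate
constants (growth 1.70/h, death 0.179/h, subpopulation 0.819 per 1e6 CFU/ml
inoculum, filamentation window 5.34 h) but not the full equations; the
compartment structure here is a **documented reconstruction** capturing
every stated feature, with all rates and the filament routing rule
configurable so a complete published system can be dropped in.

Choices made where the description is silent:

* **Ceiling.** A literal `k_growth (1 − B/b_max) b − k_death b` law comes to
  rest at `(1 − k_death/k_growth) b_max ≈ 0.895 b_max`. Because `b_max` is
  meant as the observed maximal bacterial concentration, the logistic
  bracket uses an internal capacity `b_max · k_growth/(k_growth − k_death)`
  so that the stationary total equals `b_max` exactly while the low-density
  net growth rate stays `k_growth − k_death = 1.521/h`.
* **Filamentation.** During the 5.34-h window after first drug exposure
  (clock configurable to dose start) drug-induced kill flux is diverted into
  `b_f` — live biomass invisible to plating — instead of removed; afterwards
  it is removal. Filaments do not divide and decay at the natural death rate
  plus any immune kill. The fate of filaments after the window is not
  described in the source; decay-without-division is the reconstruction's
  assumption.
* The less-susceptible subpopulation grows at the same rate as the
  susceptible one (not stated; assumed yes).

Drug kill is `emax_kill · C^h / (EC50^h + C^h)` with `EC50 = α · MIC`
(defaults `α = 1`, `emax_kill = 6/h`, `h = 1`) — **none of these are
published values**, so scenario outcomes that depend on them are labelled
qualitative. The immune term (above) uses published constants
(`Kkill_ANC = 1.74/h`, `ANC50 = 190.8 cells/µl`, `B50 = 4.3e6 CFU/ml`,
constant `ANC = 2500 cells/µl`; a hook accepts a time-varying ANC). It
applies identically to all bacterial states.

Under the defaults the qualitative predictions reproduce the reference
directionality in kidney (wild-type eradication; resistant take-over
without the immune term; immune-mediated eradication of the resistant
strain). The reported lung outcome for the resistant strain (regrowth even
with immune support) is *not* reproduced at the default inoculum of
1e6 CFU/ml — at that burden the immune term alone nearly balances net
growth, so modest lung exposure tips the balance to eradication. This is a
direct consequence of the unpublished kill parameters and of the inoculum
choice (the two-strain experiments state 5e6 + 5e6 CFU/ml; single-strain
inocula are not stated), and is called out rather than tuned away.

## Synthetic cohorts

Virtual ICU patients: weight ~ N(77, 16²) kg truncated at 30 kg, CRCL ~
N(82, 51²) ml/min truncated at 5 ml/min, 26.5 % female, age N(60, 17²)
carried as metadata only (the model uses weight, sex, CRCL), treatment
duration uniform on 3–21 days, regimen mix 86:9:6:1 for 400 mg q12h / 400 mg
q8h / 200 mg q12h (0.5-h infusion) / 600 mg q12h. Covariates are drawn
independently — real ICU weight/renal-function correlations are not
emulated. Sampling: per subject ~Poisson(5.8) observations (min 1) spread
over ~Poisson(3.1) dosing occasions, at template times {0.5, 1, 1.5, 2,
τ/2, τ−0.5} h after dose start with 0.15-h jitter — a typical
therapeutic-drug-monitoring design standing in for the unpublished true
schedule. Between-subject variability uses `ω = sqrt(ln(1 + CV²))` (CV 56 %
clearance, 55 % partition coefficients) and residual SD 0.33 on the log
scale. Everything is deterministic given the design seed.

Because the generator shares the prediction engine with the estimator,
recovery tests demonstrate *self-consistency* of the estimation machinery,
not robustness to model misspecification, assay error structure, BLQ
censoring or covariate correlation — none of which are present in the
synthetic data.

## Numerical choices and problem sizes

* ODE integration: LSODA, `rtol 1e-8 / atol 1e-10` by default (all
  configurable); integration proceeds piecewise between infusion on/off
  breakpoints so input discontinuities never cross an adaptive step.
  Bacterial system: LSODA at `rtol 1e-8 / atol 1e-3` CFU/ml, states clipped
  at zero inside the right-hand side; a materially negative solution raises.
* Steady-state identity checks run to 5000 h of constant infusion; the
  tissue:plasma ratio converges as O(1/t) there (machine precision if
  differenced over a late window).
* The packaged recovery experiment uses 30 subjects with the study's
  sampling density and variability, priors centred at the generating values,
  variance components fixed at truth (the experiment targets fixed-effect
  recovery), L-BFGS-B capped at 40 outer iterations; typical worst-case
  recovery error across `CL_NR` and all `Kp` is ~11 %. The noise-free check
  (4 subjects, dense sampling, residual SD 1e-4, zero random effects,
  15 %-perturbed start) recovers every parameter to well under 1 %.
* The Laplace-validity check integrates the random effect by dense
  trapezoid quadrature (2e5 points over ±6 SD); plain fixed-grid
  Gauss–Hermite is *not* a reliable oracle here because the conditional
  likelihood can peak sharply far from the prior mean.
* Reporting conventions: eradication = countable < 1 CFU/ml at the horizon;
  regrowth = > 10-fold post-nadir increase; both configurable, neither a
  published threshold.

## Known limitations

* Partition coefficients are total-tissue quantities; intracellular
  accumulation and active transport (efflux at barriers) are outside the
  model.
* Organ-sited elimination under-delivers nominal clearance by ~11 % (see
  above); use `"central"` mode when exact clearance bookkeeping matters.
* The physiology and albumin-ratio tables are documented stand-ins; swap in
  preferred values via the YAML configs for quantitative work.
* Strain kill parameters are reconstruction defaults; only directional
  statements should be read from the infection scenarios.
* The Laplace approximation has no fallback to adaptive quadrature for
  very sparse subjects; their marginal contributions are approximate.
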