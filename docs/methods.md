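# Methods

## The model

`cartqsp` implements a population quantitative systems pharmacology (QSP)
model of CD19-specific CAR-T cell therapy in non-Hodgkin lymphoma. Five
species are tracked from the day of infusion (t = 0): the concentrations of
four CAR-T cell phenotypes — naïve (T_N), central memory (T_CM), effector
memory (T_EM), and terminally differentiated effector (T_Eff) cells, all in
cells·µL⁻¹ — and the CD19⁺ metabolic tumor volume (MTV, in mL).

The phenotypes follow the progressive differentiation lineage
T_N → T_CM → T_EM → T_Eff with first-order rate constants k12, k23, k34.
T_N, T_CM, and T_EM expand on tumor contact through a Michaelis–Menten term

    Vmax1 · CD19⁺ · T / (KM1 + T),

which saturates in the *T-cell* concentration: at high CAR-T concentrations
expansion becomes proportional to tumor burden alone. (The explored
alternative with the tumor volume in the denominator is available as
`expansion_denominator="tumor"` but is not the selected model form.) Each
phenotype additionally proliferates homeostatically (kp1–kp3; absent for
T_Eff) and dies (ke1–ke4). The tumor grows logistically with rate k5 toward
carrying capacity K0 and is killed by each phenotype via
Vmax5,x·T_x·CD19⁺/(KM5 + CD19⁺). Units are kept mixed (µL vs mL) on
purpose: µL refers to the T-cell distribution volume, mL to the tumor.

Initial conditions impute 0.1 cells·µL⁻¹ per phenotype — the pre-infusion
distribution phase is discounted — and the baseline MTV. The packaged
default parameter set (`data/default_parameters.yaml`) carries the final
population estimates, including the derived relations: the killing rates of
T_N/T_EM/T_Eff are fixed multiples (2.57/4.04, 3.78/4.04, 4.24/4.04) of the
estimated T_CM rate, and the death rates of the long-lived phenotypes equal
2% of the effector death rate (0.518 × 0.02 ≈ 0.0104 day⁻¹, i.e. a 96-day
lifespan).

## Mixed-effects layers

Between-patient variability is exponential, θᵢ = θ·e^η with η ~ N(0, ω²),
on exactly two parameters: the baseline maximum expansion rate (reference
population only) and the T_CM killing rate. Variances are reported as
coefficients of variation using the log-normal relation
CV% = √(e^{ω²} − 1)·100; its inverse is exact, and the 150%/307% CV defaults
round-trip to machine precision.

Two typical-value subpopulations exist for the baseline expansion rate: a
reference population (Vmax1,base,ref = 0.00846) and a low-expansion
subpopulation (Vmax1,base,low = 0.000700, a 92% reduction) mixed with
probability MIXP = 0.803 of reference membership. Covariates enter as

    reference: Vmax1 = Vmax1,base,ref · (1 + 2.53·ASCT) · (CD4/CD8 day-7 ratio)^(−0.385)
    low:       Vmax1 = Vmax1,base,low · (1 + 2.53·ASCT)

— the day-7 ratio applies only to the reference population, and a missing
ratio is imputed with the neutral value 1.

Residual variability is additive on the log scale (log-transform-both-sides)
with one variance per species. Tumor scans recorded as 0 mL (complete
response) cannot enter a log-residual model; they are treated as
left-censored at a configurable limit of quantification (default 0.1 mL),
contributing a normal log-CDF term. Excluding them instead is available via
the data layer but censoring is the default.

## Synthetic cohorts

The generator emulates the study design: cell sampling at days 7, 14, and
26 (the protocol window "days 25–28" collapses to its center; optional
jitter), tumor scans at days 0, 30, 90 (months converted at 30 days/month),
log-normal residual noise per species, and truncation of tumor values below
the LOQ to censored zeros. Covariates are drawn independently: baseline MTV
log-normal with median 100 mL and log-sd 1.5 truncated to 2.5–3600 mL
(matching the observed clinical span), previous ASCT ~ Bernoulli(0.37), and
the day-7 CD4/CD8 ratio log-normal around 1 (log-sd 0.5). The joint
covariate distribution of the clinical cohort is unreported, so no
correlation between covariates (e.g. ASCT vs tumor burden) is induced; in
particular the generated low-expansion subpopulation does *not* inherit the
higher baseline tumor burden seen clinically. Consequently, passing tests
show that the pipeline recovers what the generator encodes — they do not
certify behavior under covariate correlation structures absent from the
generator.

Optional survival records are exponential with the hazard linked to the
true subpopulation (default hazard ratio 4 for low expansion, reference
median 12 months) and administrative censoring at 24 months of follow-up.
This survival layer exists purely to exercise the endpoint stage end to
end; the clinical study observed survival rather than modeling it.

## Estimation

The population fit maximizes the sum over patients of the log of the
mixture-weighted marginal likelihood, with MIXP estimated on the logit
scale and positive parameters on the log scale. Each subpopulation marginal
integrates the random effects by a Laplace approximation at the per-patient
mode (the empirical Bayes estimate). Laplace was chosen over re-implementing
first-order conditional estimation: it is a conditional approximation of
comparable accuracy, radically simpler, and directly testable against
brute-force quadrature (the suite checks 1% agreement on a single-eta
patient; the approximation degrades as the prior variance grows, reaching
~1–3% at ω² ≈ 0.5 on a one-observation patient).

Numerical choices:

- Inner problem: damped Gauss–Newton on the log-residuals with
  finite-difference Jacobians (step 0.02), warm-started per patient across
  outer iterations; step-size convergence tolerance 1e−3 during population
  fitting (1e−6 for standalone marginal evaluation). The Gauss–Newton
  Hessian — positive definite by construction — supplies the Laplace
  determinant during fitting; an exact central finite-difference Hessian
  (`hessian="fd"`) is the default for standalone evaluation.
- Outer problem: Nelder–Mead with best-so-far OFV tracking (the recorded
  history is non-increasing by construction). The default is a single start
  from the supplied initial values; jittered restarts (`n_starts`) are
  available. Nelder–Mead tolerates the small residual noise left by the
  inner tolerance better than finite-difference quasi-Newton steps.
- ODE solves inside the likelihood use LSODA at rtol 1e−6 (reporting
  simulations use rtol 1e−8, atol 1e−10, on a 0.1-day grid with tiny
  negative excursions clipped at −1e−9). Trajectories and per-patient
  marginals are memoized keyed by the parameters that affect them, so
  likelihood evaluations that revisit parameter subsets are nearly free.
- Degenerate cases: ω² = 0 reduces the marginal exactly to the plug-in
  likelihood at η = 0; MIXP pinned at 1 (or 0) skips the other branch
  entirely; a fitted MIXP collapsing below 1e−3 (or above 1−1e−3) raises a
  degenerate-mixture warning rather than hiding it; inner non-convergence
  falls back to the best iterate with a flag.

Covariate inclusion is judged by the likelihood-ratio test: ΔOFV > 3.84
(χ², 1 df, α = 0.05), with the general chi-square quantile for other df.
Parameter uncertainty uses iterative sampling importance resampling with
the schedule 5 × (1000, 1000, 1000, 2000, 2000 samples / 200, 400, 500,
1000, 1000 resamples), scalable down proportionally; the proposal is a
normal in the unconstrained space with covariance from the inverse
numerical Hessian at the optimum (regularized with a warning when
indefinite). Relative standard errors are sd(resamples)/estimate·100 on the
natural scale.

### Experiment sizes

Recovery experiments use n = 100 virtual patients (19 patients cannot
identify all variance parameters): the suite checks that the two baseline
expansion rates are recovered within ±30%, MIXP within ±0.12, subpopulation
classification accuracy ≥ 90%, and ΔOFV > 3.84 for a simulated ASCT effect.
Residual CVs are recovered within ±25% on a zero-IIV cohort, a design that
isolates the residual layer (with IIV active, five residual variances and
two IIV variances are poorly separable at this size). The reduced recovery
problem frees the three mixture parameters and fixes the variance
parameters at their known generating values. The acceptance script scales
the fitted cohorts to n = 40 and the SIR schedule to 5% so the whole
pipeline re-runs in minutes; the end-to-end composite-score chain uses
n = 200.

## Endpoints

Cell-kinetic metrics of the total CAR-T concentration: Cmax, Tmax (earliest
argmax), and trapezoidal AUC over days 0–28. Observed-basis series without
a day-0 sample are anchored at the total imputed dose (0.4 cells·µL⁻¹) —
the interpolation scheme for sparse clinical sampling is not otherwise
specified, so linear interpolation with truncation at day 28 is used. The
observed Cmax is taken as the maximum across the sampled days.

The clinical composite score is CCS = Cmax(phenotype)/baseline MTV,
homogeneous of degree +1 in Cmax and −1 in MTV; it is unit-preserving and
applies unchanged to qPCR-derived concentrations (copies·µg⁻¹ DNA). The
ROC cut-off uses the Youden index (sensitivity + specificity − 1) — the
optimality criterion behind the clinical cut-off is unstated, and Youden is
the standard default; ties break toward higher specificity. Correlations
between CCS and the expansion capacity use the raw scale for flow-based
scores and log10 for cross-platform (flow vs qPCR) comparisons.

Survival analysis goes through lifelines: product-limit curves with medians
reported as an explicit "not reached" sentinel (`None`, never a number),
two-group and pairwise log-rank tests, and univariate Cox
proportional-hazards fits (Breslow ties, Wald intervals) with a
Schoenfeld-residual diagnostic and an explicit flag for monotone-likelihood
separation. A hazard ratio translates to a percent risk reduction as
(1 − HR)·100, rounded to the nearest integer as in clinical reporting.

## Known limitations

- No pre-infusion distribution, apheresis, or manufacturing kinetics; no
  lymphodepletion effect on tumor volume.
- The two IIV positions are fixed by design; correlated random effects are
  not supported (none were reported).
- Laplace ≠ FOCE-I: OFV values are internally consistent but not numerically
  comparable with other estimation software.
- The clinical cut-off value CCS_TN = 0.00136 cannot be recalibrated here —
  the patient-level clinical data are not public; synthetic cohorts support
  qualitative (separation, stratification) but not numeric reproduction of
  patient-level endpoints.
- The synthetic covariate generator draws covariates independently; real
  cohorts exhibit covariate–subpopulation correlations the tests therefore
  do not probe.
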