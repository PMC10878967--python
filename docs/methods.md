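# Methods

`sweptrial` implements the analytic machinery of a cross-sectional
stepped-wedge cluster-randomized trial of intrapartum care: the Robson
ten-group cesarean classification, relative-risk estimation by
modified-Poisson GEE with a small-sample-corrected sandwich variance,
ICC estimation, closed-form and simulation-based power, and a
synthetic trial generator that lets every stage run without any
external data. This note records the models, the defaults and why
they were chosen, the numerical decisions, and what the synthetic
validation does and does not establish.

## Design geometry

A stepped-wedge design enrolls all clusters under the control
condition and crosses them over to the intervention at staggered,
randomly assigned steps; all clusters finish on intervention. The
reference geometry is four hospitals and seven analysis periods of 61
days (about two months) starting 1 July 2021, with one hospital
crossing over after each of periods 1–4 and the trial ending 15 July
2022, which truncates the seventh period to 14 days. A 14-day
transition window opens at each crossover; births in the window are
assigned to neither arm and are excluded from analysis (the window
models the time the intervention needs to bed in). All of this is
configurable through `SWDesign`; `condition(cluster, date)` is the
single source of truth for planned exposure, and the
intention-to-treat pipeline derives each woman's condition from her
birth date and the schedule, never from a recorded exposure column.

## Robson classification

Every birth maps to exactly one of ten mutually exclusive,
all-inclusive groups from six characteristics: parity, previous
cesarean, onset of labor, fetal presentation/lie, number of fetuses,
and term (≥ 37 completed weeks, configurable) versus preterm. The
hierarchy is applied top-down: multiple pregnancy (8); transverse or
oblique lie (9); breech, nulliparous/multiparous (6/7); cephalic
preterm (10); cephalic term with previous cesarean (5); then the
laboring low-risk groups 1–4 split by parity and onset, with induced
labor and prelabor cesarean pooled (the undivided ten-group version —
no 2a/2b or 5.1/5.2 subdivisions). Groups 6, 7, 9 and 10 absorb
previous-cesarean women. Records with unknown onset or presentation
are rejected with a validation error naming the field rather than
imputed; the audit table counts women once regardless of plurality.

## Effect model

For each binary outcome the estimand is a population-average relative
risk. The model is "modified Poisson": a log-link regression with the
Poisson variance function applied to the binary outcome, estimated by
GEE with an exchangeable working correlation, with a linear predictor
containing exactly an intercept, the treatment indicator and period
fixed effects (first analysis period as reference; empty levels
dropped; unbalanced panels supported). Fitted probabilities above 1
are possible under the log link; they are counted in diagnostics
(`n_pred_gt1_`) but never clamped, since clamping would change the
estimates.

The working-correlation parameter is updated each IRLS iteration by
the classical moment estimator — standardized Pearson-residual
cross-products averaged over within-cluster pairs, divided by the
scale, with the scale taken as the mean squared Pearson residual —
and clipped to ±5% inside its positive-definiteness boundary
(−1/(n_max − 1), 1), because iterates that sit on the boundary make
the working correlation singular and the fit oscillate. Convergence
is declared when the maximum absolute coefficient change drops below
1e−8 (at most 100 iterations); a fit that reaches the cap is returned
flagged, never silently as converged, and the pipeline renders such
outcomes as "no estimate" rows with crude statistics only.

Because the Bernoulli outcome deliberately misspecifies the Poisson
variance, all inference is sandwich-based. With N = 4 clusters the
ordinary sandwich is biased downward, so the default is the
Mancl–DeRouen correction: each cluster residual is inflated by the
inverse of (I − H_i), H_i the cluster leverage. Algebraically the
corrected cluster score equals (I_p − G_i A⁻¹)⁻¹ q_i with
G_i = D_iᵀV_i⁻¹D_i and q_i = D_iᵀV_i⁻¹e_i, so the correction is a
p-dimensional solve per cluster rather than an n_i-dimensional one;
the exchangeable inverse is applied in closed form
(R⁻¹ = c₁I + c₂J), keeping every step O(n_i p²). Both variance
estimators reproduce an independent dense-matrix computation to 1e−8
and statsmodels' robust and bias-reduced GEE covariances to machine
precision in the cross-check tests. Confidence intervals and p
values use a t reference with N − 2 degrees of freedom, the
conservative convention for a handful of clusters.

Duration outcomes (days) report the raw intervention-minus-control
mean difference, with the CI and p value from the treatment
coefficient of an identity-link Gaussian GEE run through the same
Mancl–DeRouen + t(N − 2) machinery.

The ICC of a binary outcome is reported as the fitted exchangeable
alpha of a control-period GEE without the treatment term; its CI is a
seeded cluster bootstrap (2,000 resamples by default, percentile
interval, lower bound truncated at 0 — the paper-style model-based
alternative is not implemented because the bootstrap is the more
honest quantification with four clusters). Two properties of this
estimator matter for interpretation: it pools within-period pairs
(correlation ρ) with cross-period pairs (ρ·r), so its expectation
sits slightly below ρ; and with very few clusters the period fixed
effects absorb part of the between-cluster variation, biasing it
further downward (measured mean ≈ 0.014 at true ρ = 0.02 with 4
clusters, ≈ 0.018 with 12). The acceptance suite therefore checks
recovery in the 12-cluster regime where the estimator is consistent
and documents the 4-cluster bias as expected behavior.

## Power

The closed form works on cluster-period means by generalized least
squares under nested-exchangeable correlation. Cluster i contributes
a T×T covariance block with diagonal σ²(1 + (m_eff − 1)ρ)/m_eff and
off-diagonal σ²ρr, where σ² = p̄(1 − p̄) at the midpoint of the two
proportions (sensitivity to this choice is under one power point
here), ρ is the within-period ICC, r the cluster autocorrelation, and
m_eff the effective cluster-period size. Unequal cluster-period
sizes with coefficient of variation CV degrade information by the
standard relative-efficiency factor, m_eff = m/(1 + CV²); partial
periods scale m_eff by their fraction of analysis days, which is how
the truncated final period and the transition windows enter the
calculation. GLS with intercept, period effects and the treatment
staircase gives Var(θ̂), and power is the normal approximation
Φ(|p₀ − p₁|/SE − z₁₋α/₂); under a null effect this returns α/2. At
the reference design (p 0.40 → 0.30, ρ = 0.02, r = 0.90, m = 300,
CV = 0.60, α = 0.05) the closed form gives 91.7%.

The simulation arm generates whole individual-level trials (a
homogeneous Robson-Group-1 cohort whose cluster-period size is the
analysis denominator itself) and analyses each with the package's own
GEE. Two power numbers come back. `power` applies a per-trial
rejection rule — by default the trial's actual inference,
Mancl–DeRouen + t(2), which with four clusters is drastically more
conservative than the known-variance z test (about 20% rejection at
the 92% design point); surfacing that gap is intentional, since it is
the price of valid small-sample inference. `power_known_variance`
re-tests each replicate's log RR against the ensemble standard
deviation of those estimates with a normal quantile; it is the
simulation analogue of the closed form's known-variance z test and
the quantity that validates the GLS variance model (0.918 simulated
vs 0.917 closed at the reference design, 2,000 replicates). A
per-trial z rule with the model-based working covariance is also
available; it over-rejects because a uniform exchangeable working
correlation cannot represent the cluster-period variance component.

The closed form comes in two scales. The default models the
risk-difference test — the convention under which sample sizes for
proportions are planned, and the scale on which the 92% reference
value lives. `scale="log_rr"` instead propagates arm-specific
Bernoulli variances through the log transform and tests
log(p₁/p₀), the statistic the GEE analysis actually tests; it is the
apples-to-apples comparator for the simulation and agrees with the
known-variance simulated power within about 1.5 points across
configurations that vary m, CV, ρ and r. The two scales themselves
drift apart (up to ~4 points) at high ICC or mid-range power, where
the power curve is steepest — an inherent property of the two test
statistics, not an implementation artifact; at the reference design
they differ by under 2 points. Finally, the z-based closed form of
either scale describes the information in the design, not the
rejection rate of the conservative small-sample test a 4-cluster
trial should actually use.

## Synthetic data

The generator emulates the trial's structure, not any real hospital:
log-normal cluster-period sizes (mean 1,100 women per cluster-period
at trial scale, CV 0.60, scaled by each period's length); covariates
drawn to match the study population's headline mix (47% nulliparous,
45% of multiparous women with a previous cesarean, ~1.3% multiple
pregnancies, ~4.5% non-cephalic presentations, gestational age from a
12%-preterm mixture with mean ≈ 38.3 and SD ≈ 2.5 weeks), calibrated
so roughly 30% of women fall in Robson Group 1; group-specific
baseline cesarean probabilities for laboring women averaging to an
overall cesarean rate near 50% (a prelabor cesarean is a cesarean by
construction); an intervention relative risk (default 0.85) applied
to the laboring groups 1–4 and 10; secondary outcomes drawn at their
arm-specific crude proportions with the denominator logic enforced
structurally (augmentation/ARM only in spontaneous labor, episiotomy
and operative vaginal birth only in vaginal births, stillbirth and
neonatal death per baby, the experience survey only for Robson 1/3
women with a liveborn baby delivering in the last 15 days of a
period); durations log-normal matched to the published means and SDs.

Correlation is induced on a latent logistic scale with nested random
effects — a cluster effect and a cluster-period effect — while the
targets (ρ, r) are stated on the outcome scale to match the power
conventions. A Gauss–Hermite quadrature solver maps (ρ, r, baseline)
to the two latent SDs, and per-probability offsets keep every
marginal outcome probability exactly at its configured value despite
the nonlinear link. The induced correlations verify to ±0.001 by
direct latent simulation and to ±0.005 on generated cohorts.

What passing tests on this generator do **not** show: real hospitals
have secular trends, seasonal case-mix shifts, correlated covariates
(parity with age, previous cesarean with presentation),
outcome-dependent recording quality, and exposure contamination near
crossover — none of which are modeled. Parameter-recovery results
here establish the estimators' correctness under the assumed
data-generating process, not robustness to those violations.

## Problem sizes used in the validation suite

Simulation-based checks run at reduced cluster-period sizes chosen to
make Monte-Carlo error small relative to the assertion bands: log-RR
recovery and CI-coverage studies use 500 replicates of 4-cluster
trials at 60 women per cluster-period; ICC recovery uses 200
replicates at 100–150 women; the power-agreement checks use 2,000
replicates at the configuration's own size (including the full
m = 300 reference design). Each band in the tests states the
Monte-Carlo reasoning in place.

## Known limitations

- Cross-sectional wedges only: no closed cohorts, no incomplete
  wedges, no continuous-time correlation decay.
- Exchangeable and independence working correlations only; other
  small-sample corrections (Kauermann–Carroll, Fay–Graubard) are not
  implemented.
- The ICC point estimate inherits the small-sample downward bias
  described above; with four clusters, treat it as a lower-leaning
  estimate.
- No multiplicity adjustment anywhere, matching the trial's analysis
  plan.
- The generator draws covariates independently given parity; it is a
  structural emulator, not a population model.
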