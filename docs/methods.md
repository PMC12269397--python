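# Methods

## Scientific setting

`protonrbe` analyses quantal radiation-tolerance experiments of the kind
used to measure the relative biological effectiveness (RBE) of protons in
late-responding normal tissue — prototypically the rat cervical spinal
cord irradiated at several depths of a spread-out Bragg peak (SOBP), with
the binary endpoint "paresis grade 2 within 300 days". Groups of ~5
animals receive graded total doses; the probability of the endpoint as a
function of dose is fitted per irradiation position (each position
carrying a dose-averaged LET value), and RBE quantities are derived as
isoeffective-dose ratios against a photon reference.

## Dose-response models

The per-schedule model is the two-parameter logistic in total dose D,

    logit P(D) = b0 + b1·D,        ED50 = −b0/b1,

and the joint model across fractionation schedules is the generalized
logistic whose linear predictor is linear in the LQ biologically
effective dose (BED),

    logit P(D, d) = b0 + b1·D + b2·D·d = b0 + b1·BED,
    BED = D·(1 + d/(α/β)),   BED50 = −b0/b1,   α/β = b1/b2,

with d the dose per fraction. A single global (b0, b1, b2) triplet is
shared by all schedules entering the joint fit. b1 > 0 is required for a
response increasing with dose; b2 is kept positive, when necessary by a
log-parametrised refit (the unconstrained optimum is retained on the fit
object for diagnostics, since a b2 compatible with zero means α/β is
effectively unidentified — the fit flags this rather than silently
reporting a huge ratio).

## Actuarial preprocessing and effective sample sizes

Animals lost before the follow-up horizon (here: sporadic exclusions for
intercurrent disease) carry partial information. Each dose group's
response rate is estimated actuarially as the complement of the
Kaplan-Meier survival of the endpoint at the horizon (lifelines
implementation), with Greenwood's variance. The rate/variance pair is
then converted to *effective* counts

    n_eff = p(1−p)/Var(p)   (capped at the number treated),
    r_eff = n_eff·p,

which enter the binomial log-likelihood as real-valued weights. With
complete follow-up this reduces exactly to the observed counts. The
p(1−p)/Var construction is the natural reading of "effective sample
sizes matching actuarial rates and their variances"; crude rates are
available as a configuration switch (`method="crude"`), and are used
automatically for per-group summary input where censoring information no
longer exists. Excluded animals are treated as censored at their last
observation by default (`excluded="censor"`); dropping them entirely is
the alternative policy.

## Fitting, separation, and covariance

The weighted-binomial negative log-likelihood is minimised by BFGS with
the analytic gradient, from a logit-linear weighted-least-squares start
plus two perturbed restarts (guarding against flat likelihoods); the
gradient-norm convergence criterion is relative to the total effective
count. The covariance is the inverse observed information at the
optimum. Complete separation (a perfect 0/1 fit, log-likelihood → 0, or
a numerically singular information) is detected and the fit is repeated
with a Firth-type Jeffreys-prior penalty, clearly flagged — unflagged
infinite slopes are never returned.

ED50, BED50 and α/β standard errors use the delta method with the full
parameter covariance (the b0–b1 correlation is strong and matters). 90%
confidence limits for all ratios use Fieller's theorem; when
g = z²·Var(den)/den² ≥ 1 the interval is unbounded and is returned as
such (`bounded=False`), never truncated. The confidence level defaults
to 0.90 throughout.

## RBE estimators

* RBE (per schedule) = ED50_photon / ED50_proton.
* RBE_max = BED50_photon / BED50_proton: the d → 0 limit of the RBE,
  since BED removes the fractionation dependence.
* Relative RBE = ED50_plateau / ED50_position: the photon reference
  cancels, roughly halving the SE.
* RBE at a fraction dose d (isoeffect extrapolation): solve the real
  fraction number n delivering the proton BED50 at d, then the photon
  fraction dose delivering the photon BED50 in the same n fractions; the
  RBE is the photon/proton fraction-dose ratio. The stated d is the
  *proton* fraction dose — this convention reproduces the published
  extrapolated values and is therefore fixed. Fraction numbers are never
  rounded (1.8 Gy/fraction implies n ≈ 50).
* The SE of the extrapolated RBE is linearly interpolated in d between
  the SE of RBE_max (at d = 0) and the SE of the measured 6-fraction RBE.

Photon and proton estimates come from different experiments (historical
photon reference) and are treated as independent; every ratio function
accepts a correlation parameter for sensitivity analysis, defaulting
to 0. This independence assumption also applies to the plateau-relative
ratios, whose numerator and denominator come from the same proton
experiment series; any common-mode component would reduce the true SE
below the reported one.

## Phenomenological RBE models

CRB (Carabe-Fernandez 2012), WDB (Wedenberg 2013) and MNM (McNamara
2015) express RBE_max and RBE_min (asymptotic RBE at zero and infinite
dose per fraction) as linear functions of LET_d with an (α/β)_x
dependence, combined to RBE(d) by

    RBE(d) = [√((α/β)_x² + 4d(α/β)_x·RBE_max + 4d²·RBE_min²) − (α/β)_x] / (2d),

the RBE_min-squared form printed in those references, implemented in a
rationalised form that is exact at d = 0. Coefficients are transcribed
into `data/rbe_models.yaml` with per-model citations and pinned by
checksum in the tests; swapping the file changes predictions without
code changes. The reference α/β_x defaults to 2 Gy (typical late CNS
value). Models are evaluated at the dose per fraction given by the
measured ED50 divided by the fraction number (for single fractions the
two readings coincide; the per-fraction reading is adopted and
configurable by passing a different dose). Model ranking uses the mean
(accuracy) and SD (uniformity) of signed deviations predicted − measured,
by region: plateau (LET_d < 2 keV/µm) vs SOBP. Mechanistic
(LEM/mMKM/UNIVERSE-class) and patient-derived predictors require
external engines; they plug in through `register_model` but are not
shipped.

## Synthetic cohorts

The generator emulates the experimental design: the published dose grids
(5 animals per level, 130 treated + 5 controls in the default design),
Bernoulli responses from the generalized logistic truth, log-normal
latency times for responders (median 150 d, log-SD 0.35, truncated at
the 300-day horizon by inverse-CDF conditioning), and exclusions as
independent uniform-time censoring at rate 0.05. The latency
distribution is a modelling choice — only its existence and the
censoring mechanism matter for exercising the actuarial machinery; no
dose-latency dependence is simulated, and the LET labels are design
metadata, not physics. Truths are parametrised as (BED50, α/β,
slope-per-BED-Gy); `TruthParams.from_ed50` converts a schedule-level
ED50 and total-dose slope (default 0.75 Gy⁻¹, spanning ~5→95% response
across the width of the published grids). Each animal owns a
counter-based RNG keyed by (seed, position, schedule, dose, animal), so
cohorts are byte-reproducible and adding groups never perturbs existing
animals.

Passing recovery tests therefore show that the fitting machinery is
consistent and calibrated *under the assumed data-generating model*;
they cannot validate the model against features of real animal data
(overdispersion between cohorts, dose-dependent latency, non-logistic
response shapes).

## Numerical and validation choices

* Isoeffect quadratics use the rationalised positive root
  2c/(1 + √(1 + 4c/αβ)), stable for large α/β; the negative root is
  unphysical and never selected.
* Monte-Carlo checks of delta-method SEs use the normal-consistent
  quantile scale (half the central 68.27% spread) of 10⁵ ratio draws: a
  ratio of normals has no finite moments, so the raw sample SD is
  tail-inflated once the denominator CV exceeds ~10%. Fieller limits are
  checked against the 5%/95% MC quantiles, with which they coincide
  analytically for known variances.
* Recovery study sizes: 200 replicates for logistic ED50 bias (<1%) and
  90% Fieller coverage (85–95% band); 50 replicates for the joint
  1/2/6-fraction fit, where BED50 and α/β are required to come back
  within two empirical SDs of truth — these are skewed ratio estimators
  at 5 animals/group, with delta SEs that understate their sampling
  spread exactly as the strongly asymmetric published confidence limits
  suggest.
* The packaged summary arithmetic reproduces the published ratios at
  printed precision; two cases sit on rounding boundaries (a BED50 ratio
  of exactly 0.775; an extrapolated RBE evaluating to 1.428 against a
  printed 1.42) and are asserted with the corresponding half-ULP /
  input-rounding tolerances.

## Known limitations

* No incomplete-repair or dose-rate corrections in the LQ arithmetic.
* No probit/Weibull response alternatives and no time-to-event (Cox)
  modelling; latency is used only through the actuarial rate.
* LET uncertainties (range-uncertainty driven) are not modelled.
* The generalized fit assumes a single global (b0, b1, b2) across
  schedules; schedule-specific slopes are not supported.
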