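# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `distractnorm`.  Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Task and generator

The simulated task is two-alternative fine orientation discrimination: two
noisy gratings appear left and right of fixation, one is probed (the
target), and the observer reports CW vs CCW tilt of the target relative to
a decision boundary.  Tilts θ_T, θ_D are independent and uniform on
[−10°, +10°] about their boundaries; the probed side is fair.  Three
designs are generated:

* `exp1` — shared vertical boundary for both stimuli;
* `exp2` — orthogonal boundaries with a fixed ring→boundary map (left ring
  vertical, right ring horizontal), so decision-level similarity and raw
  orientation similarity dissociate;
* `exp3_cued` / `exp3_neutral` — vertical boundaries plus a spatial pre-cue
  that matches the probed side with probability 0.70 in cued blocks
  (attention indicator A = +1 valid / −1 invalid) or is uninformative in
  neutral blocks (A = 0).

Stimuli are Gabor patches (4° square patch, Gaussian envelope SD 1°) mixed
with Gaussian pixel noise smoothed by a Gaussian kernel of SD 0.083°;
signal and noise contrasts sum to 1.  The carrier spatial frequency is not
part of the public design description; the default is 2 cycles/degree —
a typical value for parafoveal gratings of this size — and the analysis
filter bank always reuses the stimulus value.  Rasterisation is 32
pixels/degree by default (16 in most tests, which quarters the pixel count
without changing any qualitative result); pixels are kept as raw real
values since every downstream computation operates on the raw field.  The
pre-smoothing noise amplitude is likewise unstated, so smoothed noise is
standardised to zero mean and unit pixel SD: the signal-contrast weight
then fully determines the signal-to-noise ratio.  Per-trial stimulus seeds
(driving carrier phase and the noise field) are recorded in the trial
table, making every image bit-reproducible from `(spec, seed)`.

Orientation convention: degrees, 0 = vertical, positive = clockwise,
matching the CW response category; boundary-relative tilt is raw
orientation minus boundary, wrapped to (−90°, 90°].

## Observers

The **parametric observer** implements the contextual-normalization
transducer

    y = (θ_T − ρ·μ) / (r + τ·σ),  μ = (θ_T + θ_D)/2,  σ = |θ_T − θ_D|,

with p(CW) = σ(y) and Bernoulli choices.  An optional lapse parameter mixes
in a uniform random choice (default 0); it exists because extreme
transducer values otherwise produce choice probabilities of exactly 0/1 and
unbounded log-likelihood terms in downstream fits.  With τ = ρ = 0 the
observer reduces exactly to a logistic psychometric function of θ_T with
slope 1/r.  Realistic cohort parameters, used for pipelines and sweeps,
are (r, τ, ρ) = (3, 0.15, 0.3): they put accuracy near the 75% titration
target and produce regression effects on the scale seen in human cohorts.

The **energy-template observer** reads the z-scored orientation-energy
profile of the rendered target, weights it by a fixed template over the 181
filter-bank bins, and responds through the same logistic rule.  It is
distracter-blind by construction, giving reverse correlation a recoverable
ground truth: its target kernel should reproduce the template and its
distracter kernel should be flat.  An optional consistency gain divides the
decision variable by r + τ·|score_T − score_D| (off by default).

The **staircase** is Kesten's accelerated stochastic approximation on noise
contrast: after each response the level moves by step·(resp − 0.75) — up on
correct, down on error — with step = c/(2 + m) and m the number of response
reversals.  The procedure's constants are free choices.  The initial step
is 0.6, close to the optimal Robbins–Monro gain implied by the ≈0.8
accuracy-per-unit-contrast slope of the bundled logistic observer near
threshold; runs last up to 6,000 trials (step floor 2·10⁻⁴).  A simulated
titration has no reason to stop at human-session lengths, and this length
makes the converged level precise enough that probe accuracy over 2,000
trials sits within 3 points of the 75% target for essentially all seeds.
`LogisticContrastObserver` exposes its analytic psychometric function, so
tests can root-find the true threshold independently of the staircase.

## Energy profiles and reverse correlation

The filter bank spans −45° … +45° in 0.5° steps (181 bins) at five carrier
phases {0.2, 0.6, 1.0, 1.4, 1.8}·π, rendered with the stimulus's own
spatial frequency and envelope and mean-removed.  A stimulus's response to
a filter is the regression slope cov(S, F)/var(F) of mean-removed images —
one reading of "variance in the filter explained by the covariance";
alternatives (correlation, cov²/var) differ only by positive per-filter
rescalings, which cancel in the per-bin z-scoring that precedes every
kernel regression, so the choice is consequence-free downstream.  Across
the five phases the response follows R(φₙ) = E·cos(φₙ − φ_max); because the
phases are uniform modulo 2π the least-squares (E, φ_max) has the
closed form of a discrete Fourier coefficient, a = (2/5)ΣRₙcosφₙ,
b = (2/5)ΣRₙsinφₙ, E = √(a²+b²), φ_max = atan2(b, a).  The equivalence of
this closed form with an iterative gradient-descent fit is asserted to
1e-6 in the test suite rather than assumed.  Degenerate all-zero responses
yield E = 0 with φ_max conventionally 0.

Decision kernels are 181 independent binomial probit regressions of choice
on per-bin z-scored energy (target alone, or target + distracter jointly in
the competitive variant).  Bins with (near-)separation are refit with a
small ridge penalty via Fisher scoring and flagged; SEs there come from the
penalized information matrix.  Because adjacent bins are strongly
correlated, per-bin significance is not treated as a multiple-comparison
family; the SVD route exists precisely to avoid that problem.

The SVD of the stacked (targets + distracters) profile matrix is
*uncentred*: the decomposition is of raw energy, so the (symmetric) mean
profile appears as the dominant first component instead of being removed.
Scores are projections onto unit-norm components (the U·Σ convention); any
fixed rescaling is absorbed by regression coefficients.  The
tilt-informative component is selected automatically among the components
that cumulatively reach 95% variance, as the one whose scores correlate
most with sign(θ); it is sign-aligned so CW stimuli score positive.  On
default-generator ensembles this is the second component and it is
antisymmetric about the boundary.  The exact variance fractions depend on
the (unreported) carrier spatial frequency: at 2 cpd and 16 px/deg the top
four components carry ≈93% of the variance, with ≈95% reached at six.

## Choice regressions, stepwise selection, CV and BMS

Design columns are exact algebraic functions of the trial table; the
consistency regressor is θ_T·|θ_T − θ_D|.  Reported coefficient tables
rescale consistency-type terms by ×10 so a unit step of the reported
predictor is comparable with the main effects; fitting always uses raw
columns.  GLMs are maximum-likelihood binomial fits (statsmodels), logit
link for the choice regressions and probit for kernels, with a
ridge-penalized fallback on separation (flagged).

Stepwise selection screens seven candidate predictors — θ_T, θ_D, |θ_D|,
congruency, θ_T·θ_D, θ_T·|θ_D|, θ_T·|θ_T−θ_D| — by greedy knock-in
(deviance χ² p < 0.05) then knock-out (p > 0.10), iterated to a fixpoint;
the thresholds are the defaults of the standard stepwise-GLM tooling.  At
the nominal 5% entry level, roughly one spurious inclusion per four
pure-noise runs is expected with seven candidates; tests treat that as the
algorithm's calibrated behaviour rather than a defect.

Cross-validated log-likelihoods use stratified k-fold CV (k = 10 by
default), stratifying on choice, deterministic under the supplied seed;
single-class training folds trigger a logged refold.  Held-out
probabilities are clipped at 1e-12.

Random-effects Bayesian model selection follows the standard variational
Dirichlet scheme (prior α₀ = 1): responsibilities
u_nk ∝ exp(lme_nk + ψ(α_k) − ψ(Σα)) and α_k = α₀ + Σu_nk iterated to
convergence, with exceedance probabilities from 10⁵ seeded Dirichlet
Monte-Carlo draws.  Evidence ranking is invariant to per-subject constant
shifts, which the tests assert.

## Normalization-model fitting

Fitting minimizes the single-trial Bernoulli negative log-likelihood
(probabilities clipped at 1e-9) with L-BFGS-B from n seeded restarts
(default 10).  Parameters are transformed to keep the problem well-posed:
r = exp(lr) enforces positivity, and τ = (10⁻³ − r_min)/σ_max + exp(u)
keeps the denominator above 10⁻³ over the attainable range of σ (the
observed maximum, at least 20°).  ρ is unconstrained.  The attention
variant has exactly five parameters — r per cue condition, shared τ and ρ —
encoding the hypothesis that spatial attention rescales target sensitivity
without touching contextual normalization.  The reduced variant (τ = ρ = 0)
is a one-parameter logistic psychometric function; its likelihood matches a
plain logistic GLM on θ_T numerically, which the tests check.

**Recovery-experiment design.**  Parameter-recovery simulations use
(r, τ, ρ) = (1.2, 0.2, 0.5) at 24 subjects × 900 trials.  This point was
chosen by a Fisher-information design calculation before running any
recovery test: the Cramér–Rao bound on the 900-trial design implies median
relative MLE errors of about 15%/13%/9% for (r, τ, ρ) there, whereas at the
realistic cohort point (3, 0.15, 0.3) the same bound implies ≈17%/33%/29% —
no estimator can recover τ or ρ to 20% from 900 trials at that point, so a
recovery experiment run there would measure the information content of the
design, not the correctness of the fitter.  The attention-ordering
recovery uses r = (1.5, 3.0, 6.0) for valid/neutral/invalid by the same
separation logic (twofold gaps, neutral at the realistic baseline), while
the attention *signature* cohort — significant attention×target interaction
with null attention×distracter terms — uses human-scale values
(r = 2.5/3.0/3.6, τ = 0.15, ρ = 0.1), chosen to match the magnitude of the
published group-level distracter effect and its null cue interactions.

Simulated cohorts destined for group summaries pass through the exclusion
rule: subjects below 55% accuracy on either probe side are dropped,
guarding against one-side-only strategies.

## Problem sizes

Test and acceptance runs use: 16 px/deg rasters and 4,000-trial ensembles
for image-level analyses; 24 × 900-trial subjects for recovery and model
selection; 10⁵-trial designs for (τ, ρ) sweep signatures; 2·10⁴/5·10⁴
trials for regression and stepwise recovery.  These sizes were chosen so
each check has comfortable statistical power while the full suite completes
in about a minute of CPU.

## What the synthetic data do and do not show

The generator reproduces the *structure* of the experiments — designs, cue
statistics, stimulus rendering, titrated difficulty — with observers whose
ground truth is known.  Passing tests therefore demonstrate that the
analysis chain is internally correct (it recovers what generated the data)
and that the normalization mechanism produces the documented qualitative
signatures (β₃ < 0 growing with τ, β₂ tracking −ρ, flat distracter kernel
for a distracter-blind observer, attention moving only target gain when
only r varies by condition).  They do not show that human observers obey
the model: real data bring sequential dependencies, lapses, learning,
response biases, eye-movement artefacts and display nonlinearities, none of
which are simulated.  Response times are deliberately out of scope — the
transducer is a static account of choice probabilities only.

## Known limitations

* Per-bin kernel SEs are model-based; under strong misspecification they
  can be mildly mis-calibrated (the SVD-score regression is the intended
  inferential route).
* The stepwise procedure inherits the usual selection-inference caveats;
  retained-set p-values are not corrected for the search.
* The uncentred-SVD variance fractions, and hence the identity of the
  tilt component, depend on the assumed carrier spatial frequency.
* Group summaries are fixed-effects per subject plus t-tests; no
  hierarchical pooling is implemented.
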