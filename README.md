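# distractnorm

How do task-irrelevant *distracters* shape fine perceptual decisions about a
*target*?  `distractnorm` is a simulation and analysis toolkit for
two-stimulus orientation-discrimination psychophysics: an observer judges
whether a noisy target grating is tilted clockwise (CW) or counterclockwise
(CCW) of a decision boundary while an equally noisy, irrelevant distracter
grating sits in the opposite hemifield.  The package generates the full
synthetic experiment — trial designs, rendered noisy-Gabor stimuli,
simulated observers — and implements the analysis chain that distinguishes
two accounts of distraction:

* **independent** — target and distracter each push the decision variable
  with their own weight;
* **interactive** — the distracter mostly *modulates* the target's
  influence, which grows with target–distracter similarity (a
  "consistency bias").

It is aimed at researchers in perceptual decision-making who want a tested,
reproducible reference implementation of these analyses, or a simulation
harness for power analysis and parameter-recovery studies.

## The models

With θ_T and θ_D the boundary-relative tilts of target and distracter
(degrees, CW positive, uniform on ±10°), choices are Bernoulli with
p(CW) = σ(y).  The central regression is

    y = β₀ + β₁·θ_T + β₂·θ_D + β₃·(θ_T·|θ_T − θ_D|)

where β₃ < 0 is the signature of the consistency bias, and the
attention-cued variant adds interactions with the cue indicator
A ∈ {−1 invalid, 0 neutral, +1 valid}.  The process-level account is a
three-parameter contextual-normalization transducer

    y = (θ_T − ρ·μ) / (r + τ·σ),   μ = (θ_T + θ_D)/2,   σ = |θ_T − θ_D|

in which ρ shifts the psychometric function (positive ρ → repulsion from
the distracter), τ flattens its slope as the context becomes more variable
(producing β₃ < 0), and r sets baseline sensitivity; the attention variant
frees r per cue condition while sharing τ and ρ.

Around these sit the supporting analyses: oriented Gabor filter-bank energy
profiles (181 orientation bins × 5 phases with a closed-form cosine phase
fit), per-bin probit *decision kernels* for target and distracter, an
uncentred SVD of energy profiles with a tilt-informative component score
regression, forward/backward stepwise predictor selection, stratified
cross-validated likelihoods, random-effects Bayesian model selection
(exceedance probabilities), and a Kesten accelerated-stochastic-
approximation staircase that titrates noise contrast to 75% accuracy.

## Worked example

Simulate one subject (900 trials) from the normalization observer and run
the two core analyses:

```python
import distractnorm as dn
from distractnorm import normmodel

trials = dn.generate_trials("exp1", 900, rng=1)
observer = dn.ObserverParams(r=3.0, tau=0.15, rho=0.3)
sim = dn.simulate_parametric_observer(trials, observer, rng=2)
print("accuracy:", round(sim["correct"].mean(), 3))

fit = dn.fit_choice_glm(sim)                      # consistency regression
for name, (b, se) in zip(fit.params.index, zip(fit.params, fit.bse)):
    print(f"{name:>12s}  {b:+.4f}  (SE {se:.4f})")

nf = normmodel.fit(sim, n_restarts=10, seed=0)    # transducer fit
print("normalization fit:",
      {k: round(v, 3) for k, v in nf.params.items()}, "nll", round(nf.nll, 1))
```

prints

```
accuracy: 0.728
   intercept  -0.0433  (SE 0.0777)
     theta_T  +0.2544  (SE 0.0344)
     theta_D  -0.0491  (SE 0.0193)
 consistency  -0.0059  (SE 0.0039)
normalization fit: {'r': 3.045, 'tau': 0.11, 'rho': 0.365} nll 495.6
```

The observer discriminates the target well above chance (β₁ > 0), is
repelled by the distracter (β₂ < 0, from ρ > 0) and shows the consistency
bias (β₃ < 0, from τ > 0); the transducer fit recovers the generating
parameters (3.0, 0.15, 0.3) up to single-subject sampling error.  At the
scale of a cohort the same machinery supports parameter-recovery studies,
(τ, ρ) sweeps and cross-validated Bayesian model comparison — see
`distractnorm.normmodel.sweep_pattern` and
`distractnorm.normmodel.compare_models`.

A command-line interface mirrors the library:

```bash
distractnorm generate --design exp1 --n 900 --seed 1 --out run/
echo '{"r": 3.0, "tau": 0.15, "rho": 0.3}' > run/observer.json
distractnorm simulate --observer-config run/observer.json \
    --trials run/trials.csv --seed 2 --out run/sim.csv
distractnorm regress --trials run/sim.csv --out run/fit.json
distractnorm pipeline --config config.yaml
```

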