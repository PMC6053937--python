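# alarmnet

Analysis of heterospecific alarm-call communication in multi-species
communities: who listens to whose alarm calls, and why?

Savannah herbivores (and many other animals) eavesdrop on other species'
alarm calls. The value of a heterospecific informant depends on measurable
properties of the signaller–receiver relationship, and `alarmnet`
implements the quantitative framework for testing them:

* **Information-content indices.** With predators `x`, receiver `i`,
  caller `j`: vulnerability weights ε(i, x) ∈ [0, 1] (from Jacobs
  selectivity indices, ε = (D + 1)/2), alarm propensities I(x, j)
  estimated from predator-model presentations, call profiles C(x, j)
  (per-caller rate-normalised distribution of calls across predators),
  **caller consistency** L(i, j) = Σₓ I(x, j) ε(i, x) aₓ / Σₓ ε(i, x) aₓ
  (penalises false negatives; 1 = perfect informant), and **call
  reliability** V(i, j) = Σₓ C(x, j) ε(i, x) (penalises false positives).
  Body-size ratios use the Lovich–Gibbons transform as a predator-overlap
  proxy.
* **Acoustic similarity** between species' alarm calls:
  S = 1 − ‖c̄ₐ − c̄ᵦ‖/√7 on seven max-standardised call features.
* **Behavioural response coding** from playback event logs: binary
  response in a 10-s window, latency, time to resumed foraging (censoring
  aware), head-up and scratch counts.
* **Mixed-model hypothesis suite**: logistic regression of alarm
  occurrence on vulnerability; binomial-logit, log-linear and
  negative-binomial mixed models of playback responses with a per-receiver
  random intercept; all-subsets AICc model selection under marginality
  constraints. Binomial/NB random-intercept models are fitted by
  Gauss–Hermite-quadrature maximum likelihood (agrees with lme4/glmmTMB
  to ~3 decimals).
* **Directed communication network**: caller → receiver edges where the
  response probability clears a cut-off (default 0.72), with
  GraphML/edge-list export.
* **Synthetic communities**: a generator reproducing the study design
  (12 herbivores, 5 predators, 648 balanced predator-model trials,
  ~2,450 balanced playbacks) with configurable true effect sizes, so the
  entire pipeline is testable end-to-end without field data.

## Worked example

```python
import alarmnet as an

cfg = an.generate_community(seed=1)                 # 12 species, 5 predators
trials = an.simulate_predator_trials(cfg, 9, seed=2)  # 648 trials
I, n = an.estimate_alarm_propensity(trials)
L = an.caller_consistency(I, cfg.epsilon, cfg.predator_abundances)

idx = an.true_indices(cfg)
pb = an.simulate_playbacks(cfg, idx, n_per_pair=17, seed=5)   # 2448 trials
fits = an.fit_response_models(pb, idx, cfg.body_masses)
print(fits["responded"].coefficients.loc["consistency"].round(3))
```

prints (community seed 1):

```
estimate     1.726
se           0.214
statistic    8.065
p            0.000
```

— the fitted caller-consistency coefficient of the binomial mixed model,
recovering the community's true value of 1.74 on the logit scale (with its
standard error, Wald z and p-value): receivers in this synthetic community
respond more to callers that dependably flag their predators. The
`examples/` scripts walk through each capability (indices, acoustic
similarity, model suite, network) and print annotated output; a thin CLI
(`alarmnet simulate|indices|acoustics|code-responses|fit|network|run-all`)
wraps the same functions, and `alarmnet run-all` writes every artefact
(CSV matrices, model coefficient tables, GraphML network) plus a
reproducibility manifest.

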