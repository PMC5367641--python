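# speedprior

Bayesian individual-differences modelling of perceived speed.

Two classic motion illusions make stimuli look slower than they are: a
pursued stimulus appears slower than a fixated one (the Aubert-Fleischl
phenomenon), and a low-contrast stimulus appears slower than a
high-contrast one. Under a Bayesian account both arise from combining
noisy sensory evidence with a slow-speed prior that peaks at zero: as the
evidence gets less reliable, the percept is pulled toward rest. Who shows
the stronger illusion then depends on *two* individual traits — how noisy a
person's sensory evidence is, and how broad their prior is. `speedprior`
implements a one-parameter cohort model in which the variance of the
slow-speed prior scales linearly with an autism-spectrum-quotient trait
score, together with everything needed to test that model end to end on
simulated cohorts.

For an observer with trait score $Q$, fixation/high-contrast
discrimination threshold $\Delta_A$ and pursuit/low-contrast threshold
$\Delta_B$, the predicted size of the illusion (the perceived-speed ratio)
is

$$\frac{V_A}{V_B} \;=\; \frac{kQ + \Delta_A^2/2}{kQ + \Delta_B^2/2},$$

where $kQ$ is the prior variance and $\Delta^2/2$ is the likelihood
variance implied by a 2AFC threshold under signal detection theory. A
single $k \ge 0$ is fitted per cohort by least squares and compared, by
RMSE and mean absolute deviation, against two reduced one-parameter
models: traits alone ($V_A/V_B = kQ$) and thresholds alone
($V_A/V_B = k\,\Delta_A^2/\Delta_B^2$).

The package provides:

- **design** — method-of-constant-stimuli session designs for both
  paradigms (three trial types: AA, BB discrimination and AB
  cross-condition comparison) and seeded trial-list generation;
- **observer** — generative Bayesian observers (percept = posterior mean
  of a noisy measurement under the zero-mean prior) producing full 2AFC
  sessions, plus simulated 1000-Hz eye traces with jitter, blinks and
  saccades;
- **psychometrics** — maximum-likelihood cumulative-Gaussian (probit)
  fitting, PSE/threshold extraction, effect ratios, and the cohort
  exclusion rules;
- **oculomotor** — eye speed from Gaussian-smoothed position derivatives,
  saccade/blink masking, pursuit gain and sample-loss metrics;
- **bayes_model** — the cohort model, the two reduced models, and the
  RMSE/MAD comparison;
- **stats** — t-tests, Pearson correlations, and an exact flat-prior Bayes
  factor for correlations ($\mathrm{BF}_{01}$ with a uniform prior on
  $\rho$);
- **pipeline / CLI** — seeded end-to-end runs and parameter-recovery
  suites (`speedprior run-all`, `speedprior recovery`, ...).

## Worked example

Simulate a 31-observer pursuit-experiment cohort, run the whole chain
(sessions → psychometric fits → eye metrics → exclusions → model fits →
statistics) and compare the three models:

```python
from speedprior.pipeline import RunConfig, run_synthetic_study

result = run_synthetic_study(RunConfig(experiment="af", seed=1))
print(result.comparison.to_string(index=False))
```

```
        model        k     rmse      mad  winner
        BAYES 0.161405 0.215554 0.153218    True
   PRIOR_ONLY 0.037284 0.265462 0.214167   False
EVIDENCE_ONLY 0.961414 0.429928 0.368490   False
```

The full Bayes model fits the simulated cohort best — its RMSE (0.216) and
MAD (0.153) are below both reduced models' — and the fitted scaling factor
`k` estimates how many (deg/s)² of prior variance each trait point adds.
The accompanying statistics report shows the expected group-level effects
and the model's independence assumption:

```
mean V_A/V_B = 0.654
ratio vs 1: t(30) = -9.37, p = 2.1e-10
pursuit vs fixation thresholds: t(30) = 7.36
trait vs fixation threshold: r = -0.01, BF01 = 4.47
```

Pursued stimuli appear slower (mean ratio well below 1), pursuit
thresholds exceed fixation thresholds, and trait scores are uncorrelated
with thresholds (Bayes factor favouring the null), exactly the structure
the generative model builds in.

The same run is available from the shell:

```bash
speedprior run-all --experiment af --seed 1 --outdir runs/af_demo
```

which writes the cohort ground truth, per-observer trial tables and eye
traces, the fitted summaries and exclusions, model fits, the comparison
table, the statistics report, and a manifest.

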