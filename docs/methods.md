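# Methods

## The observer model

Each simulated observer estimates the speed $V$ of a moving stimulus by
combining a noisy internal measurement $m \sim \mathcal N(V, \sigma_l^2)$
with a zero-mean Gaussian slow-speed prior of variance $\sigma_p^2$. The
percept is the posterior mean

$$\hat V = w\,m, \qquad w = \frac{\sigma_p^2}{\sigma_p^2 + \sigma_l^2},$$

so percepts are unbiased measurements shrunk toward rest by an amount that
grows as the evidence degrades. Three structural assumptions define the
cohort model: (a) likelihood noise is constant over the narrow speed range
a session probes, so a single cumulative Gaussian describes each
psychometric function; (b) the two stimulus conditions of an experiment
(fixation vs pursuit, or high vs low contrast) share one prior, since the
prior encodes beliefs about object motion, not viewing conditions; and
(c) the prior variance is linear in the observer's autism-spectrum
quotient, $\sigma_p^2 = kQ$, with one scaling factor $k$ shared by the
whole cohort. Assumption (c) is the hypothesis the package exists to test;
(a) and (b) are standard in the motion literature.

**Decision rule.** On each 2AFC trial the observer draws an independent
percept per interval and reports the interval with the larger posterior
mean. No lapse or guess parameters are modelled, matching the plain
cumulative-Gaussian analysis downstream. Exact percept ties — possible
only in the degenerate case $\sigma_p^2 = 0$, where every percept is 0 —
are resolved by a fair coin so that a vanishing-prior cohort remains
simulable. The prior is not truncated at zero: percepts inherit the sign
of $m$, but with $V \ge 0$ negative percepts are rare and only relative
magnitudes enter the decision.

**The threshold mapping.** Because both intervals of a within-condition
(AA or BB) trial share the same shrinkage weight, the decision variable is
Gaussian with SD $\sqrt 2\,w\sigma_l$, and the weight cancels from the
choice probabilities: the psychometric function in test speed has SD
$\Delta = \sqrt 2\,\sigma_l$ regardless of the prior. Fitted thresholds
therefore estimate the likelihood variance as $\sigma_l^2 = \Delta^2/2$,
which is what enters the cohort equation

$$\frac{V_A}{V_B} = \frac{kQ + \Delta_A^2/2}{kQ + \Delta_B^2/2}.$$

For cross-condition (AB) trials the weights differ and the 50% point sits
at $V_{\text{test}} = V_{\text{std}}\,w_{\text{std}}/w_{\text{test}}$; the
implied effect ratio equals the cohort equation's prediction by
construction, a self-consistency the test suite checks both symbolically
and by simulation.

## Session designs

The pursuit design uses a 8 deg/s standard, seven test speeds spaced
8/6 ≈ 1.33 deg/s apart (4–12 deg/s for discrimination trials, 0–8 deg/s
for the cross-condition trials), 10 repetitions per level, sequential
presentation with uniformly jittered 1.15–1.35 s stimulus durations —
210 trials per session. The contrast design uses a 2 deg/s high-contrast
standard, simultaneous presentation, and test speeds on [1, 4] deg/s at
10 repetitions per level. The number of contrast-design levels is
configurable; the default of 9 equally spaced levels yields the 270-trial
session the protocol describes (a 1 deg/s spacing would give 4 levels and
120 trials, which is inconsistent with that total). Durations and
directions are recorded per trial but play no role in the analysis;
directions are balanced only in expectation (pure uniform draws).

## Synthetic cohorts

Default cohorts draw 31 observers with integer trait scores from
$\mathcal N(15.6, 7.7^2)$ truncated to the instrument's 0–50 range —
normative population moments for the questionnaire. The remaining
generative settings are package choices intended to be realistic rather
than protocol-stated values, and are flagged as assumed in every run
manifest:

| parameter | default | units | rationale |
|---|---|---|---|
| `k_true` | 0.08 | (deg/s)²/trait unit | puts the prior variance (≈1.2 (deg/s)² at the mean trait) on the same scale as the likelihood variances, the regime where both influences matter |
| `sigma_lA_range` | (0.5, 1.0) | deg/s | Weber fractions of roughly 9–18% at the 8 deg/s standard ($\Delta_A = \sqrt2\,\sigma_{lA}$) |
| `sigma_lB_range` | (0.9, 1.8) | deg/s | pursued / low-contrast stimuli are noisier on average, producing the expected threshold ordering without forcing it per observer |

Trait scores and likelihood SDs are drawn independently, so the model's
independence assumption holds in the generator; the trait–threshold
correlations on simulated cohorts are null, and the statistics module's
flat-prior Bayes factors typically favour that null.

What the generator does *not* emulate: serial dependencies and lapses in
responding, speed-dependent (non-constant) sensory noise, asymmetric
likelihoods, inter-session drift, and any true coupling between traits and
sensitivity. Passing tests therefore show that the analysis machinery is
correct and well calibrated under the model's own assumptions — not that
those assumptions hold for real observers.

## Eye traces and oculomotor analysis

Simulated epochs integrate a constant velocity (gain × target speed,
horizontal) plus white Gaussian velocity jitter on both axes at 1000 Hz
for 1.25 s. Artifacts are deliberately schematic, since the analysis only
has to prove its masking logic: blinks are rectangular invalid runs of
100–200 ms during which the recorded position drops to zero, and saccades
are 30 ms triangular velocity pulses with 100–300 deg/s peaks.

Analysis smooths position with a Gaussian kernel specified by its
frequency-domain SD (default 16 Hz — the only reading under which Hz is a
coherent unit for a Gaussian filter; the equivalent temporal SD is
$1/(2\pi \cdot 16) \approx 9.95$ ms), then takes central differences;
speed is the Euclidean norm of the two velocity components. Invalid
samples propagate invalidity across the kernel's truncation radius (4
temporal SDs). Samples are masked when invalid or faster than the saccade
threshold (default 30 deg/s, velocity criterion only — no acceleration
test), with a ±10 ms guard window around every masked run. The first and
last 4 temporal SDs of each epoch are excluded from all statistics: that
is the kernel's truncation radius, so interior samples of a clean ramp are
exactly unaffected by boundary padding (with 3 SDs a small residual edge
bias would remain). Pursuit gain is the pooled mean masked speed across
pursuit epochs divided by the standard speed; the loss fraction is the
masked share of interior samples pooled over all epochs.

## Psychometric fitting

"Probit analysis" is implemented as binomial maximum likelihood with a
probit link — $p(x) = \Phi((x-\mu)/\sigma)$ fitted in $(\mu, \log\sigma)$
by L-BFGS-B with the analytic gradient, initialised from a linear
regression of probit-transformed proportions, with generic restarts and a
derivative-free polish on the rare failures — rather than classical
transformed-proportion least squares. Two independent oracles guard the
implementation in the tests: an exhaustive $(\mu, \sigma)$ likelihood grid
and statsmodels' binomial GLM with a probit link. The threshold is
reported as $\sigma$, equivalently the speed difference between the 84.1%
point and the PSE. Degenerate data never raise: all-identical responses,
or data so flat that $\sigma$ runs beyond 20× the tested range, yield a
fit flagged non-converged. Standard errors come from a finite-difference
observed-information matrix and are approximate.

## Exclusion rules

Observers are excluded by the first matching rule, in order: (1) flat
cross-condition psychometric function (non-converged AB fit); (2) mean
fixation eye speed > 2 deg/s; (3) pursuit gain < 0.6; (4) > 50% of eye
samples lost; (5) contrast experiment only, AB PSE more than 15 cohort SDs
above the cohort mean. Rule 5 computes the cohort moments *without* the
candidate (leave-one-out): with the candidate included, a single outlier
inflates the SD so much that no point can ever sit more than
$(n-1)/\sqrt n \approx 3.5$ SDs out at these cohort sizes, and a 15-SD
rule could never fire. Include-candidate moments remain available via
`ExclusionConfig(leave_one_out=False)`. Eye-based rules are mandatory for
the pursuit experiment and skipped when eye metrics are absent (contrast
experiment).

## Cohort model fitting and comparison

The full model's single parameter is constrained nonnegative (it scales a
variance) and fitted by minimising the unweighted squared error between
measured and predicted ratios: a log-spaced grid over
$k \in [10^{-6}, 10^2]$ (plus $k=0$) followed by bounded scalar refinement
of the best bracket, with the objective checked against a dense-grid
oracle in the tests. The reduced models have closed-form least-squares
solutions through the origin ($k = \sum x_i r_i / \sum x_i^2$ with
regressor $x_i = Q_i$ or $\Delta_{Ai}^2/\Delta_{Bi}^2$), cross-checked
against numeric minimisation. Models are ranked by RMSE with MAD reported
alongside (MAD ≤ RMSE always, by the power-mean inequality); no
information criteria are used, as all models have one parameter. Observers
with $Q = 0$ are retained — the model handles $kQ = 0$.

## Inferential statistics

t-tests and Pearson correlations are classical two-sided procedures (thin
wrappers over scipy with explicit zero-variance handling). The
correlation Bayes factor uses the exact sampling density of the Pearson
coefficient under bivariate normality (Hotelling's hypergeometric form)
and a uniform prior on $\rho \in (-1, 1)$:
$\mathrm{BF}_{01} = f(r \mid 0, n) \big/ \tfrac12\int_{-1}^{1} f(r \mid
\rho, n)\,d\rho$, with the marginal computed by adaptive quadrature
(relative tolerance $10^{-10}$). The tests verify the density normalises,
that quadrature matches a brute-force Riemann marginal to four significant
figures, and that the result coincides with an independent analytic
implementation of the same prior. No multiple-testing correction is
applied to the trait–threshold correlations, matching the analysis the
pipeline reproduces.

## Validation problem sizes

The package validates itself at sizes chosen to make Monte-Carlo error
small while keeping a full run on one CPU in minutes: scaling-factor
recovery uses 100 replicate cohorts of 31 observers with 100 repetitions
per level (10× the session's trial count), where the median relative error
of $\hat k$ must stay within 20%; model-comparison ordering uses 200
replicate cohorts at the same size, requiring the full model to win on
RMSE in at least 95%; pursuit-gain recovery uses 100 artifact-laden traces
with gains in [0.6, 1.1] and a 0.05 mean-absolute-error bound; test
calibration uses 10⁴ null replicates. At the session's own 10 repetitions
per level, threshold noise is substantial (≈20% per threshold) and the
full model's RMSE advantage over the reduced models, while still the rule,
holds in a smaller share of replicates; `scripts/acceptance.py` reports
that session-scale ordering fraction on every run.

## Known limitations

- The generator and model share the same structural assumptions, so model
  comparison on synthetic cohorts shows identifiability, not empirical
  adequacy for human data.
- The probit fit's standard errors are asymptotic and approximate; no
  bootstrap is provided.
- Eye-trace simulation omits pursuit onset latency, catch-up saccades and
  contrast-dependent oculomotor noise; the saccade detector is a plain
  velocity threshold.
- The flat-prior Bayes factor is specific to Pearson correlations under
  bivariate normality; no general Bayes-factor machinery is included.
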