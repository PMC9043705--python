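# Methods

## The problem

Repeatedly reaching in one direction biases subsequent reaches toward
that direction (use-dependent learning). The bias measured at a rarely
probed target can come from two different sources:

* a **planning bias** — the motor system keeps a default plan aimed at
  the frequently practiced direction, and reaches initiated before
  re-aiming is complete land between the probe and the practiced
  direction. This component is large, broadly distributed, and shrinks
  with preparation time;
* an **execution bias** — a small, stable rotation of well-planned
  reaches toward the practiced direction, attributed to retuning of the
  sensorimotor map. This component is a few degrees, tightly
  distributed, and insensitive to preparation time.

`udlbias` implements the analysis that separates the two — mixture
modelling of heading distributions, bootstrap peak-shift estimation,
and reaction-time-conditioned bias statistics — together with a
generative simulator that reproduces the statistical structure both
experimental designs are expected to produce, so the entire pipeline is
testable without any external data.

## The two-process generator

Every test-phase reach toward a target `d` degrees from the frequent
location (`d ∈ {0, 30, 60, 90}` after recoding) is assigned a latent
planned bias, in coordinates where the presented target is 0 and
positive points toward the frequent target:

    b(P) = max(d − ω · max(0, P − t₀), ε) + 𝒩(0, σ²),   d > 0
    b(P) = 𝒩(0, σ²),                                    d = 0

where `P` is preparation time (reaction time plus any imperative
delay). The interpretation: until `t₀` seconds have elapsed the default
plan (aimed at the frequent target, i.e. bias `d`) stands; thereafter
the plan is rotated toward the actual target at `ω` deg/s; re-aiming
stops at the execution shift `ε`, which never resolves. Reaches
therefore occupy three regimes — *default* (`P ≤ t₀`), *intermediate*
(linear in `P`), and *re-aimed* (`b ≈ ε`) — and the model reproduces
the three signatures the analysis targets with four interpretable
parameters: bimodal heading distributions at rare probes under
self-paced timing, a broad band of intermediate angles, and a negative
bias-vs-RT slope whose magnitude grows with `d`. Optionally a reach is
a *lapse* with probability `p_lapse`, drawn Uniform(−d−30, d+30).

Baseline-phase reaches precede any learning and carry motor noise only.

### Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `eps_exec` (ε) | 3.0 | deg | matches the ~3 deg peak shifts the analysis should recover |
| `omega` (ω) | 300 | deg/s | re-aims a 90 deg probe in ~0.3 s, putting the default/re-aimed split inside the self-paced RT range |
| `t0` (t₀) | 0.1 | s | plausible planning onset latency |
| `sigma_motor` (σ) | 4.0 | deg | heading noise at 40 ms post-onset |
| `rt_mu`, `rt_sigma` | log(0.25), 0.6 | log-s | shifted log-normal RT; median ≈ 0.32 s with ~15% of reaches fast enough (< 0.2 s) to stay near the default plan — chosen for qualitative realism of self-paced reaching, not fit to data |
| `rt_shift` | 0.07 | s | anticipation floor; no generated RT is flagged `too_fast` |
| `rt_cap` | 2.0 | s | truncates the log-normal tail so trajectories stay bounded; the clipped mass (~3·10⁻⁴) is below Monte-Carlo resolution |
| `delay` | 0.0 / 0.5 | s | target-to-imperative interval (self-paced vs delayed design); the delay is assumed fully usable for planning, so `P = RT + delay` |
| `move_time_range` | [0.25, 0.40] | s | uniform; stays within the 400 ms cap |
| `p_lapse` | 0.0 | — | see "Lapses" below |
| `start_jitter_sd` | 0.002 | cm | digitizer noise before onset; see "Numerical choices" |
| `freq_loc_sd` | 0.0 | deg | SD of frequent-location jitter (0 / 7.5 / 15 in the variable-location variant; only the generator option is provided, not its analyses) |

**Lapses.** A uniform lapse process is supported but defaults to off.
A contamination of even 1% uniform outliers in an otherwise Gaussian
sample of n ≈ 10³ drives any Gaussian-vs-two-Gaussian likelihood-ratio
test to reject with near certainty (the second component absorbs the
heavy tail), which would make the delayed design appear bimodal. Since
the delayed design's empirical signature is unimodality, and emulating
that signature is the generator's purpose, the default generator is
lapse-free; `p_lapse` (validated to [0, 0.05)) exists for robustness
studies of the analysis stack.

### Schedules

Self-paced (`exp1`): two 70-trial baseline blocks (10 per target; first
with cursor feedback, second without) then eight 90-trial test blocks —
10 initial frequent-target reaches, then 80 trials holding 66 frequent
reaches with feedback and 14 feedback-free probes (two per location,
including the frequent one), so each rare location receives 2/90 ≈ 2.2%
of block trials. Fourteen probes cannot be spaced exactly one-per-seven
within 80 trials, so probes are pseudorandomized by splitting the 80
trials into 14 near-equal consecutive slots with one probe placed
uniformly within each slot; counts per block and per location are
exact, and gaps between probes never exceed 12 trials.

Delayed (`exp2`): the same baselines then six 134-trial test blocks —
113 frequent-target reaches (reward-eligible in the reward group) and
21 feedback-free probes, three per location, interleaved the same way.
The frequent location is counterbalanced (60 vs 150 deg) and the seven
session targets always sit at 0, ±30, ±60, ±90 deg from it, wrapped to
[0, 360); with the frequent target at 60 deg this is the set
{0, 30, 60, 90, 120, 150, 330}.

### Rendering

Trajectories are sampled at 200 Hz, start circle at the origin. The
hand holds the start (plus jitter) until the latent RT, then follows a
straight ray at the planned heading with a minimum-jerk radial profile
reaching the 10 cm target ring at `rt + move_time`. Straight rays are a
deliberate simplification: mid-reach online corrections and curved
interception paths are out of scope, and the 40 ms heading window is
designed to precede them anyway.

## Kinematic reduction

1. **Onset / RT** — first sample whose tangential speed (central
   differences on the 200 Hz grid, no smoothing) exceeds 3 cm/s.
2. **Heading** — direction of the displacement from onset to 40 ms
   after onset (≈2.4 cm of travel), linearly interpolated between
   samples.
3. **Validity** — `too_fast` if RT < 70 ms (anticipation), `too_slow`
   if movement time > 400 ms; the boundaries themselves are valid.
   Invalid trials are excluded from all downstream analyses and logged.
4. **Baseline correction** — per participant × target, the mean angular
   deviation in the no-feedback baseline block is subtracted from every
   test-phase deviation at that target (removes idiosyncratic,
   non-use-dependent bias).
5. **Recoding** — the frequent target is reset to 0; probe distance is
   the absolute angular separation (collapsed over side, since the
   analysis averages across target direction); the sign is flipped so
   positive bias points toward the frequent target.

Angular arithmetic is linear on deviations after wrapping to
(−180°, 180°]; the deviations of interest are far from the wrap point.

## Distributional analysis

Heading biases pooled across participants within a probe distance are
modelled as a mixture of one or two Gaussians, fit by EM (vectorized
over batches of datasets, which is what makes bootstrap replication
cheap).

* **EM details** — k = 2 initialization: median split plus jittered
  restarts (10 by default); convergence at relative log-likelihood
  change < 10⁻⁸; variances floored at 0.25 deg², so all-identical data
  yield a degenerate-safe (flagged) fit; components unconstrained in
  variance. Because two identical components reproduce the single
  Gaussian exactly, the two-component likelihood is analytically
  bounded below by the one-component solution; if EM lands lower, the
  nested solution is substituted. The reported log-likelihood is
  re-evaluated at the reported parameters.
* **Modality test** — parametric bootstrap: simulate `n_boot` (default
  999) datasets from the one-component fit, refit both models on each,
  p = (1 + #{boot LRT ≥ observed LRT}) / (n_boot + 1). The tested LRT
  is computed under the *same* EM search protocol (3 restarts, relaxed
  tolerance 10⁻⁶, ≤150 iterations) on the observed data and on every
  replicate: a likelihood-ratio statistic compared against a null that
  was optimized less exhaustively than the observed value is
  anti-conservative, and this mattered in practice — pooled samples are
  really mixtures over ~10²  participant × target cells (baseline-
  estimation error shifts each cell by ~1.3 deg SD), and an
  asymmetrically optimized test flagged that benign heterogeneity as
  bimodality at n ≈ 10³. With the matched protocol the test's type-I
  rate is ~0.05 and delayed-design unimodality is retained.
* **Peak estimate** — the execution-bias readout is the mean of the
  mixture component nearest 0 (the probe location), under the model
  selected by the modality decision (or a forced k). Its CI is a
  nonparametric percentile bootstrap over trials, 10 000 resamples at
  the 95% level by default. Percentile rather than BCa, as only a
  generic bootstrap interval is called for.

## Bias-vs-RT statistics

* **Quintiles** — per participant × distance, valid probe trials sorted
  by RT and split into five near-equal bins (remainder to the fastest
  bins); per-bin mean RT and bias; group curves are unweighted means
  across participants with SEM = SD/√n.
* **Slopes** — default `two_stage`: per-participant OLS of bias on RT
  (deg/s), then a one-sample t-test of slopes against zero. The pooled
  alternative `pooled_mixed` is a random-intercept mixed model
  (statsmodels backend, residual degrees of freedom — the backend has
  no Satterthwaite approximation); the two agree in sign and within
  sampling error on balanced cohorts.
* **Normalization** — bias divided by probe distance, for comparing
  attenuation rates across distances.
* **Distance contrasts** — per-distance one-sample tests and the three
  paired contrasts (30v60, 60v90, 30v90), Bonferroni ×3, within-subject
  Cohen's d_z.
* **Reward comparison** — accuracy at the frequent target is the
  per-participant mean absolute (baseline-corrected) bias over all
  valid distance-0 trials, compared between groups by an
  independent-samples t-test with Cohen's d; probe biases enter a mixed
  ANOVA (group between, distance within; pingouin backend) for the
  reward main effect and reward × distance interaction. The ±5.7 deg
  criterion is a property of the simulated reward feedback, not of the
  analysis.

## Problem sizes and seeds

Acceptance-style runs use desk-scale cohorts: 10 participants for the
self-paced design (8 600 trials, 320 probe trials per nonzero
distance), 16 + 16 for the delayed design (30 208 trials, 1 152 per
distance); modality tests in replication loops use 199 bootstrap
replicates, peak CIs 4 000–10 000 resamples. All randomness flows from
explicit integer seeds through `numpy.random.Generator`; there is no
hidden global state, and identical configs reproduce `summary.json`
byte-for-byte.

## Numerical choices

* Pre-onset jitter is 0.002 cm so that central-difference speed noise
  (Rayleigh with scale ≈ 0.4 cm/s) cannot cross the 3 cm/s onset
  threshold even once across millions of pre-onset samples; larger
  jitter would create false onsets and contaminate headings.
* The 10 cm ring test in movement-time detection and dataset validation
  uses a 1 mm slack to survive 6-significant-digit CSV round-trips.
* Measured RT sits 15–30 ms after the latent movement start (the
  threshold crossing of the minimum-jerk speed profile plus grid
  quantization). The offset varies only weakly with movement time, so
  slopes and quintile curves are unaffected; tests that compare against
  latent RT account for the analytic crossing point.
* Quintile bins use a stable sort so ties in RT resolve
  deterministically.

## What the synthetic data do and do not show

The generator reproduces the *statistical structure* the analysis
dissociates: schedule composition, shifted-log-normal RTs, two-process
heading mixtures, a constant execution shift, baseline idiosyncrasies
(through estimation noise only), and reward-group differences injected
via motor noise. It does not emulate: online corrections or curved
paths, sequential/learning dynamics within and across blocks (biases
are stationary from the first test trial), reward-driven RT changes,
participant-level heterogeneity in ω, t₀ or ε, or the RT distribution
of any real cohort (`rt_mu`/`rt_sigma` are qualitative placeholders).
Passing tests therefore certify that the pipeline recovers known
structure of this form at these sample sizes — not that real data will
show the same effect sizes, and not that the analysis is robust to the
artifacts the generator omits. Real-data robustness work should start
at the isolated choice points: the speed estimator, the heading
interpolation, and the lapse rate.

## Known limitations

* Mixtures are limited to k ≤ 2 Gaussian components on the linear
  angle scale; wrapped (circular) models and k > 2 are out of scope.
* The parametric-bootstrap modality test treats the pooled sample as
  exchangeable; with few participants and strong cell heterogeneity
  its null is only approximate (see the protocol-matching note above).
* The pooled mixed model reports residual degrees of freedom.
* The Dryad adapter is a stub: mapping the deposited data onto the
  canonical schema requires the deposit's on-disk layout.
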