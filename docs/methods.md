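# Methods

## The affective-instability model

Mood is a two-dimensional positive diffusion: a depressive coordinate
`D_t` and a manic coordinate `M_t` with

    dD = a_d (b_d / D − D) dt + sqrt(2 a_d) (sqrt(1 − ρ²) dV + ρ dW)
    dM = a_m (b_m / M − M) dt + sqrt(2 a_m) dW,

`V`, `W` independent Wiener processes.  The drift vanishes only at
`(√b_d, √b_m)`, which is the single asymptotically stable point of the
noise-free flow; the `b/X` term diverges as `X → 0⁺` and keeps the
process strictly positive.  Interpretation of the seven parameters:

| parameter | units    | default | meaning |
|-----------|----------|---------|---------|
| `a_d`, `a_m` | 1/day | 0.002, 0.003 | speed of symptom fluctuation; higher ⇒ shorter episodes (rapid cycling) |
| `b_d`, `b_m` | —     | 5, 5    | symptom burden; higher ⇒ more time at high levels, longer episodes |
| `ρ`          | —     | 0       | correlation of the driving noises; 0 ⇒ independent symptoms, >0 ⇒ mixed states |
| `s_d`, `s_m` | score units | 1  | observation scale mapping latent mood to survey scores, `score ≈ s·X` |

The diffusion amplitude `sqrt(2a)` is deliberately tied to the drift
rate `a`: each coordinate marginal then has closed forms, and `a` has a
pure time-scale meaning — simulating `(c·a, b)` on times `t` is
pathwise identical to simulating `(a, b)` on times `c·t` (this is an
exact property of the Euler scheme with matched noise and is tested).
The manic equation's diffusion is `sqrt(2 a_m)`, keeping the two
coordinates in the same closed-form family.

### Closed forms

By Itô, `Y = X²` satisfies `dY = 2a(b + 1 − Y) dt + sqrt(8 a Y) dW` —
a square-root (CIR-type) diffusion with `κ = 2a`, `θ = b + 1`,
`σ² = 8a`.  Hence:

* stationary law of `Y`: Gamma(shape `(b+1)/2`, rate `1/2`), i.e.
  chi-squared with `b + 1` degrees of freedom; `X` is chi-distributed
  with `b + 1` df, mode exactly `√b`;
* transition law: with `c = 1 / (2(1 − e^{−2aΔt}))`, the variable
  `2 c Y_{t+Δt}` given `Y_t = y₀` is noncentral chi-squared with
  `b + 1` df and noncentrality `2 c y₀ e^{−2aΔt}`; densities in `X`
  carry the Jacobian `2x`.

These forms are validated in the test suite against numerical
Fokker–Planck integration, quadrature normalisation, the
Chapman–Kolmogorov identity, ergodic limits, and Monte-Carlo histogram
oracles of the exact transition sampler.

Two standard comparison models share the interface: the linear
mean-reverting Gaussian diffusion (Ornstein–Uhlenbeck; Gaussian
transitions) and the general square-root diffusion
(Cox–Ingersoll–Ross; noncentral chi-squared transitions).

### Simulation

Default scheme: Euler–Maruyama with step `dt = 0.1` day and a
reflecting floor (`|x|` then clip at `ε = 1e−4`), valid for any `ρ`.
An `exact_marginal` scheme samples the noncentral chi-squared
transition of each squared coordinate and is available only for
`ρ = 0`, where the coordinates are independent; the coupled transition
has no closed form.  Long-run checks: the Euler path's `X²`
distribution passes Kolmogorov–Smirnov comparison against the Gamma
stationary law at the 1% level in 20/20 seeded 3·10⁵-day runs (thinned
to 240 samples spaced 1250 days ≈ 7.5 mixing times, so the iid KS
reference is appropriate).

### Observation model and likelihood

Integer scores relate to latent mood by `score = round(s · X)`, clipped
to the instrument range.  For likelihood evaluation an observed score
is treated as the continuous value `score + 1/2` (half the score
resolution), which keeps a score of 0 strictly inside the positive
state space; for the affective model the value is then divided by `s`
with the log-Jacobian `−log s` per transition.  The likelihood is the
Markov product of transition densities over consecutive observed
pairs, conditional on the first observation; missing surveys simply
lengthen the time gap (the transition density is exact for any gap),
never interpolated.

Fitting maximises this likelihood over log-transformed positive
parameters (the Gaussian model's mean is unconstrained) by Nelder–Mead
from a moment/autocorrelation-based start plus seeded random restarts
(5 by default); ties are broken by likelihood, then by smaller
parameter norm.  Scale parameters are estimated jointly — they are
identifiable because `s` scales the level while `a` scales the
innovation, though the two are strongly anti-correlated at slow
sampling (see limits below).

### Identifiability limits found while validating

Two findings worth knowing before fitting real surveys:

* **Quantisation.** At `s = 2` the rounding noise (uniform over one
  score unit, sd ≈ 0.14 latent units) is comparable to the weekly
  latent innovation (sd ≈ 0.2), and a likelihood that ignores rounding
  overestimates `a` by roughly a factor of two.  The parameter-recovery
  experiment therefore uses continuous-valued observations to isolate
  estimator consistency from quantisation bias.  The goodness-of-fit
  bootstrap is unaffected: replicates are rounded and re-fitted through
  the same pipeline as the data, so the bias cancels in the p-value
  (verified by self-consistency calibration).
* **Information.** For weekly sampling at `a = 0.003`/day the average
  observed Fisher information over 2000 observations gives asymptotic
  relative standard errors of about 17% (`a`), 16% (`b`) and 8% (`s`)
  with corr(log a, log s) ≈ −0.98.  The probability that all three
  estimates land within 25% of the truth is therefore only ≈ 0.76 for
  any estimator based on this likelihood; the recovery experiment's
  observed success rate (≈ 0.7–0.8) sits at this information-theoretic
  ceiling, not at an optimisation failure (the optimiser attains a
  log-likelihood at or above the truth's on every replicate).

## Patient-level tests

* **One-dimensionality.** Kendall's tau-b (tie-corrected — integer
  surveys are tie-heavy) between concurrent depressive and manic
  scores; patients with constant scores have no defined rank
  correlation and are excluded from aggregation.  Mania risk is the
  fraction of concurrent surveys with ASRM ≥ 6 among those with
  PHQ9 ≥ 10 (depressed) and PHQ9 < 10 (not depressed); an empty
  denominator makes that side undefined.
* **Rhythmicity.** Thomson's multitaper harmonic F test with 7 Slepian
  tapers at time-bandwidth 4, on 30 frequencies equally spaced
  (inclusive) between 1/24 and 1/2 of the sampling frequency.  The
  taper eigencoefficients at each frequency are regressed on the taper
  DC responses; the F statistic has an F(2, 12) null.  The series mean
  is removed via the Slepian-taper mean estimate, and missing surveys
  are filled by linear interpolation first — this is the only test
  that interpolates, because the spectral machinery needs contiguous
  data.  Adaptive eigenspectrum weighting affects background spectrum
  estimates, not the line-component F statistic, so the standard
  unweighted form is used.  Null calibration (white noise) and
  injected-sinusoid detection are tested.
* **Multistability.** Hartigan's dip statistic on scores jittered by
  uniform(−1/2, 1/2) (symmetric de-rounding of the integer grid).  The
  dip is computed exactly by a convex/concave band construction
  (greatest convex minorant / least concave majorant of the count
  ECDF per candidate mode position, with an explicit junction
  condition), cross-validated in the tests against a linear-programming
  oracle written directly from the definition.  P-values come from a
  seeded 2000-replicate Monte-Carlo null of uniform samples at the
  observed n, cached per series length.  Note the dip has limited
  power at bimonthly n ≈ 25 unless modes are well separated and both
  well occupied.
* **Model adequacy.** Two parametric-bootstrap goodness-of-fit tests.
  The density test compares the empirical distribution of observed
  scores with the fitted stationary CDF by Kolmogorov–Smirnov
  distance; the transition test applies the KS distance to the
  one-step probability integral transforms under the fitted transition
  law (intended for the weekly cadence).  The p-value is the fraction
  of B model-simulated datasets (same cadence and length, each rounded
  to scores and re-fitted — a full parametric bootstrap, B = 200 by
  default, 2 refit restarts) whose discrepancy is at least the
  observed one.  The KS distance is a deliberately simple, isolated
  discrepancy interface; any statistic with the same calling
  convention can be substituted.

## Population aggregation

The mean of the N patient p-values is compared with the distribution
of the mean of N independent uniforms: exact Irwin–Hall (scipy) for
N ≤ 50, Gaussian (mean 1/2, variance 1/(12N)) above — the two agree to
< 10⁻³ at the switchover.  For the 30-frequency rhythmicity test, the
per-patient minimum p-value is averaged and compared with the mean of
N independent Beta(1, 30) minima by seeded Monte Carlo (10⁵ replicates
by default); Monte Carlo was chosen over convolving Beta(1, 30)
because it is simple with controlled error.  Significance is α = 0.05
throughout.  Undefined patient-level results are excluded before
aggregation.

## Parametric study

Long-run protocol: simulate 1100 years from `(D, M) = (0.1, 0.1)`,
discard a 100-year warm-up, store daily samples (Euler `dt = 0.1` day,
decimated).  States by threshold 3: euthymia (both coordinates at or
below), mania / depression (one strictly above), mixed (both above);
values exactly at the threshold count as below so the partition of a
continuous path is exhaustive.  Mood episodes are maximal runs of
mania/depression/mixed lasting ≥ 7 days; shorter runs are absorbed
into the surrounding euthymic period, and euthymic episodes are the
periods between mood episodes.  Episodes truncated by the window
boundary keep their observed duration and carry a censored flag.
Scaled-down (50-year, two-seed) sweeps confirm the qualitative
parameter effects: percent time depressed rises with `b_d` (≈ 13% →
37% between `b_d` = 5 and 8) and the mean depressive episode shortens
with `a_d` (≈ 39 → 25 days between 0.002 and 0.008/day).

## Synthetic cohorts

The generator emulates the geometry of a longitudinal bipolar survey
study: a bimonthly self-report arm (ASRM 0–20 / PHQ9 0–27, 61-day
spacing, 25 surveys ≈ 4.2 years, missingness 0.55% / 3.5%) and a
weekly interviewer-rated arm (YMRS 0–60 / SIGHD 0–52, 52 surveys,
missingness 9.7% / 9.2%).  Missingness is Bernoulli per survey,
independent of the score (missing completely at random) — a stated
simplification.  Four regimes generate paired series:

* *affective* — the model above, sampled exactly at survey times when
  `ρ = 0`; scales are calibrated so the median latent maps to the
  instrument mid-range, which spreads scores over ≥ 5 distinct values
  for ≈ all patients.  This calibration favours test resolution over
  clinical realism of threshold exceedance rates (the synthetic cohort
  is "severely symptomatic" by construction).
* *rhythmic* — sinusoid (default 1 cycle/year, in-band for the
  bimonthly grid) with per-patient random phase, antiphase between
  axes, Gaussian noise sd 2.
* *multistable* — a semi-Markov switcher (euthymia/depression/mania,
  exponential dwells of 150/150/120 days, euthymia branching equally)
  with Gaussian emissions (sd 1) around well-separated state means.
  This is a test fixture embodying the multistable hypothesis, not a
  claim about bipolar disorder; dwells and separations are calibrated
  for test power at the bimonthly n, not for realism.
* *one_dimensional* — a single latent mean-reverting Gaussian process;
  its positive part drives mania scores and its negative part
  depression scores, enforcing the strict two-poles structure (mean
  Kendall tau ≈ −0.65, mania-while-depressed risk ≈ 0).

What passing regime checks do and do not show: they demonstrate that
each test has power against the data-generating structure it targets
and retains the null on affective data at the chosen cohort sizes;
they say nothing about effect sizes in real cohorts, where missingness
may be informative, parameters drift with treatment, and instruments
are reported with bias.

## Problem sizes and numerical choices

Validation experiments run at desk scale, chosen once: stationary-law
check 20 seeds × 3·10⁵ days thinned to 240 samples; parameter recovery
50 replicates × 2000 weekly observations; type-I calibration 10⁴
uniform-null trials at N ∈ {5, 15, 178}; regime power 20 patients
(15 for the goodness-of-fit retention run, B = 40); monotonicity
sweeps 50 years × 2 seeds.  Ties at the classification threshold count
as below; dip Monte-Carlo nulls use a fixed internal seed so the null
table is shared across patients; all cohort generation, fitting,
bootstraps and Monte-Carlo nulls are reproducible from explicit seeds.

## Known limitations

* The model is Markovian with time-constant parameters; treatment
  effects, covariates and non-Markov memory are out of scope.
* The transition likelihood ignores score quantisation (see the
  identifiability notes); a bin-integrated or state-space likelihood
  would be the next step for slowly sampled, coarsely scaled surveys.
* The dip test's Monte-Carlo null uses the uniform reference, the
  standard conservative choice; at n ≈ 25 its power against moderate
  bimodality is limited.
* `ρ`-coupled exact transition sampling is unavailable (no closed
  form); nonzero-`ρ` simulation falls back to Euler.
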