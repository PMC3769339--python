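# Methods

## Model

A two-alternative forced-choice (2AFC) trial offers concentrations *x* ≥ *a*
(% w/w). The probability of visiting the higher-concentration option is

Ψ(x, a) = 0.5 + (0.5 − π_l/2) · F(i_β(x, a); m, s)

with near-miss relative intensity i_β(x, a) = scale · (x − a) / ((x+a)/2)^β.

F is a Weibull sigmoid re-parameterised from the conventional
(shape k, scale λ) pair into biologically interpretable coordinates:
threshold m with F(m) = 0.5 and slope s = dF/di at m. The inverse map is
k = 2·m·s/ln 2, λ = m·(ln 2)^(−1/k). Consequences used throughout:

- Ψ(a, a) = 0.5 exactly (chance at zero intensity);
- Ψ at i = m equals 0.75 − π_l/4, i.e. 75% when π_l = 0 (midpoint between
  chance and the upper asymptote 1 − π_l/2);
- the *observable* slope of Ψ at threshold is (0.5 − π_l/2)·s; `s` itself
  is the slope of the unscaled sigmoid. Both readings are recoverable from
  the stored (m, s, lapse) tuple — this convention is stated because
  "slope at the threshold" is ambiguous between the two.

β > 1 makes intensity non-monotone in x at fixed a, peaking at
x* = a(β+1)/(β−1) (set d i_β/dx = 0); predicted performance therefore
declines for test concentrations beyond x*, which is a genuine prediction
of a strong magnitude effect, not a numerical artifact.

### Intensity scale convention

`scale` multiplies the intensity and is mathematically redundant with
(m, s): fitted curves, residuals, AICs, F tests and the β estimate are all
invariant to it. It exists because raising the mean-concentration term to β
moves raw intensities by factors of `standard^(β−1)` (about 20^(β−1) around
a 20 % standard), which would make thresholds from different β regimes
incommensurable and would start optimisers far from sensible regions.
`intensity.natural_scale(beta, standard)` returns the power of ten nearest
to standard^(β−1); this reproduces the conventional pairings β = 2 ↔ 10 and
β = 0.3 ↔ 0.1 used for the species parameter presets, and gives 100 for
β = 2.4. Parameters quoted anywhere in the package (presets, simulation
truths) are on the scaled axis of their accompanying `scale`.

## Data reduction

Each condition is presented in sessions consisting of a forced alternation
phase (100 visits, 50 per feeder, enforced by the apparatus) followed by a
free choice phase. Only choice-phase visits count; at most
`max_choice_visits` (default 100) per presentation, so each animal is
scored after the same amount of forced sampling; counts are pooled over the
(side-swapped) presentations of a condition. Sessions with fewer visits
contribute what they have and the shortfall is recorded in the record's
metadata rather than assumed away — `n_total` is always the actual count.

The per-animal table is split into a LOW set (test ≤ standard) and a HIGH
set (test ≥ standard); the equal-concentration condition belongs to both.
At x = a the "higher" feeder is the test feeder by convention and the
recorded proportion measures side/position bias only; it enters fits as the
zero-intensity anchor. A compatibility flag (`zero_substitute=1e-6`)
reproduces historical scripts that could not accept an exact zero intensity
and entered 10⁻⁶ instead; the substitution is numerically immaterial here
(implemented as diff = 1e-6·mean, i.e. relative intensity exactly 10⁻⁶ at
β = 1).

Outlier exclusion is never automatic: exclusions are an explicit config
list of (individual, test concentration) pairs.

Pooling across individuals sums counts per condition (a visit-weighted
mean). Pooling heterogeneous observers attenuates the fitted slope but
leaves threshold and lapse essentially unbiased; the test suite
demonstrates this with per-individual threshold jitter.

## Least-squares estimation

`fit_nls` minimises Σ (observed proportion − Ψ)² over
(log m, log s, lapse, β), mirroring the classical nls-on-proportions
workflow these data were designed for (a binomial-likelihood point fit is
available via `likelihood="binomial"` but is not used in the standard
workflow). Numerical choices:

- trust-region reflective least squares; m, s fitted on the log scale
  (positivity without active bounds), lapse box-bounded to [0, 0.5] and
  β to [−2, 8] (covering all exponent regimes reported for nectarivores);
  a lapse estimate at the 0.5 bound is flagged in the result message,
  not silently clipped.
- starts: m = median observed scaled intensity, s = 2/m, lapse = 0.1,
  β = 1 (or its fixed value), plus 5 deterministically seeded jittered
  restarts; lowest RSS wins, exact ties broken toward β nearest 1. The
  free-β fit additionally starts from the β = 1 solution so its RSS can
  never exceed the nested model's (nesting holds by construction, up to
  1e-8 tolerance).
- the 95 % CI for β comes from the asymptotic covariance
  σ̂²(JᵀJ)⁻¹ at the solution (central-difference Jacobian,
  σ̂² = RSS/(n − p)) with a t critical value at n − p df.
- degenerate designs (all conditions at equal relative intensity) and
  underdetermined inputs (fewer than p + 1 points) raise instead of
  returning garbage.

AIC uses the full Gaussian log-likelihood form
AIC = n·ln(2π·RSS/n) + n + 2(p + 1), counting the error variance as a
parameter, so two nested fits with equal RSS differ by exactly 2 and
ΔAIC = AIC(Weber) − AIC(near-miss) is convention-free; absolute AICs are
not comparable across conventions and are reported for within-run use
only. RSS = 0 returns a large negative sentinel rather than −∞. The nested
test statistic is F = (RSS_r − RSS_f)/(RSS_f/(n − p_f)) with
(1, n − p_f) df.

## Bayesian estimation

`fit_bayes` samples (m, s, π_l) at fixed β under a binomial likelihood with
the informative priors

- lapse ~ Beta(2, 10) (mean 1/6 — animal lapse rates exceed the 0–0.1
  typical of human observers),
- threshold ~ Normal(1, 0.5) on the scaled intensity axis,
- slope ~ log-normal, by default with location 2 and scale 1 on ln s. The
  alternative reading of "(mean 2, sd 1)" as raw moments of s is selectable
  (`slope_prior_on="raw"`, moment-matched internally); the log-scale
  reading is the cited algorithm's convention and the default.

Sampling uses the emcee affine-invariant ensemble sampler (10 walkers,
1000 burn-in steps, 5000 retained draws by default; any correct MCMC would
do — the historical analyses used a Hamiltonian sampler whose leapfrog
settings are not binding). Walkers start in a tight multiplicative ball
(5 % jitter) around the least-squares point estimate; prior-dispersed
starts were observed to strand single walkers in low-probability regions
for thousands of steps, biasing the posterior mean. With no data the
sampler is started from prior draws and returns the prior, which the tests
use to validate the prior specification. Results are exactly reproducible
given the seed; acceptance rate outside [0.1, 0.9] is surfaced as a
warning and per-parameter effective sample sizes (integrated
autocorrelation time) are reported.

Point estimates are posterior means. On well-identified simulated data
posterior means and NLS estimates agree within 2 posterior SDs (tested).

## Unit conversions

Aqueous-sucrose density at 20 °C is a cubic polynomial in mass fraction
fitted to the CRC Handbook concentrative-properties table over 0–60 % w/w
(max fit error 2.8×10⁻⁵ g/cm³); it also serves mixed sucrose/hexose
solutions, whose densities differ by <0.5 % at equal total mass fraction.
Molarity → mass fraction solves c = 100·M·342.30/ρ(c) by fixed point
(ρ varies slowly, so the map contracts rapidly); the inverse is direct, and
the round trip is accurate to well under 0.05 % w/w over 0.1–2.0 M.

Sucrose equivalents use a mass-based equivalence: one gram of hexose counts
as one gram of sucrose, so mmol/L equivalents = total sugar (g/L) / 342.30.
This reproduces the customary reference values 632 mmol/L for a 20 % w/w
and 1796 mmol/L for a 50 % w/w mixed-sugar solution exactly; for 8 % w/w it
gives 241 mmol/L where 226 is sometimes quoted (~6 % apart). No equivalence
convention we examined (mass-based, molar with 2 hexose ≡ 1 sucrose,
energy-based) reproduces all three quoted values simultaneously; the
mass-based convention is documented here and its deviation stated rather
than hidden.

## Simulator

`synthetic_data` generates the 15-condition, 20 %-standard design (two
presentation orders, sides swapped between the two presentations of each
condition, 100 analysed choice visits per presentation → n = 200 per
condition) at two levels:

- performance level: per-condition binomial draws with p = Ψ — exactly the
  generative assumption the fitting inverts;
- visit level: alternation phase emitted as 50/50 forced visits, then
  choice visits in which a lapse occurs with probability π_l and goes to
  the left feeder with probability 0.5 + position_bias, while non-lapse
  visits follow a Bernoulli draw at the lapse-free probability
  0.5 + 0.5·F(i). Because sides are counterbalanced across presentations,
  side-directed lapses average to the performance-level model at the
  condition level, so the two layers agree in expectation while allowing
  experiments on position-biased lapsing.

All randomness descends from the single scenario seed through named
`numpy.random.Generator` streams; there is no global state. Optional
per-individual heterogeneity jitters ln m, ln s and logit lapse.

What the simulator does *not* emulate: learning/warm-up drift at the start
of the choice phase (curves are asymptotic from the first visit), visit
timing structure, nectar depletion or energetics, and any stimulus
dependence of the lapse rate. Passing recovery tests therefore demonstrate
estimator correctness under the model's own assumptions, not robustness to
these real-data features.

### Calibration scenarios

The recovery harness (`recovery_experiment`) runs
simulate → fit (both β modes) → nested comparison over seeded replicates
and aggregates bias, RMSE, β CI coverage and model-preference counts at
the ΔAIC > 2 evidence rule. The standard calibration scenarios use
m = 0.25, s = 3, lapse = 0.1 at the 15-condition design with n = 200 per
condition, with β = 1 (scale 1) and β = 2.4 (scale 100 via
`natural_scale`); 100 replicates run in well under a minute each. Under
these conditions the β CI covers the truth in ≥ 90 % of replicates with
median |β̂ − β| < 0.5, and AIC selects the generating model in well over
70 % of replicates on both sides.

Species parameter presets (G. soricina, G. commissarisi, Trochilidae
hummingbirds, B. impatiens, A. m. ligustica) are shipped as configuration
for simulation and for preference-curve extrapolation; regenerating
noise-free pooled tables from them and refitting recovers each preset β to
< 0.05.

## Cross-species workflow

Thresholds and slopes are only comparable between groups fitted at the same
β. The reanalysis therefore fits β freely per species and then applies a
rounding rule over a candidate set (default {0.3, 1, 1.4, 2}): if one
candidate lies inside every group's 95 % CI it is assigned to all (choosing,
among several such candidates, the one minimising summed distance to the
point estimates); otherwise each group receives the in-CI candidate nearest
its estimate. A CI containing multiple candidates is reported as ambiguous
rather than silently resolved; a CI containing none leaves the group
unassigned and flagged. Parameters are then refit at the assigned β with
the species' display scale, and preference curves
(P(choose alternative) against a fixed standard, crossing 0.5 at the
standard with asymptotes π_l/2 and 1 − π_l/2) are extrapolated for chosen
standards.

## Known limitations

- Least squares on proportions ignores the binomial variance structure;
  it is kept as the primary route for comparability with the classical
  workflow, with the binomial fit available opt-in.
- The asymptotic β CI can be optimistic on small designs (15 points); the
  calibration scenario shows ~90–95 % empirical coverage, but bootstrap or
  profile CIs are out of scope.
- The Bayesian route fixes β; joint (m, s, π_l, β) posteriors are not
  implemented.
- The density polynomial is specific to 20 °C; no temperature correction.
- The visit-level simulator's lapse-side mechanism is a modelling tool;
  whether real animals' lapses are side-correlated is an open empirical
  question.
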