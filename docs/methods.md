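# Methods

This note documents the modelling and numerical choices behind `magest`:
what the simulator and synthetic observer assume, which parameters matter
and why their defaults are what they are, and what passing tests do and do
not establish about real data.

## Experimental designs

Two factorial designs are enumerated exactly. Experiment 1 crosses three
target dimensions (duration D, numerosity N, surface S) with five
non-target conditions — control (both non-targets at their session means)
plus each other dimension at its minimal or maximal value — under linear
evidence accumulation: 3 × 5 × 6 levels × 12 repetitions = 1080 trials.
"Minimal"/"maximal" for a non-target mean its extreme design levels, 0.75×
and 1.25× the session mean, the same factors that bound the tested range.
Experiment 2 manipulates the accumulation regime (fast–slow vs slow–fast)
and tests duration only in its control condition (144 trials) while N and S
are probed against duration min/mean/max (432 trials each), for 1008 total.

Schedules are seeded permutations. Experiment 2 trials are dealt into ten
blocks alternating between the regimes (five blocks each; 504 trials per
regime do not divide evenly by five, so block sizes differ by at most one).
Which regime leads is a flag, the hook for between-participant
counterbalancing. Experiment 1 trials are fully interleaved across target
dimensions; nothing in the design requires blocking by target.

## Stimulus simulation

A stimulus is an *event table*: per dot, an onset (quantized to the 85 Hz
frame grid, 11.765 ms), a lifetime (whole frames within 35–294 ms,
truncated so the dot extinguishes before the trial ends), a diameter, a
luminance drawn uniformly from the six-step grey set, and a position.

**Onset regimes.** Linear delivery emits 2–7 dots at a time over 9–13
evenly spaced iterations (iteration count drawn uniformly among feasible
values; group sizes by rejection-sampled multinomial). The nonlinear
regimes draw a segment fraction uniformly from the stated ±10 % band
(fast–slow: 65–85 % of dots before 0.25·D; slow–fast: 15–35 % before
0.75·D) and place onsets uniformly within each segment — the sources
specify only segment totals, so uniform within-segment pacing is the
maximum-entropy choice. Group-size limits are applied only to the linear
regime; the nonlinear regimes place dots singly.

**Surface.** The surface dimension is the cumulative area covered by all
dots in a trial (mm²). Degrees convert to screen millimetres through the
viewing distance (60 cm): mm = 10 · dist · tan(deg·π/180). Per-dot
diameters start uniform over the permitted range and are rescaled
multiplicatively with clipping until the summed circle areas hit the trial's
surface target within 0.5 % (at most 100 iterations; typically < 10).

*Geometry accommodation.* Corner design cells that pair the smallest
surface level with the largest dot count (e.g. S = 357 mm² with N = 40)
demand a mean dot area below the floor implied by the 0.35° minimum
diameter (10.55 mm² at 60 cm). The stated parameter set is internally
inconsistent there under any plausible conversion, so for exactly those
trials the minimum dot diameter is relaxed (with 10 % slack) and the
surface target is honoured exactly. `partition_surface` called directly
keeps its strict feasibility contract and rejects such requests.

**Placement.** Dots lie wholly inside the outer disk (drawn per trial from
12.3–15.2° unless pinned) and wholly outside the 3.3° fixation-protection
disk. "No overlap" is enforced between *simultaneously visible* dots
(display intervals intersect), since cumulative surface over a trial can
exceed the annulus area. Placement is rejection sampling: 10 000 attempts
per dot, then a whole-trial restart, at most 20 restarts before an error
naming the trial size and budget.

Large-scale simulations (cohort sessions in the tests and pipeline) build
event tables without spatial placement: the observer consumes only onsets
and dot areas, and skipping the placement step cuts per-trial cost roughly
in half. Placement and its invariants are exercised at full fidelity in the
stimulus tests. Positions are NaN in unplaced tables, never silently wrong.

## The synthetic observer

Each estimate is the posterior mean of a Gaussian prior and a noisy
measurement. Noise is *scalar*: the measurement standard deviation is
ν · m (coefficient of variation ν), consistent with Weber-like
discrimination. Priors and noise operate on linear magnitude because the
slider analysis is linear; a log-space option exists but is off by default.

Defaults (per dimension): prior mean = the session mean (this is what
produces regression toward the mean of the stimulus set), prior sd =
0.25 × mean, ν = 0.15, lapse rate 0.02 (so the goodness-of-fit machinery
sees occasional misfits), primacy half-life 0.5·D. With these values the
central-tendency slope is ≈ 0.6–0.75 and Weber Ratios ≈ 0.1–0.15, ordinary
values for adult observers on such tasks.

**Rate–duration coupling.** Accumulated dimensions (N, S) are estimated as
r̂ · D̂. The rate r̂ is the primacy-weighted mean accumulation rate of the
event table: evidence at time t gets weight exp(−t·ln2/(h·D)) with
half-life fraction h, normalized by the integral of the weight over the
trial, so a temporally uniform stream is read out unbiased. D̂ is the
perceived duration — itself shrunk toward the duration prior. Consequences:

* D̂ > D on short trials and D̂ < D on long trials, so N and S are over-
  and under-estimated respectively while D judgments are unaffected by N, S
  or the regime (there is no reverse pathway in the model);
* front-loaded delivery raises r̂ and back-loaded delivery lowers it, so
  fast–slow inflates N and S estimates relative to slow–fast.

This coupling is one admissible formalization of a verbal account
(rate read-out biased toward early evidence, multiplied by perceived time);
it is interpretive, not uniquely determined, and the package treats it as a
generator of qualitative signatures rather than a quantitative fit to any
participant.

**Cohorts.** Individual differences enter through a log-normal scaling of
ν per dimension, driven by a latent factor with loadings 0.9 (duration),
0.9 (numerosity) and 0.55 (surface). Sharing the factor strongly between D
and N and weakly with S makes the central-tendency slopes of D and N
correlate more tightly across participants than either does with S — the
generative structure probed by the correlation analyses. Cohort size
defaults to 17.

## Psychometric fitting

The logistic is fitted by explicit Bernoulli maximum likelihood
(Nelder–Mead on (μ, log s), moment-based start, objective trace recorded)
rather than through a GLM wrapper, because the analysis chain needs honest
convergence flags: one-sided data, perfect separation (s below 1 % of the
level span) and flat likelihoods (s above 50 spans) are flagged unusable
and propagate into participant exclusion instead of producing spurious
numbers. A statsmodels Binomial GLM serves as an independent cross-check in
the tests. Goodness of fit is the residual deviance against the saturated
model on the six level bins, df = levels − 2.

The midpoint tie in binning (slider exactly at 50) counts as '−': the
cursor starts at the midpoint, so an untouched slider should not register a
'+'. Exclusion implements the stated rules verbatim — top-level '+'
proportion below 0.5, or control-condition goodness-of-fit p > 0.05 — with
a switch for the conventional direction (drop p < 0.05). The pipeline uses
the conventional direction: for a correctly specified observer the deviance
p-value is approximately uniform, and the verbatim rule would discard most
of any well-behaved cohort.

Outlier handling replaces values beyond two standard deviations of their
condition's mean (computed once, on the original values) by the group mean,
in a single pass. The pass is deliberately not iterated; on pathological
inputs a second pass could find new outliers, which is why the operation
reports its replacement count.

**Calibration.** Task difficulty is matched across dimensions by an
iterative loop: each iteration probes every dimension with 5 trials × 6
levels, fits PSE and WR, and accepts when all PSEs lie within 95–105 % of
their means, the largest/smallest WR ratio is below 3 and every WR is below
0.25. Otherwise the numerosity and surface means are multiplicatively
rescaled by PSE/mean (duration stays fixed at 800 ms). Starting values are
N̄ = 30 and S̄ = 432 mm²; at most 50 iterations, after which the loop fails
loudly with its last state. An additional "WR spread" criterion mentioned
in some protocols is not interpretable as printed and is exposed only as an
optional callable hook, disabled by default.

## Statistics

Fisher z-tests for correlation differences use the independent-samples
formula (this is the variant that reproduces the published contrasts for
slope correlations at n = 17); Steiger's dependent-correlations test is
provided separately for users who want the overlap-corrected version.
First-order partial correlations use the closed form and are verified
against the regression-residual definition to 1e-12. The cell-wise
correlation matrix adjusts for the number of unique off-diagonal pairs
(Bonferroni) and reports the implied |r| threshold at the given n.

## What the synthetic data do and do not show

The generator reproduces the *structure* of real data — central tendency,
unidirectional duration-on-N/S interference, regime sensitivity of N and S,
correlated individual differences — with known ground truth, which is what
makes it useful for validating the analysis chain (parameter recovery,
directional tests, exclusion logic). It deliberately omits: sequential
(trial-history) effects, reaction times and decision dynamics, learning or
drift across blocks, lapses structured by fatigue, and any retinotopic or
luminance-dependent perceptual nonuniformity. Passing tests therefore
certify the pipeline's correctness and the model's qualitative adequacy,
not quantitative parameter values for human observers.

## Problem sizes and determinism

Cohort-level checks run 17 observers × the full 1080/1008-trial designs;
regime signatures use 500 stimuli per regime; recovery suites use 100
replicates at 12 trials per level. These sizes keep every Monte-Carlo
standard error comfortably below the tolerances they are tested against.
All randomness flows through numpy `SeedSequence`s derived from named
seeds; identical configurations produce byte-identical tables.
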