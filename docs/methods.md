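# Methods

## Statistical model

All estimation rests on the one-way random-effects ANOVA model for a
two-scan test-retest design:

    y_ij = mu + s_i + e_ij,  i = 1..n subjects, j = 1, 2 scans,
    s_i ~ N(0, sigma_s^2),   e_ij ~ N(0, sigma_e^2),  independent.

The package standardises on exactly two scans per subject (k = 2).  The
absolute percent test-retest index is defined only for a pair of scans
and does not generalise cleanly to k > 2, so rather than support a
partial k > 2 mode for some indices and not others, tables with any
other replication count are rejected at construction.  A subject missing
a retest carries no within-subject information; strict readers reject
such rows, lenient readers drop the subject and log a count.  Values are
never imputed.

## Estimation

Parameters are estimated by the method of moments from the ANOVA mean
squares, which is closed-form at k = 2:

    msw = sum_ij (y_ij - ybar_i)^2 / n          (df = n)
    msb = 2 sum_i (ybar_i - ybar)^2 / (n - 1)   (df = n - 1)
    sigma_e^2 = msw,    sigma_s^2 = max(0, (msb - msw)/2).

This is the classical estimator underlying the one-way ICC; it requires
no iteration and its sampling distribution is fully characterised by the
chi-square laws of the mean squares, which is what the interval formulas
and the sample-size search exploit.  REML/ML mixed-model fitting is a
non-goal: for balanced two-replicate data the moment estimator is the
standard choice and keeps every downstream formula exact.  When
msb < msw the between-subject variance estimate is clamped at zero and
the fit carries a `truncated` flag, so boundary cases are detectable
rather than silent; the ICC is then 0 by construction.

All sums are accumulated in double precision with numpy; the test suite
pins agreement with an explicit double-loop sums-of-squares oracle at
1e-10 relative error.

## Agreement indices

* **WSCV** = sigma_e / mu.  Requires mu > 0 (a coefficient of variation
  is meaningless otherwise).
* **ICC** = sigma_s^2 / (sigma_s^2 + sigma_e^2), in [0, 1] thanks to the
  clamping.  Undefined (an error) when both components are zero.
* **RC** = sqrt(2) z_{1-alpha/2} sigma_e, the smallest detectable
  difference: the (1-alpha) bound for a single subject's test-retest
  difference, whose SD is sqrt(2) sigma_e.  Default alpha = 0.05, where
  the multiplier of sigma_e is 2.77 (1.96 quantile).
* **PTRT** (absolute) = mean_i |2 (y_i2 - y_i1)/(y_i2 + y_i1)|; the
  signed variant keeps the sign.  Reported as a fraction; percent
  rendering (x100) happens only in the human-readable report, which
  avoids silent unit bugs.  Requires positive pair sums.

The estimators obey RC / mu = sqrt(2) z WSCV exactly; `evaluate`
asserts the identity on every call.  A first-order Taylor expansion of
the pair-normalised difference shows PTRT behaves like a log-transform
of the data, i.e. each difference is scaled locally by its own pair
mean.  Under the clean model with small relative noise the expected
PTRT is (2/sqrt(pi)) * WSCV ≈ 1.1284 WSCV (mean absolute value of a
centred normal); this closed form is verified by Monte Carlo.  The
expansion also explains PTRT's outlier insensitivity, quantified by the
sensitivity experiment below.

## Confidence intervals

* **ICC**: the exact one-way F interval.  With F0 = msb/msw on
  (n - 1, n) df, the bounds are (F0/Fu - 1)/(F0/Fu + 1) and
  (F0 Fv - 1)/(F0 Fv + 1) with Fu = F_{1-a/2; n-1, n},
  Fv = F_{1-a/2; n, n-1}, clamped to [0, 1].
* **WSCV and RC**: a chi-square interval on sigma_e^2 (df = n),
  transformed to the SD scale and, for WSCV, divided by the point
  estimate of mu.  The interval is exact for sigma_e and a plug-in
  approximation for the ratio: mu's uncertainty, O(1/sqrt(2n)) relative,
  is ignored.  Simulation in the test suite confirms ~95% coverage for
  the sigma_e component at n = 50.

## Sample-size planning

The precision planner returns the smallest n >= 3 whose *expected* CI
width is at most the target, found by doubling then bisection (the
width functions are decreasing in n; the result is verified against
exhaustive linear search in the tests).  Expected widths plug the
population value of the pivotal statistic into the same interval
formulas used for data: F0 = (1 + rho)/(1 - rho) — the population
MSB/MSW ratio at k = 2 — for the ICC, and msw = sigma_e^2 for WSCV/RC.
PTRT is deliberately excluded: it estimates no model parameter, so
there is no interval to invert.  An unreachable target (width floor
above the target at the search cap) raises an error reporting the
limiting width.

The pre-post planner uses the normal-approximation paired formula
n = ceil((z_{1-a/2} + z_power)^2 * 2 sigma_e^2 / delta^2), the paired
difference variance 2 sigma_e^2 following from the model with no period
effect.  The approximation ignores the t-distribution of the test
statistic, so the realised power of a paired t-test at the returned n
is slightly below nominal for small n (about 0.75 instead of 0.80 at
n = 8) and converges to nominal as n grows; the Monte-Carlo check in
the suite runs at n ≈ 140 where the deficit is within a couple of
percentage points.  Users planning very small studies should add a
subject or two or use a noncentral-t iteration.

## Bland-Altman

Points are (pair mean, difference) with difference = retest - test by
default — the direction is a convention, stated on the summary and
configurable, since the underlying method does not fix it.  Limits use
the normal quantile (bias ± 1.96 SD at alpha = 0.05); a t-based
small-sample option exists but is off by default to match the
conventional limits.  `sd_diff^2` estimates 2 sigma_e^2, tying the plot
back to the model.

## Synthetic data generator

The generator draws directly from the model above, one region at a
time, from per-region streams spawned off a single integer seed
(`numpy` `SeedSequence`), so output is bit-for-bit reproducible and
regions are independent.  Defaults emulate the structure of a published
five-dataset brain-PET test-retest corpus: datasets of 7, 10, 7, 5 and
8 subjects, ten common brain regions, three quantification methods per
dataset.  Region grand means are fixed plausible V_T-like levels (6-16
units; amygdala 12.3); per-method noise defaults to WSCV 5% for the
well-identified methods and 7% for the two-tissue-compartment model,
with ICC 0.93 — the regime published for well-behaved tracers.  These
defaults are study-structure choices, stated once here and not tuned.

Contamination multiplies one scan (default the retest) of selected
subjects by a factor gamma, emulating a kinetic-model identifiability
failure that returns an unreasonably inflated outcome; an additive mode
exists as an alternative.  Generated values are floored at 1e-6 so the
ratio-scale indices stay defined; floor events are counted and logged
(they are essentially impossible at the default parameters).

What the generator does *not* emulate: PET time-activity curves, image
noise, arterial input functions, region-size effects, correlated
regions within a subject, or session-order (period) effects.  Passing
tests therefore demonstrate correctness of the statistics under the
stated model, not robustness to every feature of real PET data.

With one gamma ≈ 4 outlier among seven subjects the generator
reproduces the qualitative signature reported for a poorly identified
quantification method — WSCV ≈ 0.7, PTRT ≈ 0.2, ICC near 0 — see
`examples/04_outlier_sensitivity.py`; this is a demonstration, not a
pinned test, because the underlying clinical datasets are not publicly
deposited.

## The sensitivity experiment

`outlier_sensitivity_experiment` draws clean data once per replicate,
applies the contamination to a copy of the same draw, and evaluates all
indices on both, reporting relative changes.  The contract verified by
the suite: at gamma = 3 with one outlier among 7 subjects, the relative
inflation of WSCV exceeds that of PTRT in at least 95% of 1,000
replicates, and ICC decreases.

## Numerical and design choices

* Default alpha = 0.05 everywhere; the exact quantile 1.95996 is used
  internally (the conventional rounding 1.96 appears only in prose).
* Strict vs. lenient I/O is an explicit flag, as is the long/wide
  dialect — no auto-detection, because silently misreading
  repeatability data is worse than an error.  Dropped rows/subjects are
  always counted in the log.
* Figures are an optional layer (`retest.plots`); the numeric pipeline
  never imports matplotlib.
* Known limitations: one-way model only (no rater-crossed two-way
  designs), exactly two replicates, no concordance correlation or
  kappa, no REML, and the WSCV/RC intervals are plug-in approximations
  as described above.
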