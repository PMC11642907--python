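# Methods

## The statistical model

Let x_A(t), x_B(t) be the node-averaged BOLD time courses of two regions in
one subject and session. Observed connectivity is Pearson's r(x_A, x_B).
Within-subject time-course reliability of a node is Pearson's r between its
test-run and retest-run series. Because correlation is attenuated by
measurement error, the observed connectivity cannot (in expectation) exceed

    ub(A, B) = sqrt(max(ρ_A, 0) · max(ρ_B, 0)),

and *detectable connectivity* is defined by the case rule

1. ρ_A < 0 or ρ_B < 0  →  0 (the bound is undefined for negative reliability);
2. observed r ≥ 0      →  min(r, ub);
3. observed r < 0      →  −min(|r|, ub).

The rule is idempotent and preserves the attenuation chain
|detectable| ≤ ub ≤ 1 and |detectable| ≤ |observed|, which the test suite
asserts on every subject × path.

Serial dependence is handled twice, deliberately with two different tools:

- **AR(1) prewhitening** corrects the *point estimate*: for each pair of
  series the lag-1 autocorrelation of the mutual regression residual is
  estimated in both directions and averaged into one common weight ρ, and
  both series are filtered as y[t+1] − ρ·y[t] (first sample dropped). One
  weight per pair per context: the test/retest pair of a node for
  reliability, the A/B pair within a session for connectivity.
- **the stationary block bootstrap** corrects the *uncertainty*: CIs of all
  correlations are 2.5/97.5 percentiles over replicates that resample
  time indices in blocks with geometric lengths (mean b) and uniform starts,
  wrapping circularly. The expected block length is selected per series by
  the flat-top lag-window rule (scan the autocorrelation function for the
  first lag followed by an insignificant run, estimate the spectral
  quantities with trapezoidal flat-top weights, b ∝ n^(1/3)), and the
  largest b among the jointly resampled series is used for all of them.
  Every replicate applies ONE index vector to all series so cross-series
  alignment — and hence the correlation being bootstrapped — is preserved.
  For detectable connectivity the replicate recomputes the full case rule
  from the resampled underlying series (session pair plus both test/retest
  reliability pairs; with AR(1) variants these are the prewhitened series,
  whitening weights held fixed across replicates).

Group analysis Fisher-transforms the per-subject correlations (forward only)
and runs a two-sided one-sample t test per path and session. Conjunction
takes the smaller t / larger p of the two sessions; a path is reproducible
at α iff its conjunction p < α, i.e. iff it is significant in both sessions.
Dice overlap 2|A∩B|/(|A|+|B|) summarizes map agreement along the grid
p = 0.05^(0.1·n), n = 1…250 (0.74 down to 2.98e−33), with the Bonferroni
point 0.05/n_paths marked. Distribution summaries (grand means, averaged CI
bounds, percentiles, std) pass through the Fisher z domain; because all
series have equal length, degrees-of-freedom weighting of CIs is unnecessary.
Entries whose CI upper bound is negative are treated as robustly negative
connectivity and enter the grand mean by magnitude (bounds swapped).

## Synthetic cohorts

The generator emulates a slow event-related working-memory design measured
twice: 24 task cycles (~10 s active, pauses jittered uniformly around 12 s)
in 488 volumes at TR = 1.24 s, 50 subjects × 34 nodes by default. Each node
series is

    gain_s · profile_n · regressor_sess(t) + Λ_n·f(t) + leak·nuisance + AR(1) noise.

- **Task regressor**: boxcar cycles convolved with a canonical double-gamma
  hemodynamic response, unit peak. Jitter shifts each cycle within a fixed
  slot rather than accumulating; accumulated pause jitter would decorrelate
  the test and retest schedules almost completely by the 24th cycle, whereas
  the fixed-slot design keeps the two session regressors correlated (~0.96),
  which is what makes high within-subject reliability attainable at all.
- **Subject gains** g_s ~ Gamma(shape 4, scale 0.44) with an 8% zero-gain
  mass: right-skewed reliability heterogeneity including non-reproducing
  subjects, whose time courses fluctuate to negative test-retest
  correlations about half the time.
- **Node profile**: gain multipliers linspace(0.5, 1.5), spreading mean
  reliability across regions roughly threefold.
- **Latent factors** (3, AR(1), unit variance): loadings with one global
  positive factor (scale 0.7) and two weaker random-sign factors. They
  create inter-node correlation that does not repeat across sessions —
  connectivity *beyond* what reliability licenses — which is exactly the gap
  between observed and detectable connectivity.
- **Noise**: AR(1) with φ = 0.4, unit innovation variance; 12 nuisance
  series (5 "white matter", 5 "ventricle", 2 motion-like components) leak
  weakly (0.25) into the data and are available for GLM residualization.
- **Response times**: 48 items per session, Stroop items (odd positions)
  systematically faster than memory items. A subject's target RT reliability
  is a squashed latent trait correlated with that subject's time-course
  reliability at strength `rt_coupling` (default 0.46); session noise is
  scaled to realize the target in expectation. Subject-specific stable item
  deviations dominate the shared task profile (~80/20), so RT reliability
  reflects the subject rather than the template.

With these defaults a full-scale cohort reproduces the calibration anchors:
grand-mean reliability ≈ 0.18 raw / 0.09 after AR(1), mean absolute
connectivity ≈ 0.38 observed / 0.32 AR(1) / 0.17 detectable / 0.08
detectable-AR(1), behavioral coupling ≈ 0.4–0.5, group RT-curve reliability
≈ 0.8. The generator does **not** simulate volumetric images, physiological
noise spectra, motion artifacts, scanner drift beyond a linear trend, or
learning effects between sessions — so passing tests demonstrate the
statistical machinery under the stated dependence structure, not robustness
to every artifact of real BOLD data.

## Numerical choices

- Correlations of exactly ±1 are clipped to ±0.999999 before the Fisher
  transform; distribution std is computed in z and back-transformed.
- Undefined correlations (constant series) are carried as NaN sentinels,
  excluded from means and counted.
- Cross-subject t tests treat spreads below 1e−12 (relative to the mean) as
  degenerate: zero mean gives t = 0, p = 1, nonzero gives signed-infinity t
  with p = 0.
- Block lengths are floored at 1 and capped at n/3; the automatic selector
  requires n ≥ 20 and a nonconstant series.
- Bootstrap replicates with undefined statistics are dropped; more than 1%
  is an error.
- The reliability of exactly 0 is treated as nonnegative in the case rule
  (strict `< 0` test).
- Top-fraction maps break magnitude ties by path index.
- Pipeline outputs record the config hash and seed; cohort TSVs are written
  with 17 significant digits and parsed with round-trip float precision so
  write→read is bit-identical.

## Design choices where the design was open

- The automatic block-length selector is implemented in-package (flat-top
  lag-window rule with the standard finite-sample cap), following the
  published algorithm; percentile CIs (not BCa) are reported everywhere.
- Whether test and retest series should be resampled jointly or
  independently for reliability CIs is not determined by the estimator
  itself; joint resampling was chosen because it preserves the alignment the
  statistic depends on.
- Monte-Carlo "subsamples" of size n from an n-subject cohort are drawn
  *with replacement* — without replacement there is no sampling variability
  at full n, yet between-sample variability at full n is one of the
  quantities of interest.
- Random connectomes sample node subsets from a generator-defined pool with
  a configurable task-driven fraction (no surface geometry is simulated).
- The Monte-Carlo summary reports mean reliability with negative values set
  to zero, and grand mean / std / 2.5–97.5 percentiles per statistic. The
  grand mean of a discrete statistic with a boundary point mass (e.g. Dice
  = 1 in almost every iteration) can legitimately fall outside its own
  percentile band; only ordering and sign of the summaries are enforced.

## Problem sizes used by the test suite

Unit tests run reduced cohorts (typically 12 subjects × 8 nodes × 240
volumes × 9 cycles) that keep the full temporal structure; calibration-level
checks use 20 seeded cohorts at default amplitudes with 20–50 subjects × 12
nodes × 488 volumes; bootstrap coverage uses 500 runs × 300 replicates at
n = 488. Bootstrap replicate counts in tests (150–500) are reduced from the
10,000 used for production CIs; percentile endpoints converge well before
that for the quantities tested.

## Limitations

- The AR(1) model leaves very small residual autocorrelations at lags 1–3
  (checked < 0.05); higher-order or frequency-domain whitening is out of
  scope.
- The attenuation bound assumes the reliability estimates themselves are
  noiseless; at n = 488 their sampling error is small but nonzero, so
  detectable connectivity inherits some of that noise (visible in the
  bootstrap CIs).
- Negative-reliability handling (zeroing) is a convention; alternatives
  (excluding such paths entirely) change the summaries of heavily
  unreliable cohorts.
- The synthetic RT model shares one task template across subjects; shuffling
  subjects therefore leaves a small residual behavioral coupling (~0.1)
  rather than exactly zero.
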