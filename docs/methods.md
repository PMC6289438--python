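# Methods

## The signal-processing chain

A trial is one 15-m run recorded by a six-channel trunk sensor: three
acceleration channels (X caudal-cranial, Y medial-lateral, Z
ventral-dorsal, in G) and three angular-velocity channels (dps), sampled
every 20 ms within hardware ranges of ±8 G and ±1000 dps.

Processing order is: (1) estimate the gravity offset as the per-channel
mean over the standing window of the *full* recording and subtract it
from every acceleration sample (angular velocity is not corrected);
(2) restrict all channels to the start→goal run segment; (3) summarise.
The order matters and is a package choice: estimating the offset before
segmentation lets a pre-run standing window calibrate the run. Offset
removal is idempotent, and a stable Kalman-style identity is not needed
here — it is plain mean subtraction, tested against a brute-force
oracle.

Summaries per trial: `Ax, Ay, Az, Gx, Gy, Gz` are means of absolute
values; `AM` is the per-sample Euclidean norm of the three acceleration
channels averaged over the trial; each acceleration ratio is the
per-sample percentage `100·|axis|/AM` averaged over the trial.
Averaging ratios per sample (rather than taking the ratio of trial
means) is deliberate and unit-tested as a different statistic. Samples
with `AM = 0` carry no direction and are dropped from the ratio average;
their count is logged and reported. Standing windows shorter than 6 s
are accepted with a warning (the study design includes 2–5 s fallback
windows); below 1 s the calibration is rejected. Samples at the exact
range limits are kept but counted as possible clipping.

Each 15-m pass is one trial; a session summary is the unweighted mean of
its passes.

## The local level model

For dog *i* at month *t* in one phenotype group,

    z_it ~ N(m_t + β·x_it, σ₀²),   m_t ~ N(m_{t−1}, σ₁²),

where `z` is `log(y)` for positive outcomes or `log(r/(100−r))` for
percentages. One trend is shared by all dogs in the group — there is no
subject-level random effect, by design; the model's only pooling is the
common trend, so "improving" it with per-dog effects changes the
estimand. Months with no observations are allowed: the trend evolves
across them and their bands widen. Fits are run separately per group,
region and outcome; covariate fits run on dystrophic dogs only, one
covariate at a time.

Inference is Gibbs sampling with three blocks: a joint draw of
`m_1..m_T` by forward-filtering backward-sampling (exact for the
linear-Gaussian state space; months with multiple dogs collapse to
their mean with variance σ₀²/n_t), conjugate inverse-gamma draws of σ₀²
and σ₁², and a conjugate normal draw of β. With the variances fixed the
sampler reduces to exact iid posterior draws, which is the basis of the
oracle-equivalence tests against the Rauch-Tung-Striebel smoother, and
the smoother itself is tested against dense joint-Gaussian conditioning.

Priors (all configurable): `m_1 ~ N(0, 10²)` on the transformed scale,
`σ² ~ InvGamma(0.001, 0.001)` for both variances, `β ~ N(0, 10²)`.
Defaults for production fits: 4 chains × 10 000 iterations, 5 000
burn-in; the packaged study configurations use 2 chains × 4 000
(burn-in 2 000), which the convergence diagnostics accept comfortably at
this problem size (≤ 66 observations, T = 11). Chains are seeded by
spawning a NumPy `SeedSequence`, so reruns are bit-identical.

Reported summaries are posterior means with equal-tailed 2.5/97.5%
sample quantiles (not HPD). β "excludes zero" iff 0 lies outside its
interval. Convergence is flagged (not raised) when the split-chain
statistic exceeds 1.05; split-R̂ and effective sample size come from
arviz.

Covariates may be standardized (z-scored across the panel) before
fitting, exposed as a flag and used by the pipeline, so β is per
standard deviation of the covariate; fitting on the raw scale is the
library default.

### Numerical choices

- Kalman update uses `P ← R·K` instead of `(1−K)·P`, which avoids
  catastrophic cancellation under diffuse priors (P ~ 1e10).
- The logit back-transform `100/(1+exp(−z))` cannot overflow and is
  clamped to the nearest representable values inside (0, 100), so
  extreme draws cannot round onto the boundary.
- σ₁² may be passed as ~0 (static-level limit); σ₀² must be positive.
- FFBS consumes pre-drawn standard normals; the draw order is fixed, so
  results are reproducible across refactors of the inner loop.

## MRI analysis

`SNR = intensity / SD_air` per ROI; `Ave SNR` is the pixel-weighted mean
over both sides' ROIs of one muscle. The input boundary is the ROI table
(intensity, pixel count, background SD) — ROI delineation is manual in
practice and is not emulated. One `SD_air` per ROI row accommodates
either a per-image or per-slice noise estimate.

The Mann-Whitney U test enumerates the exact null distribution of U over
all group assignments of the pooled midranks whenever the combined
sample size is ≤ 12 (the study compares 5 vs 6), which is valid under
ties; the two-sided p is the null probability of a deviation
`|U − n₁n₂/2|` at least as large as observed. Larger samples use the
normal approximation with tie correction and continuity correction.
Pearson's r and its t-based p come from scipy. Both tests use the 5%
level. Fast/slow muscle grouping (fast: TC, EDL; slow: GM, GL, FDS, with
GM the sign exception) is stored as metadata only.

## The synthetic-data generator

The generator emulates the study design: 11 dogs (5 dystrophic, 6
wild-type littermates), months 2–12, two sensor regions, four 15-m
passes per session, 20 ms sampling, 10 s standing windows, and the named
missing dog-months (incomplete thoracic recordings, absent clinical
scores and activity counts, shortened offset windows).

- **Trials** are a quasi-static standing window (gravity + noise)
  followed by a periodic run: up to three harmonics at the stride
  frequency per axis. The waveform shape is a package choice — the
  downstream contracts are algebraic, not biomechanical — with
  wild-type peak amplitudes of order 1–2 G (X-dominant) inside the ±8 G
  range, and dystrophic amplitudes elementwise lower, declining from
  60% to 25% of wild-type across the study window, with a slower
  stride. Per-dog amplitude factors create between-dog variation.
- **Panels** are drawn from the local level model itself (so trend fits
  are parameter-recovery exercises): defaults σ₀² = 0.04, σ₁² = 0.01 on
  the log scale, latent trends interpolating natural-scale anchor
  points chosen to rise to a mid-study wild-type peak (month 4
  thoracic, 7 lumbar) and to decline monotonically in dystrophic dogs.
- **Clinical scores** are totals of seven sign grades (1–5 each, totals
  7–35), non-decreasing then plateauing per dog, with severity scaling
  the peak; **activity counts** decline roughly linearly with month
  under severity, with small lognormal noise.
- **MRI ROI tables** add a group intensity shift (~30 units ≈ 7.5 SNR
  at SD_air = 4) to dystrophic muscles plus a per-muscle coupling to
  the dog's end-of-study AM, planting the fast-muscle-negative /
  slow-muscle-positive correlation pattern with GM as the negative
  exception.

Everything is a pure function of its arguments including the seed; the
pipeline derives child seeds per dog/stage from one base seed, so adding
a dog does not perturb other dogs' draws and whole-study reruns are
byte-identical.

What the generator does *not* emulate: stride-to-stride variability and
gait transitions within a trial, sensor drift, per-dog trend
heterogeneity beyond amplitude scaling, and any image-level MRI
structure. Passing tests therefore demonstrate that the chain recovers
what the model family can express — algebraic signal contracts, exact
small-sample inference, and correctly calibrated trend/coefficient
posteriors under the model — not that the model captures real canine
gait.

## Problem sizes in the test suite

The suite favours small, well-understood instances: smoother-oracle
checks use T ≤ 5 with ≤ 10 observations (200 instances);
MCMC-vs-smoother checks use 10 panels at 5 dogs × 11 months;
coefficient-recovery uses 50 replicates per β ∈ {−0.5, 0, +0.5} at the
study's panel scale with 2 chains × 2 500 iterations, enough for the
interval endpoints' Monte-Carlo error to be small relative to the
posterior spread. In recovery simulations the latent trend is drawn from
the model's own random walk; planting a trend outside the model family
(e.g. an exact line) with a month-collinear covariate induces genuine
posterior bias in β and is not a calibration check. The end-to-end runs
use the packaged strong-effect configuration (two passes, 10 s trials)
rather than the full four-pass design purely to keep them brisk; the
full design runs the same code paths.

## Known limitations

- Exact Mann-Whitney enumeration grows combinatorially; beyond a
  combined n of 12 the implementation switches to the tie-corrected
  normal approximation.
- The shared-trend model cannot express per-dog severity trajectories;
  β estimates under strongly month-collinear covariates lean on
  within-month contrasts between dogs and inherit their precision.
- Ave SNR assumes the provided pixel counts are on a common grid across
  ROIs of a muscle; no resampling is attempted.
- `compare_trends` reports band overlap per month; it is a descriptive
  display, not a formal test of trend difference.
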