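# Methods

This note documents the models and procedures implemented in `meiomove`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Input model and derived descriptors

Tracks are long-format records of (group, particle, time in minutes, x, y)
plus optional morphology descriptors. Validation is strict: non-finite
rows and duplicated or non-monotone time stamps are errors, never silent
drops. Time alignment supports a common zero at the first or the last
frame of each track; the last-frame convention matches the biology
(anchoring every cell's clock at meiosis I onset) and is the default.

Linear velocity is the centroid displacement norm per minute. Angular
velocity is the signed, wrapped change of the displacement heading in
(−π, π] radians per minute — the heading of the centre-of-mass motion,
not the blob's major-axis orientation, which is an upstream morphology
descriptor; an orientation-based variant would be a small extension of
`derive_velocities`. Zero-displacement frames keep the previous heading
(no turn). Edge frames with undefined velocities are explicit NaN and are
excluded from densities and tests, never zero-filled.

Principal-axis rotation centres each track and applies a det=+1 rotation
taking the leading eigenvector of the positional covariance to the x axis,
with the sign fixed so the first nonzero displacement has non-negative x.
Value normalisation (min-max to [0,1] or z-score) is computed per dataset,
pooled across groups, so groups remain comparable; a per-particle mode
exists behind a flag. A constant column normalises to zero with a warning.

## Synthetic trajectory generator

Each track is a four-stage piecewise signal of 180 one-minute steps in
dimensionless units. Within a stage of duration L starting at value b,

    x(t0 + k) = b + W(k) + osc(k) − osc(0),   k = 0..L−1,
    osc(k) = A · sin(2π k dt / P + φ) · g(k),

with W a cumulative Gaussian walk (per-stage step sd), P ~ U(period
range), A ~ U(amplitude range), φ ~ U(0, 2π), and g(k) = 1/(1 + k·dt)
when decay is on (decay is stage-local; a global reciprocal-of-time gain
would flatten every later stage trivially). Subtracting osc(0) makes the
trajectory exactly continuous at stage joins for any phase, which is what
observed chromosome trajectories look like; with φ = 0 the formula reduces
to b + W(k) + A·sin(2π k dt / P)·g(k). The y channel is a small
independent walk (sd 0.05) so 2D operations are exercised.

Stage defaults emulate a wild-type-like meiotic prophase: A — period
5–7 min, amplitude 2–3 (fast horsetail oscillation); B — period 8–12 min,
amplitude 1–1.5 (slower, lower oscillation); C — decaying oscillation
(transition); D — amplitude ≈ 0 with a low-sd walk (confined,
post-horsetail-like). Durations are 50/50/40/40 steps. Type I plays
A,B,C,D; Type II plays B,A,C,D.

All per-stage random draws are keyed by (master seed, track index, stage
label), not by play order. A Type I track and its Type II counterpart
therefore share walk increments and sinusoid parameters exactly and differ
only in stage order, which guarantees that pooled, order-blind summaries
(velocity distributions, displacement histograms) match between types by
construction — the property the power experiment rests on. For null or
calibration experiments this sharing is wrong (the two groups must be
independent samples), so `null_config` / `share_draws=False` decouples the
draw streams.

The generator is a test fixture with known ground truth, not a
biophysical model: it has no inertia, no confinement geometry, no
measurement noise model, and its stages switch instantaneously. Passing
tests on it demonstrate that the analysis chain recovers order structure
and planted couplings under realistic amplitudes and time scales, not that
it would resolve any particular real mutant.

`generate_coupled_covariates` adds a channel m(t) = c·v(t−lag) + ε(t)
(v = linear velocity, ε Gaussian) with the ground-truth edge recorded, as
the recovery fixture for the causality stack.

## Segmentation

For one or two channels, change points minimise the heteroscedastic
Gaussian contrast: cost(i..j) = Σ_channels (L/2)(log 2πσ̂² + 1) with the
MLE variance per segment, floored at 1e−10 against log 0. Using both a
segment-specific mean and variance lets the programme separate regimes
that differ in variability (oscillation amplitude) and not just in level —
essential here, because behavioural stages mostly modulate variance. The
dynamic programme is exact for every k ≤ K (verified against exhaustive
enumeration in the tests), subject to a minimum segment length L_min.
Model order follows Lavielle's criterion: normalise the contrast curve to
J̃(k) with J̃(1) = 1 and J̃(K) = K, and pick the largest k whose second
difference D(k) = J̃(k−1) − 2J̃(k) + J̃(k+1) exceeds S. Defaults K = 10,
L_min = 5, S = 0.75 (the standard choice in the change-point literature;
smaller S segments more aggressively). Series too short for K·L_min reduce
K with a warning; a constant series yields one segment.

For d ≥ 3 channels, time points are first clustered into n_states = 4
states by k-means on the standardised channel vectors; a dynamic
programme then maximises Σ_segments [max_state Σ_t sim(t, state)] − λ·(#
segments), sim being the Pearson correlation between a time point's
vector and a state centroid. λ defaults to 0.5·L_min·d so that the
penalty scales with both channel count and minimum length; on the
synthetic fixture this lands segment counts in the 3–6 range.

Per-segment features are, for each selected covariate: mean, sd, dominant
period and dominant power fraction from the mean-removed periodogram,
plus segment duration. Segments shorter than 4 frames carry missing
spectral features. Features are z-scored across all segments (constant
features left at zero, missing values imputed to 0 after scaling) and
clustered by full-covariance Gaussian mixtures for each candidate k in
1..10, five EM restarts each (scikit-learn's best-of-restarts), selected
by BIC = 2·log L − p·log n, maximised — the sign convention is stated
because both conventions circulate; ties go to the smaller k.

The default analysis covariate for movement-based segmentation is linear
velocity: it is stationary within a behavioural stage, whereas raw
position is dominated by the random-walk drift, which the Gaussian
contrast then attributes to spurious mean shifts. This mirrors the
practice of segmenting movement descriptors rather than coordinates.

## Composition statistics

The observation unit is the segment — the only entity carrying all the
named predictors (cluster label, start time, end time, proportion of
track). With Y indicating group membership, the model family is:
cluster × start × end (full factorial; the headline model, since start
and end jointly encode both location and duration of a cluster's
occurrences), start × end ("time"), cluster × proportion, cluster main
effects, and intercept-only. Each is fitted by iteratively reweighted
least squares with a ridge penalty of 1e−4 on slopes (never the
intercept) to stabilise separation-prone fits; separation is additionally
flagged at |β| > 15. Significance is the analysis-of-deviance χ² of the
model against intercept-only; the "likelihood-ratio" variant uses the
same deviance statistic, so the two agree by construction. Continuous
predictors are z-scaled (this leaves deviances unchanged). P-values are
reported per model without cross-model adjustment, matching the practice
of reporting a single headline comparison.

Power assessment generates, per replicate, a fresh Type I/II dataset pair
at the requested size, runs the named test end-to-end (composition:
velocity segmentation → GMM → headline ANOVA; global_velocity: pooled
Mann-Whitney U), and reports the fraction of replicates with p < α, with
per-replicate seeds and p-values stored so the estimate is exactly
recomputable. Replicate seeds spawn from the master seed via
`numpy.random.SeedSequence`.

## Spectral, velocity and MSD summaries

The periodogram is the mean-removed FFT power on a period axis, normalised
so total power equals the series variance (Parseval, tested to 1e−8).
Spectrograms use 30-min Hann-tapered slices hopped one frame at a time
(defaults; none are prescribed anywhere authoritative), ensemble-averaged
across particles on the common-zero time axis and optionally normalised to
[0,1] per time slice for display. The spectral-density group test is a
declared construction: per-particle log band powers in octave period bands
(2–4, 4–8, 8–16, ≥16 min) feed a binomial GLM of group on band powers,
tested against intercept-only by analysis of deviance.

Velocity densities are Gaussian KDEs per stratum (group, or group ×
behavioural cluster); the time-resolved variant is a (time × velocity)
histogram grid with each time slice normalised to integrate to 1.

MSD(τ) averages ‖r(t+τ) − r(t)‖² over particles and overlapping start
times; MSD(0) = 0. Per-cluster curves assign each (t, t+τ) pair to the
cluster of its start frame, so the pair-count-weighted average over
clusters reproduces the global curve exactly (tested); pair counts are
proportional to cluster durations up to edge effects.

## Matrix profile and motifs

The matrix profile stores, per window start, the z-normalised Euclidean
distance to the nearest window at least ⌈w/2⌉ positions away (the
exclusion zone; distance and Pearson correlation are related by
d² = 2w(1−ρ)). The exact method is a streaming diagonal pass with running
dot products — O(n²) time, O(n) memory — and matches an O(n²) brute force
to 1e−6 in the tests. The approximate method runs anchor-window distance
profiles on a ⌈w/4⌉ grid plus a seeded random 25% of the diagonals; since
the profile only ever min-updates, it upper-bounds the exact profile
pointwise and converges to it as the budget grows. Windows with variance
below 1e−12 take the maximal distance 2√w instead of a degenerate
z-normalisation, so flat (post-horsetail-like) stretches produce neither
trivial motifs nor discords. Concatenation junctions mask every window
spanning them, and masked positions are excluded both as queries and as
neighbours; a provenance table maps every concatenated index back to
(group, particle, common-zero time). The "number of samples" parameter is
kept for interface parity with the field's tooling; it only budgets the
approximate phase and is a no-op for the exact method.

Motifs are extracted greedily: seed at the smallest unmasked profile
value, collect all windows correlating at least the threshold with the
seed (nearest first, overlaps within the exclusion zone suppressed), mask
the collected regions, repeat. The default threshold is 0.98; on the
synthetic fixture, where oscillations have random phases and a random-walk
component, near-duplicate windows at ρ ≥ 0.98 are rare, so the fixture
analyses in the tests use ρ = 0.9, which yields tens of matches per motif
— the interesting quantity there is the motif's *location* distribution,
compared between groups by a Mann-Whitney U-test per motif.

## Causality

**PC algorithm.** Observations are time points treated as iid samples (the
classical caveat applies and is why the variable-lag routes exist).
Conditional independence is tested by the Fisher-z transform of the
partial correlation obtained from regression residuals, with statistic
√(n−|S|−3)·|z|. The skeleton phase is the stable variant (adjacency sets
frozen per level) so the output does not depend on variable order;
v-structures are oriented by the separating sets, then Meek rules R1–R3
close the orientation. Only arrowheaded edges count as causal claims —
undirected CPDAG edges contribute 0 in both directions, since an
unoriented edge is not a directional finding.

**Variable-lag alignment.** Both variable-lag routes align the source to
the target by a banded, monotone dynamic time warping on z-normalised
copies with per-time lags Δ(t) ∈ [1, max_lag] — strictly positive, so the
aligned source x̃(t) = x(t−Δ(t)) is genuinely past information. Each lag
change along the path costs a penalty (default 4.0 on the z-scale). The
penalty is load-bearing: an unpenalised alignment is free to chase value
coincidences and manufactures dependence between independent series
(measured here as ≈0.55 bits of spurious transfer entropy and a 100%
false-positive rate for the naive Granger F-test on white noise), while
the penalised path leaves drifting-lag detection intact. The penalty
default was chosen by these operating characteristics: at 4.0 the noisy
binary channel reproduces its closed-form transfer entropy within 0.01
bits and null-noise TE drops to ≈0.1 bits.

**VLGC.** Nested regressions y(t) ~ y(t−1..p) versus
y(t) ~ y(t−1..p) + x̃(t−0..p−1), p = max_lag, compared by the F statistic
on the residual-sum-of-squares reduction. Because the alignment is
data-adaptive, the analytic F reference is invalid for the variable-lag
statistic (it rejects essentially always under the null); significance is
instead calibrated by circular-shift permutations of the source, each
re-aligned and re-fitted (default 200; the analytic reference remains
available, and exact, for the fixed-lag variant). The direction flag
requires a positive median alignment lag.

**VLTE.** Transfer entropy in bits with history length one,
TE = Σ p(y_t, y_{t−1}, x̃_t) log₂[p(y_t | y_{t−1}, x̃_t) / p(y_t |
y_{t−1})], over quantile-discretised series (default 3 bins; series with
fewer distinct values use them directly). The alignment pairs the source
with the *next* target sample (Δ ≥ 1 relative to y_t), which is what makes
the lag-1 noisy binary channel attain its closed form 1 − H(ε).
Significance comes from circular-shift permutations of the source with
re-alignment (default 100 per direction; the scan uses enough permutations
that the smallest achievable p clears the Bonferroni-adjusted α for a
two-variable scan at 200). A claim additionally requires
TE(x→y) > TE(y→x).

**Aggregation.** Per particle, the ordered-pair p-values are adjusted
(Bonferroni by default, m = pairs actually tested for that particle; Holm
and Benjamini-Hochberg available) and thresholded at α = 0.01 into a
binary matrix A. Â is the entrywise mean over particles — â_ij is the
fraction of cells in which i→j was individually significant — and the
reported graph keeps edges with â_ij at or above the presence threshold
(default 0.8 for strongly conserved relations; 0.75 or 0.5 reproduce the
more permissive settings). Exports: Â as CSV, the retained edge list as
CSV, and GraphML with weights.

Whether to detrend series before causal discovery is left to the caller
(`detrend` flag, off by default — raw series are the default input).

## Pipeline and reproducibility

The `run` pipeline executes ingest → normalise → derive → segment →
cluster → stats/motifs/causality from a YAML/JSON configuration whose
defaults are exactly the module defaults above. Every stage draws its
randomness from a named SHA-256-derived substream of the master seed; no
stage touches global RNG state. The manifest — written last, as the
completion marker — records the resolved configuration, consumed seeds
and SHA-256 checksums of every output, and two runs with the same
configuration are bit-identical (tested). All outputs are plain CSV /
JSON / GraphML.

## Problem sizes used in the shipped experiments

The power experiment runs 100 replicates at 60 tracks per group of 180
frames each (the sample size at which the composition route reaches
1−β ≥ 0.8 while pooled-velocity testing stays near its nominal level);
oracle-equivalence checks use series of length ≤ 200 against brute force;
causal recovery uses 20 particles with a planted lag-5 coupling and
n = 1000 linear-Gaussian fixtures for the PC ground truths; the
order-swap analyses use 60 tracks per type. These sizes are the package's
standard demonstration scale; every harness accepts larger values through
its parameters.

## Known limitations

- The Lavielle and multivariate engines are offline, whole-track methods;
  there is no streaming or HMM-based alternative.
- The composition GLMs inherit logistic regression's linear-response
  assumption, and the mixture clustering assumes Gaussian feature
  clusters.
- The matrix profile is univariate (one variable at a time), as
  multidimensional motif interpretation is out of scope.
- PC treats time points as exchangeable samples; for autocorrelated
  series its error control is approximate, which is precisely why the
  variable-lag routes and the per-cell presence aggregation exist.
- Permutation p-values are resolution-limited at 1/(n_perm+1); scans at
  small α need n_perm chosen accordingly (the defaults already are).
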