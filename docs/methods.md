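# Methods

This note documents the models implemented in `popdecode`, the parameter
choices behind them, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would want recorded.

## Task and circular conventions

Orientations live on a half-circle: θ and θ+180° are the same grating, so
every trigonometric transform uses the doubled angle 2θ and differences
are wrapped to (−90°, +90°] (`popdecode.circular`). The signed angular
distance Δ between stimulus and template is the central task variable:
cos 2Δ is the decision-value (magnitude) component — 1 at targets, 0.92 at
±11.25°, −1 at ±90° — and sin 2Δ the task-irrelevant sign component —
±0.38 at ±11.25°, 0 at 0° and ±90°.

The task generator draws stimuli in successive shuffled full cycles of the
16 orientations. This is the only reading of "equiprobable and exhausting
the set" that makes the 1/16 target rate exact: each block of 480 stimuli
contains exactly 30 targets. Templates are drawn without replacement
within a session (8 of 16); whether they may repeat across sessions is a
config flag (`templates_unique_across_sessions`, default off). Onsets
accumulate 100 ms stimulus duration plus a uniform 516–783 ms ISI.

## Synthetic sensor data

`generate_sensor_epochs` builds trials × sensors × time arrays as
spatially correlated Gaussian noise (exponential correlation across the
sensor index, length 5 sensors — enough structure to make Mahalanobis
whitening non-trivial) plus up to three linear orientation codes, each a
pair of unit-norm random sensor patterns multiplied by (cos 2·, sin 2·) of
its label:

| code | label | default window | dynamics |
|---|---|---|---|
| stimulus | θ_s | 50–500 ms | static, or rotating through an orthogonal pattern pair with a configurable period |
| template | θ_t | −100–300 ms | static; optionally *shares* the stimulus patterns (enables cross-generalization) |
| distance | Δ | from 350 ms | separate patterns for cos 2Δ and sin 2Δ, individually switchable |

The rotating option reproduces dynamic coding: decodable at every moment,
but with weights that do not transfer across time — while the pairwise
geometry of conditions (what RSA measures) stays fixed. The shared-pattern
option makes template-trained weights decode the stimulus, but (with a
rotating stimulus code) only at test times where the rotating pattern
passes through the shared pair, i.e. early.

What the generator does *not* emulate: evoked transients and 1/f spectra,
temporal noise autocorrelation, eye-movement or cardiac artifacts, sensor
physics (gradiometer/magnetometer scaling), or any nonlinearity. Passing
tests therefore demonstrate the correctness and calibration of the
analysis chain on data satisfying its linear-model assumptions, not
robustness to real M/EEG noise.

Behavior: each stimulus elicits a response with probability
p_max·e^{κ(cos 2·tilt − 1)}; defaults p_max = 0.7, κ = 4.5 reproduce a
~70% hit rate with ~50% false alarms at ±11.25°, the regime a practiced
observer shows in this task. RTs follow a shape-4 gamma shifted to 200 ms
and truncated at 1000 ms (mode ≈ 550 ms).

## Encoding model

The basis is a half-rectified cosine raised to the 15th power, peaking at
1 on its center and reaching 0 at 90° tilt; 16 channels tile the circle at
the task orientations (FWHM ≈ 34.5°). Weight estimation follows ordinary
least squares per time point, with the data boxcar-averaged over the
scheme's sliding window (20 ms stimulus/distance, 32 ms template); a
window is an average, not a feature concatenation, so there is one weight
per sensor. A constant regressor absorbs overall signal differences
between sensors; it is estimated with the design and discarded after
inversion. Rank-deficient designs (structural for the template scheme —
see below) fall back to the pseudo-inverse, logged at debug level.

Tuning-curve slope: channels equidistant from 0° are averaged, each folded
channel timecourse is smoothed with a 16-ms-SD Gaussian (smoothing 0 for
cross-temporal matrices), and a least-squares line is fit across channels
against −|tilt|, so positive slope = information. "Width X ms" of every
Gaussian kernel in the package means the standard deviation.

Template scheme: the 8 (typically irregular) template angles of a session
are assigned to 8 equally spaced pseudo-channels in rank order; tuning is
estimated in that space and the estimated values are linearly
(circularly) interpolated onto the doubled grid afterwards. Leave-one-
block-out removes one template from every training set, which makes the
design rank-deficient by construction; the pseudo-inverse path handles it.
The angular-distance scheme treats signed Δ as the circular label with the
standard 16-channel design; the tilt axis after sign-folding is the 0–90°
grid in 11.25° steps.

## Cross-temporal analysis and dynamic coding

Training times move in 12-ms steps (24 ms in the desk-scale cohort runs);
weights at each training time are applied to every test time, with no
extra smoothing. The dynamic-coding statistic is the elementwise minimum
of the two paired t maps t(slope(i,i) − slope(i,j)) and
t(slope(j,j) − slope(i,j)), cluster-formed at one-sided p < 0.05 and
corrected by 2-D cluster-extent permutation with joint per-subject sign
flips — the minimum implements the "both comparisons must hold"
conjunction while still permitting cluster correction.

Template→stimulus cross-generalization trains with template-scheme
preprocessing (baseline −200..−150 ms, 32-ms smoothing and window) and
tests with stimulus-scheme preprocessing (baseline −150..−50 ms, no
smoothing), recentering by the stimulus orientation; the result is
smoothed with a 20-ms kernel. A pre-stimulus variant trains on the
time-averaged −150..0 ms window only.

Jack-knife latency comparison: onset = first time point of the
cluster-corrected significant window; leave-one-subject-out onsets give
SE = √((n−1)/n · Σ(d_i − d̄)²) — the (n−1) inflation undoing the
jack-knife's variance reduction — and t = full-sample difference / SE on
t(n−1). At very small n a sign-flip cluster test cannot reach p < 0.05,
so an uncorrected-threshold onset rule is available (`onset_rule`).

## RSA

Condition means are computed per odd/even split; the within-condition
covariance is pooled over conditions and splits per time point and shrunk
toward its *diagonal* with an analytic (Schäfer–Strimmer-style) intensity
λ* = Σ_{i≠j} Var(s_ij) / Σ_{i≠j} s²_ij, clipped to [0, 1] — regularization
is required at desk-scale trial counts and the diagonal target preserves
per-sensor variances. RDM comparisons vectorize the strictly lower
triangle (the zero diagonal carries no information and would inflate
correlations). MDS is classical (double-centering eigendecomposition):
deterministic, rotation/reflection-invariant. The angular-distance RDM
regression uses the circular simplex over signed Δ plus two nuisance
models: the distance between unsigned decision values
(d(0°, −22.5°) = 22.5°, d(−22.5°, +22.5°) = 0°) and the absolute
difference in response frequency.

## State space

PCA loadings come from the trial-averaged sensor × time matrix (time
samples as observations) after 20-ms smoothing; single trials are
projected onto them. Per fold and time point, a GLM of the normalized
component scores on the six task regressors gives a 30 × 6 coefficient
matrix, replaced by the polar factor UVᵀ of its SVD — the closest matrix
with orthonormal columns ("symmetric" because no axis is privileged, in
contrast to Gram–Schmidt). Normalization (mean/SD across training trials)
is per component and per time point; test data reuse the training
statistics. Held-out condition means (one per signed Δ) are projected and
averaged over the 8 folds. The sign-axis divergence is the cw − ccw
difference of sign-axis projections for the ±11.25°, ±22.5°, ±33.75°
pairs, group-tested with a two-sided cluster permutation.

## Population model

Eq.-level choices: the von Mises response uses the doubled angle (the
layers code orientation, a 180°-periodic variable) and A = e^κ so the peak
is exactly 1. The template layer is updated as the element-wise product of
the stimulus and template responses and *propagated unnormalized*: the
product's peak value e^{−2κ_s sin²Δ′}·e^{−2κ_t sin²Δ″} falls off with the
stimulus–template distance, which is what makes the decision-layer peak
height decrease monotonically over 0–90° — renormalizing the product to
peak 1 would destroy that monotonicity, leaving only a width difference
that moves the peak the wrong way. Peak-normalized copies of every layer
are exposed separately for display. The template→decision weight matrix is
a von Mises profile (κ = 5) centered so the template-tuned unit drives the
0° decision unit; decision activity is therefore invariant to rotating
stimulus and template together (exactly so for rotations that are
multiples of the 1.8° unit spacing). The accumulator comparator is the
inner product of the stimulus response with the template tuning profile —
a matched filter: symmetric in the sign of Δ by construction. Model RDMs
use Euclidean distances between layer responses over the 16-point Δ grid;
the stimulus-layer RDM follows the circular simplex in rank order
(Spearman ≈ 0.995) but not linearly, because the distance between von
Mises bumps saturates beyond the tuning width at κ = 5.

## Inference

Cluster statistic: extent, at a cluster-forming threshold of p < 0.05
(one-sided for directional slope tests, two-sided otherwise), 8-connectivity
in 2-D (configurable), sign-flip permutation of subject maps, rank p-value
(1 + #null ≥ observed)/(n_perm + 1). Two calibration facts worth knowing:
on temporally *white* null maps the extent statistic is strongly discrete
(clusters of size 1–3) and hence conservative (FWER ≈ 1%); on smoothed
nulls matching the autocorrelation of decoding timecourses it operates at
≈ 3–6% for nominal 5%. And when an effect is nearly homogeneous across
subjects, sign-flip permutations close to the identity reproduce the
observed cluster, putting a floor of roughly P(≤k flips) on the attainable
p — the cohort simulator therefore draws per-subject gain (U(0.6, 1.4))
and noise (U(0.85, 1.2)) factors, emulating real between-subject
effect-size variability.

## Desk-scale problem sizes

Tests and the acceptance script run the full analyses at reduced sizes
chosen to keep every stage exercised: cohorts of 6–10 subjects, 8 blocks ×
48 stimuli, 24 sensors, epochs −250..600 ms at 12-ms resolution,
cross-temporal grids at 24–36 ms, 300–500 permutations, and
family-wise-error calibrations over 200 repetitions. The task generator's
own defaults keep the full design (8 × 480 trials, −1000..1000 ms at 4 ms);
behavioral analyses use complete 3840-trial sessions, where (P_MAX, κ)
recovery is tight. Gains (0.4–0.8 noise-SD units) are set so that effects
are reliably detectable at these sizes without being trivial.

## Known limitations

Linear codes and Gaussian noise only; no artifact or source modeling; no
cross-validated (cross-nobis) distances; the accumulator and population
models are static in time by design. The cluster test implements extent
only (no TFCE or mass statistics).
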