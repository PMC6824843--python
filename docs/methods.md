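# Methods

`bilat` reimplements, as a tested pipeline, the population analysis of how a
single motor-cortex hemisphere represents mechanical loads applied to the
contralateral versus the ipsilateral arm.  This note records the models,
estimators, and numerical conventions the package uses, the choices made
where the procedure was genuinely open, and what the synthetic-data tests do
and do not establish.

## Task structure and session model

A session contains trials from one recorded hemisphere.  Each trial holds an
unloaded posture for at least 500 ms, then applies one of eight step torque
combinations to the shoulder and/or elbow of one arm: the four single-joint
loads at ±0.20 Nm and the four multi-joint combinations at ±0.14 Nm per
joint, spanning joint-torque space at 45° spacing.  Flexion torques are
positive at both joints and the torque-space angle is measured
counter-clockwise from the shoulder axis; any consistent sign convention
reproduces the statistics, since only angles and angle differences are ever
compared.  Trials are labelled `contra` or `ipsi` by which limb was loaded
relative to the recorded hemisphere, so one code path serves either
hemisphere.

Spike times are stored as integers at 1 ms resolution.  All analyses align
to the load onset and use three epochs (half-open windows): baseline
[−200, 0) ms, perturbation [0, 300) ms, and steady state = the last 1000 ms
of the trial.

## Firing-rate estimation

Spike trains are convolved with a causal post-spike kernel

    k(t) = (1 − e^(−t/1 ms)) · e^(−t/20 ms),  t ≥ 0,

normalized to unit area and truncated where it falls below 10⁻⁶ of its peak.
Causality matters for onset estimation: a symmetric kernel would smear
response energy backwards in time.  The kernel peaks at ln(21) ≈ 3.04 ms.  A
Gaussian alternative (σ = 20 ms) is available for variance-capture analyses
that are conventionally reported with Gaussian smoothing; it changes the
context-matrix values but none of the bookkeeping.  Convolution uses FFTs
with zero padding before trial start; the baseline window begins ≥ 500 ms
into the trial, so edge effects cannot reach it.

## Context matrices

For the population analyses each neuron's trial-averaged perturbation-epoch
rate is point-sampled every 10 ms (0-based grid: t = 0, 10, …, 290 ms,
giving T = 30 samples; whether the grid should start at 0 or 5 ms is
unspecified in the source procedure, and the choice only relabels samples).
Rates are soft-normalized by each neuron's maximum trial-averaged rate
across *both* contexts plus 5 spikes/s — a joint maximum, because
per-context normalization would distort cross-context magnitude comparisons
— and the mean across the eight load conditions is subtracted at each time
bin within each context.  The result is one matrix per context,
`C, I ∈ R^(N×240)` with condition-major columns.  Every recorded neuron
enters these matrices, load-sensitive or not.  Because the cross-condition
mean is removed at each time bin, every row sums to zero exactly, and the
context covariance is simply `M Mᵀ/(240−1)`.

## Load tuning

**Sensitivity.**  A three-way ANOVA (epoch 2 × context 2 × load 8, Type-II
sums of squares, fully crossed linear model) runs on per-trial epoch-mean
rates for the baseline and perturbation epochs.  A neuron is load-sensitive
if the epoch main effect or any interaction involving epoch has p < 0.05.
Per-trial means are the observation unit — trial-averaged means would leave
no residual degrees of freedom for the F tests.  No multiple-testing
correction is applied anywhere; the 0.05 threshold is used throughout.

**Preferred load.**  For each neuron, context and epoch, per-trial epoch
means are fit with `rate = β₀ + β_s·τ_shoulder + β_e·τ_elbow` by least
squares after removing the mean rate.  The preferred angle is
`atan2(β_e, β_s)` and the magnitude `√(β_s² + β_e²)` in Hz/Nm.  The fit's
p-value is the overall regression F test (a single p per fit; per-coefficient
t tests are not used).

**Circular statistics.**  Population distributions of preferred angles are
summarized by the Rayleigh mean resultant length R; the bimodal variant
doubles the angles first, detecting axial (180°-symmetric) structure, and
reports its major axis in [0°, 180°).  Significance is the fraction of 1000
same-size uniform-angle samples whose R reaches the observed R.  Tuning
changes (between contexts, or between epochs) are signed circular
differences wrapped to (−180°, 180°], summarized with the unimodal R and the
same bootstrap.  Magnitude contrasts use the Wilcoxon signed-rank test
(normal approximation, so a z statistic is reported); ties in the
contra-larger fraction count one half.

## Response onsets

**Single neurons.**  The load evoking the largest |perturbation mean −
baseline mean| is selected; the trial average over that load and its two
45° neighbours forms the onset trace.  The onset is the first post-load
millisecond at which the deviation from the baseline mean exceeds 3 baseline
SDs and remains above threshold for 20 consecutive ms.  The criterion is
two-sided on |deviation| by default (inhibited neurons are detected too);
`two_sided=False` restores a one-sided rule.  Baseline statistics come from
the 1 ms trial-averaged trace over the 200 ms baseline window.  A zero
baseline SD yields an undefined onset with a degenerate flag.

**Population.**  The population trace averages each neuron's best-load
response change, signed so the dominant deflection is positive.  Selection
and sign determination use two-fold cross-fitting on a deterministic
alternating trial split: each fold's best load and sign are estimated on the
*other* fold, so no trial influences its own selection.  Without this, the
max-over-loads selection rectifies noise into a positive pedestal that
appears only after load onset; the pedestal does not shrink with the neuron
count while the averaged trace's baseline SD does, so at population scale it
produces spurious near-zero onsets.  On zero-response control sessions the
cross-fitted detector produced 0/8 false detections.

**Estimator properties worth knowing.**  Threshold crossing adds a delay
that scales with (3·SD)/amplitude along the response rise, so weaker
responses are detected a few ms later than stronger ones.  At the study
conditions this inflates the recovered contra→ipsi lag by ~2–4 ms on
average, and it couples *single-neuron* onset estimates to response
magnitude (Pearson r ≈ −0.4 between onset difference and log magnitude
ratio on synthetic data) even though the generator's latencies are
magnitude-independent.  Population-level comparisons should therefore rely
on the population trace, not on averaged single-neuron onsets.  Single
sessions also carry a few ms of onset jitter; occasional early crossings
survive the 20 ms dwell because smoothing correlates neighbouring samples.

## Correlation restructuring

Pearson correlations are computed between every unordered neuron pair's
context-matrix rows, per context; the statistic is the median |r_contra −
r_ipsi| over pairs (pairs with a constant row are skipped).  Soft
normalization cancels in Pearson r but the cross-condition mean subtraction
does not, so correlations are computed on the fully preprocessed rows.

The null asks how much change finite trial counts alone produce: per
replicate, the trials of every condition within one context are randomly
halved (the larger half takes the extra trial when counts are odd), the two
halves are trial-averaged and preprocessed with the *full-data*
soft-normalization divisors (the divisor is a property of the session, not
of a resample), and the median |Δr| between halves is recorded; 1000
replicates per context, with the observed value's p reported against each
context's null separately.  Full null samples are retained in results
rather than only a mean ± SD summary.

## Subspace analyses

**PCA and the alignment index.**  PCA uses the SVD of each (row-zero-mean)
context matrix.  The alignment index of a k-basis B against a covariance
`Cov` is

    A = Tr(Bᵀ·Cov·B) / Σᵢ₌₁..k λᵢ(Cov),

the variance captured normalized by the most any k orthonormal directions
could capture (the sum of the top-k eigenvalues).  It is 1 exactly when B
spans the top-k eigenspace and 0 when B is orthogonal to the support.  The
headline quantity is the mean of the two cross-context indices (contra PCs
on the ipsi covariance and vice versa), k = 10.

**Random-subspace null.**  PCA runs on the column-concatenation [C I]; each
replicate draws two k-sets of those components with selection probability
proportional to the variance each captures, and scores them exactly as the
observed indices are scored.  The two sets are drawn *independently* (each
without replacement internally).  A stricter variant forcing the sets to be
disjoint is available (`disjoint=True`) but is not the default: disjoint
sets cannot both contain shared structure, so that null can never straddle
a genuinely aligned observation (two random halves of the same context land
outside it every time), and with low-rank signal the disjoint partition has
a small atom that exactly reproduces the orthogonal configuration, placing
the null's tail on the observation.  A third construction
(`method="rotation"`) draws each basis by orthonormalizing `Cov^(1/2)·G`
for Gaussian G — a variance-weighted random rotation; it agrees with the
default on every qualitative call and produces a tighter null.  Orthogonality
shows up as an observed index *below* the null, so p is the fraction of null
samples at or below the observed value.

**Joint orthogonalization.**  Over jointly orthonormal `[Q_c | Q_i]`
(N × 2d, a point on a Stiefel manifold) the pipeline maximizes

    f(Q_c, Q_i) = ½ [ Tr(Q_cᵀ·Cov_c·Q_c)/Σᵢ₌₁..d λᵢ(Cov_c)
                    + Tr(Q_iᵀ·Cov_i·Q_i)/Σᵢ₌₁..d λᵢ(Cov_i) ],

with d = 3 per context.  The normalizers are the covariances' top-d
eigenvalue sums (not data-matrix singular values), which makes the
objective's maximum exactly 1, attained when each context claims its own
top-d eigenspace without conflicting with the other's.  The optimizer is
projected-gradient ascent: Euclidean gradient `[Cov_c·Q_c/s_c,
Cov_i·Q_i/s_i]`, projection to the tangent space `G − Q·sym(QᵀG)`, QR
retraction with a positive-diagonal sign convention, backtracking line
search with doubling on success, convergence at Riemannian gradient norm
≤ 10⁻⁶ or 2000 iterations.  Six starts are used — the jointly
orthonormalized top-d PCA pair plus five seeded random frames — and the
best objective is kept, so the result can never fall below the PCA feasible
start.  Identical covariances of the form σ²I make the objective constant
(every frame captures d/d = 1 per term); the optimizer then stops at the
start with zero gradient, and the flat case is exercised in tests.  The
optimizer was verified against an exhaustive grid search over parametrized
frames on small problems (agreement to 10⁻³) and against the exact solution
on disjoint-support covariances (principal angles to the true eigenbases
below 10⁻⁴).

**Relative projection difference.**  Both context matrices are projected
onto one context's orthogonal dimensions and compared as
`100·‖P_ref − P_other‖_F/‖P_ref‖_F`: about 100% when the other context
contributes nothing to those dimensions, 0% for identical projections, 200%
for antipodal ones.  Variability comes from bootstrapping the non-reference
context's trials within each condition (1000 replicates, full-data
divisors, within-resample mean subtraction); the report carries the
bootstrap distribution, a 95% percentile interval, and a one-sided p for
the difference exceeding zero (the fraction of replicates ≤ 0) — the
reference procedure reports "bootstrap p" without defining its null, so the
package states its definition explicitly.

**Weight balance.**  To check that PCA is not simply splitting the
population into context-specific neuron groups, each neuron's summed
|weight| across the top-10 components per context gives the index
`(w_ipsi − w_contra)/(w_ipsi + w_contra) ∈ [−1, 1]`; the standardized
indices are tested against normality with a one-sample Kolmogorov–Smirnov
test.  A bimodal index distribution (KS rejection) would indicate separate
groups; neurons with zero total weight are excluded with a warning.

## Peripheral channels

EMG: 6th-order Butterworth band-pass 20–200 Hz, full-wave rectification,
6th-order low-pass at 100 Hz.  All stages are zero-phase
(forward–backward); the source procedure does not state phase handling, and
since onsets are never computed from EMG the choice only affects display
alignment.  Epoch statistics are per-trial means over the baseline and
perturbation windows with a two-way ANOVA (epoch 2 × load 8) per muscle;
when muscles are compared as a group, the muscle sample is the statistical
unit (matching the t(4) degrees of freedom such comparisons report).
Kinematics: positions are low-passed (3rd-order Butterworth, 10 Hz,
zero-phase), differentiated to speed, and integrated by trapezoid over
[0, 300] ms after the load (endpoint included so the integral spans the full
window).

## Synthetic sessions

The generator is the pipeline's ground-truth instrument.  Its construction:

- **Tuning.**  Contra preferred-load angles are drawn from an axial von
  Mises distribution (doubled-angle kappa = 2, axis 135°, matching the
  empirically observed bimodality along the shoulder-flexion/elbow-extension
  diagonal), with lognormal per-neuron gains (σ = 0.4).  The contra loading
  matrix is `W_c = [g·cosθ, g·sinθ, r]` with a random third column.
- **Subspace alignment.**  With `U_c = orth(W_c)` and `V_⊥` the
  orthogonalized loading frame of an *independently* sampled bimodal angle
  set (projected off `U_c`), the ipsi basis is
  `U_i = cos(α)·U_c + sin(α)·V_⊥` with `cos²α` equal to the requested
  alignment — every principal angle between the ground-truth subspaces is
  exactly α, while ipsi tuning stays bimodal.  Ipsi loadings are
  `W_i = U_i·K_c` with `K_c` the contra QR factor, so the ipsi rate map
  spans exactly `span(U_i)`.
- **Dynamics.**  The two planar latent channels follow a phasic-tonic
  profile: a 10 ms linear rise to a transient peak 2.5× the sustained
  plateau, decaying to the plateau with τ = 60 ms and held through the
  trial.  The sharp rise is essential for latency recovery: with a slow
  linear ramp, the 3-SD threshold-crossing delay scales with the inverse
  response amplitude, and the 2:1 contra:ipsi gain ratio would inflate the
  recovered lag well past the configured 10 ms.  The third latent channel
  carries a second-harmonic condition profile, `cos 2φ`, with a decaying
  temporal profile — a constant-across-loads channel would be erased by the
  cross-condition mean subtraction, so the second harmonic is what makes
  each context genuinely three-dimensional downstream.
- **Rates and spikes.**  Neuron rates are baseline (gamma-distributed
  around 10 Hz) plus the context's loading matrix times the latents,
  rectified at zero; contra response amplitude is 8 Hz at a preferred
  single-joint load (≈ 40 Hz/Nm median planar magnitude) and ipsi is that
  divided by the 2.0 gain ratio.  Onsets default to 25 ms (contra) and
  35 ms (ipsi).  Spikes are drawn per millisecond as an inhomogeneous
  Bernoulli approximation of a Poisson process (rates ≪ 1000 Hz, so count
  dispersion stays within a few percent of Poisson).  Ten trials per
  condition per context; the whole session is reproducible byte-for-byte
  from its config and seed.

**What the generator does not emulate** — and hence what passing tests do
not show about real recordings: spiking is Poisson and independent across
neurons (no shared trial-to-trial fluctuations, no refractoriness, no
non-Poisson dispersion), latencies are identical across neurons within a
context, temporal dynamics are a single stereotyped profile per channel
rather than heterogeneous per-neuron dynamics, there is no slow
non-stationarity across trials, and no EMG or kinematics beyond a minimal
bell-speed displacement helper for filter smoke tests.  Recovery tests
establish that the estimators are correct and calibrated under known ground
truth; they do not certify effect sizes on real data.

## Problem sizes and numerical conventions

Test and acceptance runs use sessions of 90–110 neurons with 10 trials per
condition — the scale of the recordings the pipeline targets — with
bootstrap sizes of 300–1000 chosen to keep the full suite comfortably
reproducible on a single CPU; the pipeline defaults are k = 10, d = 3, and
1000 bootstrap replicates throughout.  Other conventions: all windows are
half-open [start, end); ties in best-load selection break toward the lower
load index (logged); orthonormality is validated at 10⁻⁸ and covariance
PSD-ness at −10⁻⁸ relative; circular differences live in (−180°, 180°];
bimodal axes in [0°, 180°); preferred angles in [0°, 360°).  Every
stochastic routine takes an explicit seed, and the pipeline refuses to run
without one per stage.

## Known limitations

- Statistics that depend on per-neuron onset estimates inherit the
  amplitude-dependent threshold-crossing bias described above.
- The alignment-null construction is stated ambiguously in the literature;
  the package defaults to independent variance-weighted component draws and
  exposes the disjoint and random-rotation variants so users can check
  robustness of their conclusions across constructions.
- The reader for the published data deposit's native format is out of
  scope; sessions enter through the documented CSV layout or the simulator.
- No dPCA, jPCA, factor analysis, or cross-validated dimensionality
  selection; k and d are fixed analysis parameters.
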