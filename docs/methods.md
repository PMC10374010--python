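# Methods

`popreach` simulates attention-guided reaching in a color-oddity
(priming-of-popout) task and implements the trajectory-analysis and
model-comparison pipeline used to study inter-trial *selection history*:
the carry-over of the previous trial's target and distractor colors into
the current trial's target selection. This note records the model, the
numerical and design choices, what the synthetic data emulate, and the
known limitations.

## Task and conditions

Each trial shows one odd-colored target among three same-colored
distractors at the corners of a 13 cm square; colors come from a fixed
four-color pool (red, green, blue, purple). Relative to the previous
trial, the current target (T) and distractor (D) colors are each
*repeated* (same color, same role), *swapped* (the color reappears in the
opposite role) or *new* (absent from the previous trial), giving seven
possible conditions: TRDR, TRDN, TNDR, TSDN, TNDS, TSDS and the no-overlap
baseline TNDN. Two of the nine nominal combinations (TRDS, TSDR) are
impossible because they would force the current target and distractor to
share a color. Balanced pseudo-random sequences are built by a
quota-constrained Markov walk: the transition count of every condition is
fixed within a tolerance (default ±5 over 7×120 trials) and each next
display is drawn uniformly from the displays whose transition label still
has quota. From any display all seven labels remain reachable, so the
walk cannot dead-end. Balance is enforced per experiment, not per block.

## The simulator

The selection-and-reaching model has three coupled stages, stepped in
parallel with a common Euler step (2 ms).

**Color competition.** Four color units form a rectified recurrent
(Grossberg-style) network

    tau * du_i/dt = -u_i + b f(u_i) - d * sum_{j != i} f(u_j) + s_i + bias_i

with half-wave rectification `f`, self-excitation `b = 0.9`, mutual
inhibition `d = 0.8`, time constant `tau = 200 ms`, and additive Gaussian
noise of standard deviation `0.002 / sqrt(ms)` (the per-step increment
scales with `sqrt(dt)`, so the stochastic dynamics are insensitive to the
integration step). The drive `s_i` is the feed-forward saliency: 1.0 for
the odd color, 0.4 for the distractor color, 0.0 for absent colors, so
more salient colors integrate faster. With `b < 1` the network is
contractive: the target unit rises steadily while the distractor unit
rises, peaks near the moment the target's inhibitory output overtakes its
drive, and then decays — a temporally extended competition rather than an
instantaneous choice. A color is flagged as the *winner* when its
rectified activation crosses 1.0; the dynamics keep running afterwards,
which is what lets late history biases leak into an ongoing movement.
The parameters were chosen so that, with no noise and no history, the odd
color wins for every one of the 12 valid displays and the distractor unit
stays active for roughly the first 250 ms — the window in which selection
can bend a movement.

**Selection history.** A one-trial store holds the previous target and
distractor colors. Five variants turn the store into a bias on the color
units: facilitation only (M1, `+fac_gain` on the previous target's unit),
inhibition only (M2, `-inh_gain` on the previous distractor's unit), both
simultaneously (M3a), facilitation then inhibition (M3b), and inhibition
then facilitation (M3c). The timed variants switch at
`switch_fraction × onset_interval`, where `onset_interval` is the mean
display-onset-to-movement-onset time measured from noiseless, history-free
calibration trials (one per corner); this breaks the circularity of
defining the switch relative to a movement onset that does not yet exist.
Defaults: `fac_gain = 0.3`, `inh_gain = 0.6`, `switch_fraction = 0.65`,
variant M3c. The asymmetry (inhibition twice as strong as facilitation)
is deliberate: inhibition acts only during the pre-onset window in M3c,
while facilitation persists through the movement, and the empirical
phenomenon being modeled — the partial-swap condition TSDN outweighing
TNDS in mid-reach — requires a strong early inhibitory imprint.
Sustained inhibition of that size is not usable by the untimed variants:
at `inh_gain = 0.6` a full-trial bias makes the full-swap target's drive
fall to the distractor level and target selection fails outright. The
grid search treats such parameterizations as infinitely bad (a condition
with no valid trials cannot be compared to a reference), which is the
model-level expression of the erroneous-selection constraint that
handicaps the simultaneous variant.

**Location field.** Each present color has a feature map: Gaussian bumps
(sigma 1.3 cm) at the positions of the items carrying that color. The
maps are gated multiplicatively by the rectified color-unit outputs and
summed into the input of a 2D Amari-type neural field over the display
plane (grid step 0.625 cm, tau 60 ms, resting level -0.1, local Gaussian
excitation, global inhibition). Early in a trial all four item locations
are active; as the color competition resolves, the target's bump takes
over. Absent colors contribute exactly zero.

**Movement.** The hand starts at the bottom-center of the workspace,
20 cm below the square's center. The aim point is the population-vector
readout of the field — the activation-weighted centroid of the rectified
field output. The desired velocity points from the hand to the aim with
gain 4 s⁻¹, capped at 80 cm/s; actual velocity relaxes toward it with a
40 ms time constant. A trial ends when the hand comes within 1.5 cm of
any item (arrival at a non-target item is an error) or at the 1500 ms cap
(unresolved). The argmax "peak" readout specified by the field type is
retained as a config option (`aim="peak"`), but it is not the default:
with a single winner-take-all aim point, trajectories are either straight
or fully captured by a distractor, and no graded attraction exists. The
centroid readout is the standard way motor dynamic-field models convert a
distributed decision into a continuous movement command, and it is what
produces the leakage of unresolved competition into curvature.

**Movement initiation** is time-locked to the calibrated neutral onset
time (provided the field has a defined readout), not to the field
threshold alone. The behavioral motivation: reach initiation latency is
empirically constant across inter-trial conditions. The computational
motivation is sharper: with a pure threshold rule, a history bias that
merely slows target selection delays movement onset by the same amount,
so the field state *at onset* — and therefore the trajectory — is
unchanged, and conditions that act on the current target's unit (TSDN,
TSDS) produce no attraction at all. Time-locking the onset turns a
slowed selection into a less-resolved field at movement start, which is
the observable the attraction score measures.

## Trajectory analysis

Resultant hand speed is computed by numerical differentiation and
filtered with a zero-phase (forward-backward) second-order Butterworth
low-pass at 10 Hz. Movement onset is the first crossing of 15 cm/s that
*stays* above threshold for at least 50 ms — the hold-time rejects
filter edge transients on noisy stationary data and stands in for
per-trial visual inspection; offset is the first subsequent drop below
15 cm/s. Per-trial manual overrides take precedence. The onset-offset
segment is resampled at 100 equal increments of cumulative path length
(monotone piecewise-cubic interpolation of each coordinate against arc
length).

Deviations are computed against the participant's corner-matched mean
TNDN trajectory and signed so that deviation toward the distractors is
positive on each axis (for a top-left target, rightward and downward are
positive). The combined attraction score is the Euclidean magnitude of
the (dx, dy) deviation carrying the sign of whichever axis deviates more;
exact ties go to the horizontal axis. Condition-level profiles combine
the across-trial *mean* deviations, which makes every participant's TNDN
profile identically zero — the baseline is a definition, not an effect.
Trials flagged as incorrect, unresolved, with no detectable movement,
with a zero-length path, or with more than 10% missing samples are
excluded.

## Cluster-based permutation test

Attraction scores are tested pointwise (one-sample or paired t) at each
of the 100 distances; maximal same-signed runs of |t| above the two-sided
critical value at df = n−1 form clusters whose mass is the sum of t
values. Cluster significance is the add-one-smoothed fraction of
permutations whose maximum absolute cluster mass reaches the observed
mass. Two permutation schemes are implemented. The default flips the
sign of whole participants' score profiles and recomputes the t series;
it is exact under per-participant symmetry of the null regardless of
correlation across distances. The alternative (`scheme="order"`)
permutes the order of the observed t values, as sometimes described for
this family of tests; it is valid only if the t series is exchangeable
across distances. Real attraction profiles are smooth across distances
(adjacent points share trajectory samples and segment-registration
error), and on null synthetic data the order scheme's family-wise false
positive rate is several times the nominal level while the sign-flip
scheme calibrates at alpha — which is why sign-flip is the default. A
side effect worth knowing: under the order scheme a *uniformly*
supra-threshold t series can never be significant, because every
reordering has the same cluster mass. The default `n_perm` is 100,000;
the calibration experiments and tests use 2,000 for runtime, which is
ample for p ≈ 0.05 decisions.

## Principal component regression

At every distance in 11–90% a PCA is run on the participants × 4 matrix
of partial-condition scores (TRDN, TNDR, TSDN, TNDS; columns centered).
Three post-processing steps make per-distance components interpretable as
smooth functions of distance:

1. **Tracking.** Components are matched to the previous distance's
   components by absolute loading similarity before anything else. The
   variance ranking of two latent factors can cross mid-reach; without
   tracking, one "component" would splice together different factors.
2. **Sign alignment.** Sweeping distances in order, a component's sign is
   flipped when the angle between consecutive loading vectors exceeds
   120° (dot product below −0.5 on unit-norm loadings).
3. **Orientation.** After the no-intercept regression of the pop-out
   effect (attraction TSDS − TRDR per participant) on the component
   scores, each component is globally oriented so its average regression
   coefficient is positive.

Because eigenvectors are genuinely rotating where two factors have
near-equal variance, tracking cannot always preserve identity, so factor
*interpretation* does not rely on it: a condition is reported as loading
on a component when, within distances where that component's regression
coefficient is significant, the product of its loading and the local
coefficient sign exceeds 0.35 in magnitude for at least 15% of
consecutive distances (12 points of the 80-point range). This reads the
loadings in the frame where the local coefficient is positive, which is
how such loadings are conventionally presented. The regression reports
the through-origin (uncentered) R²; per-component partial coefficients
and p values are kept per distance. Collinear score columns are dropped
from a distance's fit rather than inverted.

## Model fitting

Goodness of fit is the root-mean-square difference between simulated and
reference mean attraction profiles over the six non-baseline conditions
and all 100 distances, in centimeters. The grid search sweeps each
variant's free parameters (defaults: fac 0.15/0.30, inh 0.30/0.60, switch
0.40/0.65) with a common seed ladder across grid points and variants, so
comparisons differ only through the parameters. Per-repetition errors
(each repetition's profiles against the reference mean) are kept for
paired uncertainty. Five-way comparison fits all variants and ranks by
error. Simulated experiments use 21 repetitions per condition with
target corners cycled deterministically so every corner contributes to
the TNDN baseline.

## Synthetic data

The generator emulates multi-participant reach datasets: straight
start-to-corner paths with a minimum-jerk speed profile (600 ms movement,
150 ms stationary lead-in, 240 Hz sampling), lateral deviations shaped as
Gaussian bumps over path fraction (positive toward the distractors), and
0.03 cm per-sample position noise (the measuring error of a typical
electromagnetic tracker). Bumps belong to named latent factors; each
participant draws one multiplicative scale per factor, shared across the
conditions loading on it — this between-participant covariance is what
group statistics and the PCR operate on. The two-factor plant gives the
prior-distractor conditions (TSDN +, TNDR −) an early factor (bump at
30% of the path) and the prior-target conditions (TNDS +, TRDN −) a late
factor (bump at 60%), with the full conditions carrying both, so the
pop-out contrast is driven by exactly the factors the partial conditions
expose. Its default between-participant scale SD is 1.0 (deliberately
heterogeneous): with a no-intercept regression on centered scores the
component t statistic scales with sqrt(n) × (scale SD / scale mean), so
weak heterogeneity makes even a perfectly planted factor undetectable at
n = 21. Null datasets plant nothing and are exchangeable across
conditions.

What the synthetic data do *not* emulate: reaction-time distributions,
within-trial feedback corrections, truly curved (non-lateral-bump)
deviation shapes, trial-order effects beyond lag 1, or realistic missing
data. Passing tests on these data show that the pipeline recovers what
was planted under its own assumptions; they are not evidence about human
reach data.

## Problem sizes and determinism

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); per-trial streams are derived from
`(seed, condition, repetition)` so runs are reproducible and
parallelizable. The shipped calibration and recovery experiments use
desk-scale sizes chosen as a compromise between statistical resolution
and turnaround: 21 repetitions per condition for simulations (matching
the experiment's participant count), 500 null datasets at 2,000
permutations for the type-I calibration, and the 2×2×2 default grid for
model comparison. The acceptance script reruns the same computations at
300 null datasets.

## Known limitations

- The competition net, field and movement rule are a deliberately small
  reconstruction: no motor-field dynamics, no 3D kinematics, no reaction
  time model. Absolute attraction magnitudes (≈0.1–2 cm) are in the
  plausible range but are not fitted to human data, which are not
  distributed with the package.
- The grid search is a coarse grid, not an optimizer; it is meant for
  model *comparison* under common random numbers, not for precise
  parameter estimation.
- With strong autocorrelation across distances the order-permutation
  cluster scheme is unreliable (see above); it is kept only for
  comparability with descriptions of that procedure.
- History is strictly one trial back; longer-lag and reward-based
  history are out of scope.
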