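# Methods

This note documents the models, algorithms, parameter choices and known
limitations of every stage, in the order data flows through the package.

## Trial model and interchange format

A trial is one continuous capture of 3-D marker trajectories (mm, nominally
250 Hz), 13 named surface-EMG channels (ME, MA, FL, RF, VM, VL, ST, BF, TA,
PL, GM, GL, SO) and a triaxial ground-reaction force (N), the latter two on
a shared analog timebase (nominally 1 kHz). Interchange is a single wide
TSV/CSV with a kinematic column block and an analog column block (the
shorter NaN-padded), metadata in `# key: value` header comments, UTF-8 and
`.` decimals. A YAML schema can rename user columns to canonical names.
Marker gaps are stored as NaN and linearly interpolated up to a
configurable maximum run (default 10 samples) before any differentiation;
longer gaps are a hard error for derivative-consuming stages, because
numerical differentiation amplifies interpolation artifacts. All event
indices are stored on the analog timebase; kinematic indices are converted
by the rate ratio with round-half-up.

## Cycle segmentation

**Touchdown** is the first GRF sample whose Euclidean norm exceeds a
threshold — 0 N by default, appropriate for synthetic plates that are
exactly zero when unloaded; ~10 N is a sensible choice for real plates,
which never read exactly zero.

**Lift-off** uses the foot acceleration-and-jerk rule. The fifth-metatarsal
vertical trace is low-pass filtered (zero-phase 4th-order Butterworth,
50 Hz), acceleration and jerk are obtained as second and third central
differences, the lift-off estimate LOe is the global acceleration maximum
in the 800 ms window before touchdown, and the returned event is the jerk
zero-crossing marking a local acceleration minimum inside (LOe − 50 ms,
LOe + 200 ms). "Jerk equals zero" is operationalized as a − to + sign
change between adjacent samples, taking the adjacent sample with the
smaller |jerk|; with several candidates the one nearest LOe wins, ties
toward the earlier sample. If no candidate exists the detector falls back
to LOe with a logged warning.

**Steady state** ends the cycle. After maximum knee flexion (global
maximum of the flexion trace; plateaus break to the earliest sample) the
flexion slope series is segmented by divisive energy-statistic
change-point detection and the first segment whose mean slope does not
significantly differ from zero (one-sample sign-flip permutation test)
starts the steady state. The E-divisive estimator recursively bisects at
the split maximizing the scaled energy statistic
Q(τ) = n₁n₂/(n₁+n₂) · [2B/(n₁n₂) − ΣW₁/(n₁(n₁−1)/2)/2 − …] computed in
O(1) per split from pairwise-distance prefix sums; each split must survive
a within-segment permutation test. Defaults: energy-distance exponent
α = 1, 199 permutations, significance 0.05, minimum segment 30 points.
These internals are surfaced in `EventDetectionConfig`, not hard-coded,
because no single canonical parameterization exists for this detector; the
implementation is property-tested against a literal O(n³) energy scan.
An entirely flat trace yields the trace start; a trace that never settles
raises `NoSteadyStateError`, mirroring the protocol rule that such an
attempt is invalid and repeated.

Multi-repetition recordings are split into GRF loading episodes (unloaded
gaps ≥ 100 ms separate repetitions); each episode is segmented
independently and per-episode failures are logged, not fatal.

## EMG processing

Envelopes: zero-phase 4th-order Butterworth high-pass at 50 Hz, full-wave
rectification, zero-phase 4th-order low-pass at 20 Hz, clipped at zero
(the zero-phase low-pass can undershoot slightly). "4th order" is the
per-pass order; forward-backward application doubles the effective
attenuation, matching common practice in this literature. The envelope
operator is positively homogeneous, which the amplitude normalizations
rely on.

Two normalizations exist. *Per-direction-max* (for envelope and
coactivation comparisons) divides each muscle by its maximum over all of a
participant's trials of one direction, with no minimum subtraction, making
the output invariant to common input rescaling. *Synergy* normalization
(for factorization) scales each muscle to span exactly [0, 1] over the
trial. The underlying prescription — divide by the trial maximum, then
subtract the minimum activity so signals range between zero and unity —
only produces both unit maximum and zero minimum if the result is
renormalized after the subtraction; the two operations then collapse to
per-muscle min–max scaling, which is what the package implements. Dead
channels (zero maximum) are an error naming the muscle; constant channels
become all-zero rows with a warning.

Coactivation indices are pointwise antagonist/agonist ratios of
per-direction-normalized envelopes: hip (FL+RF)/2 ÷ (ME+MA)/2, knee
(BF+ST)/2 ÷ (RF+VM+VL)/3, ankle TA ÷ (GM+GL+SO)/3. Zero-agonist points
propagate as NaN, never as zero, so averages are not biased downward.

Each cycle is time-normalized to 200 points by linear interpolation — 50
points for the swing [lift-off, touchdown), 150 for the stance
[touchdown, steady-state end] — and cycles are concatenated. Touchdown
always maps to the 50/150 boundary. Averages over repetitions are
pointwise means over the normalized cycles after dropping the first and
last repetition and keeping up to the central 50.

## Synergy extraction

Gaussian NMF with multiplicative updates (H first, then W), ε = 10⁻¹²
added to denominators. Convergence: relative change of R² over a
20-iteration window below 0.01%; iteration cap 10⁴ with a warning. Ten
restarts per rank from uniform-random initials, seeded as master seed +
restart index; the highest-R² solution is kept. Model order: ranks
1..round(0.75 m) (10 for 13 muscles); a straight line is fitted to the
R²-vs-rank points and the lowest-rank point dropped until the fit MSE is
below 10⁻⁵ or two points remain; the chosen rank is the smallest remaining
— so a perfectly linear curve yields rank 1, and exhaustion yields the
lower of the final two. Before metric computation each primitive row is
scaled to unit maximum with the scale folded into W (fixing the scale
indeterminacy of NMF without changing the reconstruction).

CoA is computed on the circularized cycle and reported in normalized
points [0, 200); a numerically zero resultant (uniform primitive) is an
error. FWHM counts points strictly above half of the minimum-subtracted
maximum; it is computed on the mean primitive by default (per-block means
for the early/late analysis). Classification unit-normalizes mean-cycle
primitives, clusters them agglomeratively (cosine distance, average
linkage, distance threshold 1 − 0.80), and labels clusters of at least two
members whose medoid has a single peak (one smoothed local maximum above
half maximum) as fundamental, ordered by ascending CoA into swing,
touchdown, weight acceptance and stabilization; everything else —
unclustered primitives and multi-peaked cluster shapes — is combined, and
no CoA/FWHM is reported for combined synergies. The similarity threshold,
linkage and minimum cluster size are configurable: the clustering is a
design choice of this package, not a canonical algorithm. Overlap analysis
binarizes each fundamental primitive at half maximum (consistent with
FWHM) and counts, per time point, the number of simultaneously active
primitives minus one, floored at zero, averaged across trials.

## Kinematics and inverse dynamics

The limb is a planar three-segment chain (foot, shank, thigh) in the
sagittal x–z plane (x anterior, z up); joint centers sit at the lateral
malleolus, lateral femoral epicondyle and greater trochanter. Angle
conventions: knee = inter-segment angle at the epicondyle (180° = full
extension); ankle = angle between the shank axis and the
calcaneus→fifth-metatarsal foot axis (90° = neutral); hip = thigh
inclination from the downward vertical (positive anterior). These are
fixed, documented conventions — no claim is made that they reproduce any
particular lab's anatomical-zero offsets.

Moments come from a bottom-up Newton–Euler recursion: the GRF acts at the
center of pressure (from the force plate when available; otherwise a
configurable ground point under the fifth metatarsal), segment weights act
at the CoM, CoM accelerations and segment angular accelerations come from
zero-phase low-pass filtered (50 Hz) marker data differentiated by central
differences, and inertial parameters are Winter's anthropometric fractions
(shipped as an editable table: mass fractions 0.0145/0.0465/0.100 of body
mass, CoM at 0.50/0.433/0.433 and gyration radii 0.475/0.302/0.323 of
segment length for foot/shank/thigh). Reported signs: ankle
plantarflexion, knee extension and hip extension positive. The planar
simplification is deliberate: only sagittal-plane moments are in scope.
In the static limit the recursion reduces exactly to force × lever
equilibrium, which an independent oracle verifies to float tolerance; a
single-segment pendulum recovers the analytic torque within 1% RMS.

## Synthetic data: what it emulates, and what it does not

The generator produces the only data the package is validated on, so its
scope matters. EMG envelopes are V = clip₀(W·H + ε) with Gaussian-bump
primitives through a known module matrix; noise is additive Gaussian
truncated at zero (clipping keeps V non-negative and the factorization
assumptions clean) and cycle-to-cycle variability is jitter of primitive
centers (sd 2 points) and amplitudes (5%). Defaults define the reference
study conditions: four synergies centered at 25/60/85/120 points with
σ = 6, 25 cycles, noise sd 0.05. The published protocol this emulates
reports no per-cycle variability statistics, so the jitter magnitudes are
engineering choices fixed once, not estimates. Kinematic streams are
likewise constructed signals: a GRF that is exactly zero before a known
contact time and loads over ~20 ms, a metatarsal height whose designed
acceleration places the global maximum 40 ms before a jerk-zero minimum at
the known lift-off, and a knee angle that rises to maximum flexion and
settles linearly onto an exact plateau at the known steady-state time.
Raw EMG for full-trial tests is band-limited noise amplitude-modulated by
the primitive mixture mapped onto real time.

Passing tests therefore demonstrate correct implementation of the stated
algorithms and recoverability of planted structure — not robustness to
real-data phenomena the generator omits: motion artifact and crosstalk in
EMG, soft-tissue marker wobble, force-plate drift, non-Gaussian primitive
shapes, correlated noise across muscles, or 3-D kinematics. The generator
makes no attempt at forward-dynamic consistency between its streams
(markers, GRF and EMG are constructed independently).

Problem sizes in the test suite and acceptance script (25-cycle envelope
matrices, 3-repetition trials, 200-point change-point series) are chosen
to exercise every code path at desk scale; all quantities they report are
computed at run time from freshly generated data.

## Reproducibility and numerical choices

Every stochastic component (generator, NMF restarts, permutation tests) is
driven by explicit integer seeds; identical (spec, seed) pairs are
bit-identical, and the pipeline is deterministic end to end under a fixed
`RunConfig.seed`. Tie-breaks are fixed and documented (earliest sample for
flexion plateaus and jerk candidates, smallest remaining rank, lowest rank
dropped first). Degenerate inputs fail loudly: all-zero muscle rows,
zero-variance matrices, uniform primitives, constant primitives, missing
CoP under load, zero-length segments.

## Known limitations

- Frontal/transverse-plane kinetics, trunk and contralateral limb are out
  of scope by design.
- Group-level inferential statistics (statistical parametric mapping,
  repeated-measures ANOVA, post-hoc corrections) are deliberately
  excluded; summary tables are descriptive only.
- C3D ingestion is not implemented; the tabular dialect is the sole
  interchange format.
- The shape-clustering classifier is a configurable stand-in for a family
  of unsupervised classifiers used in this literature whose exact
  internals vary between labs; results depend on the similarity threshold
  (default cosine 0.80).
- The per-direction maximum is taken over the trials supplied in one call;
  cross-session normalization is the caller's responsibility.
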