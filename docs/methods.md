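# Methods

`felanding` implements a complete analysis chain for quadruped (cat) forelimb
landing biomechanics: synthetic trial generation, signal conditioning, planar
three-link inverse dynamics, principal-waveform reconstruction, deep-network
classification of adjacent drop heights, and layer-wise relevance propagation
(LRP) to attribute the classification to individual joints. This note records
the models, the parameter choices that matter, and the places where a design
was genuinely open.

## The synthetic cohort

No public recording of the landing cohort this analysis targets exists, so
the generator is a first-class module: it produces trials with the structure
the downstream stages assume, plus a *planted ground truth* that lets the
attribution pipeline be tested end to end.

**Structure.** By default 56 cats x 10 trials x 4 drop heights (60, 80, 100,
120 cm) at 1,000 Hz; body mass is drawn from N(4.32, 0.53²) kg. Each trial
carries three GRF channels (medial/lateral, anterior/posterior, vertical) and
four sagittal angle traces: the carpal-link pitch α1, the forearm and arm
segment angles α2, α3, and the shoulder joint angle α4. Segment lengths are
drawn per cat around 0.05 / 0.10 / 0.11 m (carpal link, forearm, arm) with 6%
relative spread — no published lengths exist for this cohort, so these are
order-of-magnitude anatomical defaults.

**Waveform family.** The vertical GRF is a pair of smooth bumps (impact peak
plus a broader second peak) gated by a contact ramp; the peak scales as body
weight times (1.4 + 2.2·√h), reflecting impact speed ∝ √height. The
anterior/posterior channel carries a braking-then-propulsive shape, the
medial/lateral channel a small bump with a per-cat sign. Angle curves are
logistic flexion ramps completing at the end of the landing phase, followed
by a short re-extension tail so maximum elbow flexion is an interior event of
the recording (the landing *phase* still ends exactly there). Landing-phase
duration is drawn per trial from 120–250 ms so time normalization is
exercised on unequal lengths; with the 6 Hz angle filter this range keeps the
flexion content inside the analysis band. (During development we found that
letting ramps end at the final sample, or letting their spectral content
reach the filter cutoff, makes the filtered excursion amplitude a strong
function of trial duration — a shared nuisance factor that corrupts both
classification and attribution; the post-flexion tail and the duration floor
remove it.)

**Variability.** Cat level: a multiplicative GRF scale (sd 8%), additive
angle offsets (sd 2°) and per-cat segment lengths. Trial level: a GRF scale
(sd 5%) and low-pass-filtered white noise on every channel (2 N on forces,
0.8° on angles). Angle curves are built in *joint space* — the carpal pitch
and the wrist/elbow/shoulder joint angles each get independent offsets and
noise, and the segment chain (α2, α3) is derived from them. Building the
curves segment-first instead couples the joint-angle channels through shared
segment noise, which a trained classifier exploits as suppressor variables
and which then pollutes the relevance attribution; the joint-space
construction keeps each joint's angle block statistically independent.

**The planted effect.** An effect profile maps each adjacent height pair to
(wrist, elbow, shoulder) weights summing to 1 — by default (0.6, 0.3, 0.1)
for 60→80 cm, uniform for 80→100 cm, and (0.1, 0.3, 0.6) for 100→120 cm,
encoding a distal-to-proximal shift of the discriminating joint as height
grows. Climbing one rung of the height ladder multiplies the weighted
joints' flexion excursions by (1 + 0.5·weight); the scale 0.5 is chosen so
that adjacent-height separability sits in the 90–96% classification regime
the analysis is designed around. The wrist share also drives the carpal
pitch (hence the wrist moment) and part of the shoulder share drives an arm
segment rotation (hence the shoulder moment), so both kinematic and kinetic
trajectories carry signal. `planted_truth()` returns the injected weights
per pair for recovery tests.

## Signal conditioning

Contact is the first sample where the vertical GRF strictly exceeds 10 N
(a tie at exactly 10 N does not trigger). GRF channels are filtered with a
fourth-order zero-phase (forward–backward) Butterworth low-pass at 50 Hz,
angles at 6 Hz; reflection padding of 3x the filter order suppresses edge
transients, and the effective magnitude response is the squared single-pass
response. Maximum elbow flexion is the global minimum of the filtered elbow
joint angle, with ties resolved to the earliest index after contact (a
relative tolerance of 1e-6 of the trace range absorbs float-level filter
ripple); if the extremum falls at or before contact the phase is degenerate
and an error is raised. Wherever two criteria for the phase end could be
argued, maximum elbow flexion governs — it is the event every downstream
stage (normalization, endpoint extraction) is anchored to.

Every curve is resampled to 100 points by piecewise-linear interpolation on
the uniform phase grid 0, 1/99, …, 1; endpoints are preserved exactly. Six
100-point blocks per trial — wrist/elbow/shoulder angle then
wrist/elbow/shoulder moment, in that fixed order — form one 600-column row;
560 trials per height give the canonical 560 x 600 matrices, and two adjacent
heights stack into a labeled 1,120 x 600 pair with the *lower* height as the
positive class.

Joint angles derive from segment angles as wrist = 180° − (α2 − α1),
elbow = 180° + (α2 − α3), shoulder = α4, so flexion reads as a decreasing
angle and "maximum elbow flexion" is a minimum.

## Inverse dynamics

The forelimb is a chain of three rigid links pinned at the contact point:
segment 1 is the distal carpal link receiving the ground force, segment 2 the
forearm, segment 3 the arm. This distal-first numbering is forced by the
mechanics — the recursion applies the measured GRF to segment 1 and walks
proximally — even though descriptions of such models sometimes label the arm
"segment 1". Masses are 0.30 / 1.30 / 2.37% of body mass and COM inertias
7.51 / 233.34 / 391.81 g·cm² (converted to SI) for carpal link / forearm /
arm; the COM sits at the segment midpoint (the fraction is configurable for
sensitivity studies); g = 9.81 m/s² exactly.

Per segment, the pinned-chain COM acceleration expansion in (α, α̇, α̈) gives
the proximal reaction forces, and the moment balance about the COM gives the
proximal joint moment (see the module docstring for the explicit equations).
The sign pattern of the centripetal/tangential terms and of the −I·α̈ term is
uniform across all three segments — the segment-3 equations follow the same
pattern as segments 1 and 2, which is the only form consistent with the
free-body mechanics of a pinned chain (an independent oracle that
differentiates the chain's COM positions numerically agrees to ~1e-9
relative; transcriptions of these equations elsewhere contain two sign slips
in the third segment that would break that equivalence). Angular derivatives
are central finite differences with second-order one-sided boundary stencils
(exact for polynomials of degree ≤ 2 at interior points). Angles are degrees
at every I/O boundary and radians internally, converted once at load.

The expansions presuppose a stationary contact point during the landing
phase; the oracle equivalence is asserted only in that regime.

## Principal waveforms

For one height and one variable the trials form a 100 x 560 matrix with
phase points as observations and trials as variables (a transposed-
convention flag exists for comparison studies). Columns are z-scored with the
sample standard deviation (n−1 divisor; recorded in the output metadata since
either convention is defensible). The covariance eigen-decomposition yields
eigenvalues λ1 ≥ … ≥ λp ≥ 0 (clipped at zero against round-off), orthonormal
eigenvectors with the sign fixed so the largest-magnitude loading is
positive, scores, and the cumulative contribution G(m) = Σᵢ≤m λᵢ / Σ λ. The
retained count is the smallest m with G(m) ≥ 0.90; on generated cohorts the
first component alone typically clears 95%, and a diagnostic flag records
the m = 1 case. Reconstruction multiplies the retained scores by the
transposed coefficient matrix and de-standardizes (× sd, + mean); with all
components retained this is the identity to ~1e-9.

The 560-column reconstruction is collapsed to one representative curve by the
column-wise mean (median available) — the collapse is not dictated by
anything upstream, so it is configurable and recorded. The endpoint is the
representative value at the 100th phase point, i.e. at maximum elbow flexion;
the per-height, per-variable endpoint table is the terminal product of this
branch (the downstream finite-element stress analysis is out of scope).

## Classifier

A fully connected feed-forward network, reference size 600 input – 10 hidden
layers of 1,200 tanh units – 2 output nodes (≈13.7 M weights; the shape audit
instantiates it, training runs use a 600–64–64–2 variant of the same code
path). Inputs are standardized per column with training-set statistics —
depth-10 tanh stacks are untrainable otherwise — and weights start
Xavier-uniform with a recorded seed; both are stored with the network.

Training specifics nothing upstream fixes, chosen as standard practice and
recorded here: softmax cross-entropy on the two output nodes (compatible with
LRP, which decomposes the pre-softmax score), mini-batch SGD with momentum
0.9, learning rate 0.01, batch size 25, epoch limit 3,000 (scaled-down runs
use 300), no early stopping by default (a patience option exists), L2 weight
decay 1e-3 and Gaussian jitter (sd 0.3) on the standardized training inputs.
The last two matter at desk scale: without them the over-parameterized net
memorizes trial-level noise, which both costs held-out accuracy and smears
the relevance attribution across uninformative blocks. The 80/20 split is a
pure function of its seed; if a class is missing on either side the split is
re-drawn with an advanced seed (warned). Trial-level splitting means a cat
can appear on both sides; a group-aware split is a one-line change on
`split_dataset` for users who need cat-disjoint evaluation. Ties at equal
output scores resolve to the lower class index.

## Layer-wise relevance propagation

Relevance starts at the predicted class's pre-softmax score and is
redistributed with the z-rule, R_{i←j} = (z_ij / z_j)·R_j with z_ij = u_i
w_ij. The denominator is stabilized as z_j + ε·sign(z_j) with ε = 1e-9
relative to the layer's pre-activation scale (configurable); bias relevance
is absorbed by default — each layer keeps the (1 − b_j/z_j) share — with an
optional mode redistributing the absorbed share equally over the layer's
inputs. For bias-free networks the layer totals are conserved to stabilizer
tolerance, and a single linear layer decomposes exactly into its
pre-activations; both are asserted in the acceptance suite.

Aggregation takes the mean absolute relevance over all correctly classified
trials of the pair dataset (more trials give a stabler map than the held-out
subset alone) and normalizes to the maximum. Smoothing applies three passes
of the (0.25, 0.50, 0.25) kernel *within* each 100-point trajectory block —
smoothing across block boundaries would mix joints — with the missing
neighbour's weight folded into the centre at block edges, so each pass
preserves block totals exactly and leaves constant blocks untouched. The
smoothed vector is min-max rescaled to [0, 1] and the top-100 variables are
selected on it (ties to the lower index); ranking on the raw aggregated
scores is available as the alternative. Per-trajectory contributions are
block sums over the rescaled vector as percentages of its total, and joint
totals add each joint's angle and moment shares.

## Pipeline and reproducibility

`run_pipeline` executes both branches from one config; a single global seed
derives the generator, initialization and shuffle seeds, and the manifest
records a SHA-256 hash of every numeric artifact, so identical configs
reproduce byte-identical numbers. All intermediate artifacts (trial CSVs,
height matrices, endpoint tables, network bundles, relevance tables) are
plain CSV/JSON and re-validated on load.

## Problem sizes in the test and acceptance suites

The classifier-metric and joint-contribution recomputations are closed-form
and run on the published count tables directly. The property checks run at
desk scale: the inverse-dynamics oracle on 0.3 s of 10 kHz analytic
trajectories, the PCA suite on random matrices up to 50 x 20, LRP
conservation on 100 random bias-free nets, and the planted-effect recovery
on cohorts of 20 cats x 5 trials x 4 heights with the 600–64–64–2 network
trained 300 epochs, repeated over five seeds — sizes chosen so the whole
suite stays desk-scale while every stochastic band (accuracy ≥ 0.90,
correct joint ranking in ≥ 4 of 5 seeds) is meaningfully testable.

## What passing tests do and do not show

The generator produces smooth, unimodal, height-graded trials with
independent joint-level variability and a *known* discriminative structure.
Real landings add things it does not model: hind-limb and out-of-sagittal
forces, marker-tracking error with non-stationary spectra, correlated
fatigue effects across a session, cats that refuse the task. Passing the
recovery checks therefore shows the *pipeline* is sound — that when a
distal-to-proximal shift exists, this chain of filtering, dynamics, training
and attribution finds it — not that any particular real cohort contains such
a shift. The exact-surface checks (metric and contribution recomputation)
are unconditional arithmetic and carry no such caveat.

## Known limitations

- Sagittal plane only; three joints; no muscle or tendon forces; no digit
  joints.
- The inverse-dynamics expansions assume the contact point is stationary
  during the phase.
- The single-point AUC is balanced accuracy, not a swept ROC area (the swept
  curve and trapezoidal area are provided separately and labeled as such).
- LRP is the plain z-rule; no α/β-rule variants, gradients or SHAP.
- The trained reference-size network on real data is not reproducible here;
  its scaled-down counterpart on synthetic cohorts is the tested regime.
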