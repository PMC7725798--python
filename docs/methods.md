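# Methods

This note documents the models, the numerical choices, and what the
synthetic study conditions do and do not establish.

## Signal processing

Kinematic/kinetic series and EMG envelopes use fourth-order zero-phase
Butterworth filtering (forward–backward `sosfiltfilt`).  "Fourth-order
zero-phase" is read as a 4th-order *design* applied forward–backward
(effective 8th-order magnitude); a config option (`convention="effective"`)
selects the alternative reading (2nd-order design applied twice).  Low-pass
cut-offs scale with the gait-cycle period: 7/t_f Hz for motion data (≈6 Hz
at ordinary cycle periods) and 3.5/t_f Hz for EMG envelopes.  The EMG
pipeline is, in order: 40 Hz high-pass, demean, full-wave rectify, variable
low-pass, clip at zero (envelope ringing below zero is nonphysical).
Edge handling pads by odd reflection sized to ten cutoff periods, which
keeps the forward–backward pass reversal-symmetric to ~1e-12; per-muscle
envelopes are normalized to each muscle's maximum over all trials.

## Muscle-tendon model

Each actuator is a Hill-type muscle with a **rigid tendon**: fiber length
and velocity follow algebraically from muscle-tendon length at constant
muscle thickness `l_opt·sin(α₀)`.  The rigid tendon makes tendon force
affine in activation at fixed kinematics, which turns per-frame static
optimization into an exact box-constrained quadratic program and makes
calibration residuals cheap; tendon compliance is deliberately out of
scope (at hemiparetic walking speeds series-elastic effects are modest,
and none of the package's contracts depend on them).

Curves (coefficients in `CurveCoefficients`, all dimensionless):
active force-length is a Gaussian bell of width 0.45 about `l_opt`;
passive force is exponential with onset at `l_opt`, reaching 1·F_iso at
normalized length 1.7; force-velocity is a Hill hyperbola (shape 0.25) on
the shortening side, with a C1-continuous eccentric branch saturating at
1.4·F_iso.

The EMG-to-activation chain per muscle: cyclic time shift by the
electromechanical delay (fractional samples linearly interpolated) and
multiplicative EMG scale; first-order activation dynamics with
deactivation 4× slower than activation (ratio fixed; backward Euler at the
trial rate, cycle iterated twice so the initial condition is periodic);
optional exponential non-linearization `a = (e^{Aã}−1)/(e^A−1)` fixed at
the endpoints.

Parameter bounds (enforced at construction): delay ∈ [0, 0.1] s, activation
time constant ∈ [0.01, 0.1] s, shape factor ∈ [0, 3], EMG scale ∈ (0, 1.5],
optimal-fiber-length and tendon-slack-length calibration multipliers ∈
[0.75, 1.25], pennation ∈ [0, 0.6] rad, v_max default 10 l_opt/s.

## Surrogate geometry

Muscle-tendon length is a multivariate polynomial in the spanned joint
angles; the moment arm about DOF j is **identically** −∂l/∂q_j (shared
coefficients — lengths and moment arms are fit simultaneously in one
stacked least-squares solve, so derivative consistency is exact by
construction rather than approximate).  Sign convention: a muscle that
shortens as an angle increases has a positive moment arm about that angle.
Muscle-tendon velocity is the chain-rule total derivative Σ_j (∂l/∂q_j)q̇_j.
Joint workspaces are sampled by Latin hypercube (scipy's
`qmc.LatinHypercube`, one sample per equal-width stratum per DOF; default
500 samples when sampling externally supplied geometry).  Default fitting
degree is 4 with cross-terms; the sample count must give ≥10 equations per
coefficient.  Length and moment-arm rows are weighted equally (exposed as
`momentarm_weight`).

## Static optimization

Per frame: minimize Σaᵢ² + w_r Σr_j² subject to moment balance including
passive muscle forces, 0 ≤ a ≤ 1, with per-DOF reserve moments r_j
(default weight 1000) guaranteeing feasibility when demanded moments
exceed muscle capacity.  Eliminating the reserves reduces the QP to a
bound-constrained linear least-squares problem solved exactly by BVLS
(`scipy.optimize.lsq_linear`, tol 1e-14); tests verify agreement with a
dense active-set enumeration oracle on small instances.  Passive forces
enter the constraint but not the objective.

## Calibration

Bound-constrained nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective, numerical Jacobian, `x_scale="jac"`).  The cost is
the sum of squared joint-moment residuals over all calibration trials and
DOFs, plus an optional passive-moment term against reference angle–moment
curves, plus quadratic penalties on deviation of each design variable from
its initial value (default weight 1.0, exposed per class).  Design
variables are dimensionless: multiplicative parameters (time constant, EMG
scale, l_opt, l_ts) as multipliers of their initial values; parameters
whose initial value may be zero (delay, shape factor) as absolute values
divided by a fixed class scale.  On noiseless synthetic data the truth
parameters are recovered to ≈1e-10 relative; iteration cap 100–200 solves
the shipped problem sizes in seconds.

## Energetics models

Coefficients are transcribed from the three cited publications into YAML
configs (`data/metabolic_constants/`), never hard-coded; the test suite
cross-checks them against a second, independently written transcription.
Muscle mass is `ρ·(F_max/σ)·l_opt` with density 1059.7 kg/m³ and specific
tension σ = 0.25 MPa (configurable — CoT magnitudes are sensitive to σ).
Sign conventions that distinguish the models: B04's shortening/lengthening
heat is −α·v (negative during lengthening), and its work rate includes
eccentric work; U03/U10 assign positive lengthening heat; U10 additionally
clamps the work rate at zero (concentric only).  In the Umberger models
activation and maintenance heat form a single combined term, reported
under `maintenance_heat_rate` with `activation_heat_rate` zero so that
component additivity stays exact.  Per-muscle totals are **not** clamped at
zero by default (B04 can go negative during strong eccentric phases; a
clamp flag exists for parity studies).  Whole-body rate sums all modeled
muscles plus a toggleable basal term (1.2 W/kg × body mass, on by
default).  CoT integrates the whole-body rate trapezoidally over the
101-sample cycle.  Where the pipeline computes activations by static
optimization, excitation is taken equal to activation in the energetics
inputs (no EMG is available on that path).

## Synthetic study conditions

The default synthetic leg is sagittal-plane: 3 DOFs (hip, knee, ankle
flexion) and 8 muscles with antagonist pairs about every DOF — small
enough for exhaustive QP oracles, structured like a reduced lower-limb
model.  Truth geometry uses degree-2 polynomials with physiological moment
arms (2–6 cm); activations are raised-cosine bumps at gait-appropriate
phases plus a co-contraction floor (default 0.02 of max excitation; 0.15
in the co-contraction experiment).

Per trial, the generator computes activations, forces and moments through
the package's own chain, so "inverse dynamics" moments are *defined* as
the truth-model prediction and forward consistency is exact.  Events are
placed in closed form to realize signed stance-time and double-support
asymmetries exactly; foot trajectories are cosine curves whose two grid
samples bracketing each heel strike are offset so the linearly
interpolated foot–pelvis distance at the event is exact.  Cycle period
follows stride length 0.35 + 0.70·v.  An imposed linear CoT–speed trend is
realized by root-finding (Brent) the per-speed activation amplitude under
the trend's energetics model; per-trial amplitude jitter (SD 3%) scatters
trials around the line.  Envelope noise defaults to zero so the headline
pipeline is exactly self-consistent; noise is exercised in dedicated
tests.  The two shipped subjects walk at 0.4–0.8 and 0.35–0.65 m/s with
Fugl-Meyer scores 32 and 25 and B04 CoT trends (−3.0, 6.2) and (−3.0, 7.0).

What the generator does **not** emulate: marker trajectories, realistic
GRF waveforms beyond threshold-crossing structure, upper-body or
frontal-plane musculature, tendon compliance, and EMG crosstalk.  Passing
tests therefore establish the pipeline's internal correctness and its
qualitative behavior (personalization and co-contraction effects, trend
statistics), not quantitative accuracy on real gait data.

Reference "experimental" trend points and Fugl-Meyer data are synthetic
(seeded, labeled as such): CoT 6.3 − 3.0·v ± 0.30 over 0.2–0.95 m/s, with
asymmetries shrinking with speed, and mean CoT 8.6 − 0.13·FM ± 0.5 across
15 reference subjects.

## Statistics

Trend comparison uses ANCOVA on pooled per-trial points: the slope test is
the covariate-by-group interaction in `y ~ x * group`; the intercept test
is the group effect in the common-slope model `y ~ x + group` (the standard
parameterization); the absolute intercept difference comes from the two
groups' separate OLS fits.  Reference points are cropped to ±0.05 m/s of
the predicted speed range; Fugl-Meyer matching keeps reference subjects
within ±3 points.  p-values are reported raw (no multiplicity correction
across the 4 covariates × 9 combinations), matching the reporting
convention of the trend-comparison literature.  The test suite checks the
slope p-value against a Freedman–Lane permutation oracle.

## Known limitations

* Rigid tendon biases fiber velocities (hence shortening/lengthening heat)
  for muscles with long compliant tendons (e.g. plantarflexors).
* Static optimization here uses the Σa² objective only.
* The Umberger implementations use a single aerobic scale (1.5) and apply
  the shortening-heat activation exponent to the combined slow+fast term.
* Event detection on real treadmill data would need force-plate
  cross-validation; the 20 N / 50 ms threshold rule is the usual
  convention, chosen because the data source does not dictate one.
* Problem sizes in the shipped analyses (8 muscles, 3 DOFs, ≤3 trials per
  speed, ≤200 calibration iterations) were chosen so the full study runs
  in about a minute; they are stated here as the package's default study
  conditions.
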