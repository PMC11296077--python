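# Methods

This note documents the models, conventions and numerical choices behind
the package, and what its synthetic-data tests do and do not demonstrate.

## Coordinate and sign conventions

All mechanics are sagittal-plane, lab (treadmill-machine) frame: `y`
fore–aft, positive in the direction of progression; `z` vertical, positive
up; SI units. Rotations are counterclockwise-positive about the `+x` axis
internally; reported joint moments and angular velocities are remapped to
the clinical convention — extension-positive for ankle and hip,
flexion-positive for knee — which in this plane is a sign flip for all
three joints. Work quantities are stored signed (`W− ≤ 0`) and reported in
J/kg of body mass.

## Centre-of-mass mechanics

CoM accelerations come directly from the force plate (`a_f = F_y/m`,
`a_v = F_z/m − g`; the lateral component is not modelled). Velocities and
the vertical displacement are trapezoidal integrals with integration
constants applied **per stride** (stride-mean velocity zero in the lab
frame), so drift cannot accumulate; the spec-level alternative of per-trial
constants was rejected because the analysis is per-stride anyway.

The fore-aft external energy uses the **belt-relative** speed:
`E_kf = ½m(v_f + V_avg)²`, where `V_avg` is the belt speed magnitude and
the belt surface moves at `−V_avg` in this frame. This is the
overground-equivalent frame — the stance foot is stationary in it, so the
GRF does no translational external work and the external + internal energy
rate is commensurable with the summed joint powers. With the opposite sign
choice the `F_y·V_avg` cross term enters the bookkeeping twice and joint
work can never reconcile with total work; the package's rigid-gait null
test (below) is the regression guard for this choice.

Positive/negative work per stride is the sum of positive/negative
sample-to-sample increments of the relevant energy curve at the force rate,
with no smoothing and no dead-band (low-pass filtering upstream already
suppresses noise); the telescoping identity
`W+ + W− = E(end) − E(start)` therefore holds exactly and is asserted
property-style in the tests.

## Signal conditioning

Force and marker signals are filtered with an 8th-order low-pass Bessel
filter applied forward and backward (zero phase). A two-way pass squares
the magnitude response, so the design frequency is pre-warped by a 1-D root
find until the realized two-pass half-power point lands on the configured
cutoff (default 30 Hz for both force and kinematics, configurable in
`AnalysisConfig`; the meaningful range for running data is roughly
10–50 Hz). Markers (200 Hz) are oversampled to the force grid (1 kHz) with
interpolating cubic splines before filtering; derivatives are central
finite differences on that grid.

Foot contacts are maximal runs with `F_z` above 10% of body weight; runs
shorter than 20 ms are discarded as threshold chatter (the debounce removes
crossing noise without deleting real contacts at any tested cadence).
Contacts are labelled left/right by which ankle marker is nearer the centre
of pressure (COP) at mid-contact — on a single-belt treadmill, plate-based
labelling is impossible — and strides run from each right-foot touchdown to
the next. Running is assumed: overlapping contacts raise an error.

## Segments, internal work and inverse dynamics

Segments are thigh (greater trochanter → knee), shank (knee → ankle), foot
(ankle → midpoint of heel and fifth-metatarsal markers) and a single trunk
segment (midpoint of waist/backwaist → neck). Masses, CoM locations and
gyration radii come from a named anthropometric table of body-mass and
segment-length fractions; Winter's standard values ship as the default and
alternative tables can be registered or loaded from TSV. Joint centres are
the marker positions themselves (no joint-centre regression), and arms are
not modelled: internal work excludes them, and the bottom-up joint chain
never reaches them.

Internal energy per limb sums `½(m_i V_i'² + I_i ω_i²)` over the limb's
segments **before** increments are taken, so energy may transfer between
ipsilateral segments but not across limbs or into the CoM term; `V_i'` is
the segment-CoM speed relative to the force-derived CoM velocity (a
marker-derived CoM variant exists behind `AnalysisConfig.kinematic_com`
for auditing, off by default).

Joint moments are bottom-up sagittal Newton–Euler: the foot receives the
GRF at the COP, and reactions/moments propagate foot → shank → thigh.
Within a contact, COP samples where `F_z < 300 N` (where a force-plate COP
is unreliable) are clamped to the nearest valid sample of the same contact;
the error is bounded because force, hence moment, is small there. Joint
powers `P_j = M_j ω_j` are summed per limb before time-integration
(ipsilateral inter-joint transfer), and the increments of that integral
give `W_j±`.

`W_tot±` and `W_ST±` follow by the two exact construction identities. Even
on perfectly rigid, dynamically consistent data the residual `W_ST` is not
exactly zero — the limb-grouped transfer conventions of the two sides of
the comparison differ — so the package's null expectation is a bound
(|W_ST−| within 10% of W_tot+ on rigid synthetic gait), not zero; measured
values on the shipped generator are a few tenths of a percent.

## Spring-mass-actuator model and hysteresis area

Per contact, the leg is the COP→GT axis: `L_leg` its length, `V_leg` its
central-difference rate, `F_projected` the GRF component along it divided
by body mass, with frames below the 300 N COP threshold masked. The model
`F_projected = cst + k·L_leg + c·V_leg` is fitted per step by ordinary
least squares (own normal-equations-free `lstsq` implementation;
statsmodels serves as an independent cross-check in the tests only);
`SpringMassActuator.fit()` returns estimates, standard errors, R², RMSE
and a `summary()`. On realistic loops the coefficient on `L_leg` is
negative — force peaks when the leg is shortest — and its magnitude is the
leg stiffness; the raw signed coefficient is reported.

`Δ_area` is computed as the hysteresis **loop area**, `−∮F dL` by
trapezoidal path integration over the valid span of the contact, closed
with a straight chord from the last sample back to the first. The chord
closure makes any conservative `F(L)` integrate to exactly zero even when
touchdown and toe-off leg lengths differ slightly (synthetic gait loops
close only to ~10% of the compression depth; a warning is attached beyond
that). A damper contributes `−c∫V_leg² dt > 0`: positive area = net energy
absorbed. The printed two-branch signed-integral variant (which does not
vanish for a conservative spring) is available behind
`AnalysisConfig.literal_delta_area` for auditing. Compression and
decompression split at the global minimum of `L_leg`, earliest index on
ties; monotone contacts are excluded with a warning.

## Aggregation and statistics

Per-limb and per-step quantities are averaged right/left within each
stride first, then across strides — the estimator is invariant to
left/right ordering and stride permutation. Pearson correlations are
reported with 95% Fisher-z intervals (`z = atanh r`, half-width
`1.96/√(n−3)`) and two-sided p-values from the t-distribution with `n − 2`
degrees of freedom. The default correlation pairs are `Δ_area` against
total soft-tissue work (`|W_ST+| + |W_ST−|`), against `c` and against `k`.
Mixed-effects condition modelling is out of scope; the package reports
condition means ± SD.

## Synthetic gait generator

The generator is **kinematics-first and CoM-prescribed** so that rigid-mode
trials are Newton-consistent by construction:

1. The GRF is prescribed in closed form: half-sine vertical bursts with
   peak `πmg/(2·duty)` (impulse balances body weight exactly), a
   braking→propulsion fore-aft sine of amplitude 0.20 body weight with zero
   net impulse, and true flight phases.
2. The true CoM trajectory is the double trapezoidal integral of that
   force; it goes into the ledger.
3. Ankle trajectories are belt-locked during stance and quintic-Hermite
   swings with belt-speed-matched endpoint velocities; the pelvis is solved
   per frame (damped fixed point, residual < 1e−9 m) so the segment-mass-
   weighted CoM equals the prescribed CoM *exactly*, with knees from
   two-link inverse kinematics (anterior solution).
4. The COP is placed by the whole-body angular-momentum balance about the
   origin, making force, COP and kinematics a consistent dynamic triplet;
   ledger joint moments are computed by an independent d'Alembert
   formulation (sum over distal segments), not by the package's recursive
   Newton–Euler.
5. Wobble mode carves a point mass out of the trunk and couples it to the
   rigid remainder with a spring-damper. The relative coordinate obeys a
   reduced-mass oscillator driven by `−F_z/m_r` (solved as an LTI system
   with `scipy.signal.lsim`), the rigid part recoils accordingly, and the
   written GRF remains the prescribed total — so flight stays ballistic for
   the whole body and the construction stays physical. Damper dissipation
   `c_w·ẋ²` is integrated per stride into the ledger.
6. Measurement noise is added last from a single seeded generator
   (defaults: 0.5 N force, 0.2 mm markers — instrument-grade for a
   force-transducer treadmill and a calibrated optical capture volume).

Default conditions: 73.7 kg, 1.84 m subject at 3.06 m/s (11 km/h) and
2.8 steps/s, duty factor 0.65 of the step period, 10 strides — a mid-range
treadmill protocol small enough that the full pipeline runs in about a
second per trial. The generator's leg is slightly long (0.255·height per
thigh/shank) with the CoM at 0.47·height: the rigid straight-knee linkage
has no plantarflexion to extend its reach at touchdown, and these constants
keep the touchdown geometry feasible at the default conditions. Parameter
sets that would overextend a leg (fast belts at low cadence) raise
`InfeasibleParametersError` rather than producing silently inconsistent
kinematics.

Wobble defaults — mass fraction 0.15, natural frequency 4.5 Hz (visceral
wobbling-mass band, near the second loading harmonic), damping ratio 0.25
(rising branch of dissipation vs damping) — were chosen from the oscillator
response analysis so the injected per-stride dissipation is of realistic
magnitude (~0.16 J/kg) and large relative to the mode-difference
systematic. Because the element's storage-return component interleaves with
the residual-curve increments, the split of the recovered dissipation
between `W_ST+` and `W_ST−` depends on gait geometry; the robust recovery
statement, used in the acceptance checks, is that the **net**
wobble-minus-rigid change `−[Δ(W_ST+) + Δ(W_ST−)]` matches the ledgered
dissipation (within 15%), with the extra soft-tissue work appearing on the
negative branch.

The wobbling mass rides on the trunk, *above* the greater trochanter, so
its dissipation is outside the measured COP→GT leg axis and does not
inflate the measured `Δ_area` — on this generator the force–length loop
area responds to the kinematic recoil, not to the trunk-level dissipation.
The damping-sweep test of the correlation surface therefore uses the
spring-loop harness (`simulate_spring_loop`), where the actuator damping is
swept with the loop kinematics held fixed and the dissipated energy
`−c∫V²dt` is the soft-tissue-work analogue; the full-trial wobble sweep is
used for the monotonicity of `W_ST−` in the injected damping coefficient
(swept through the wobble mass fraction at fixed damping ratio, which keeps
dissipation monotone in the coefficient by construction).

### What passing tests do and do not show

The generator reproduces the structural properties the pipeline assumes —
Newton consistency, alternating contacts with flight, ipsilateral energy
flow, a known dissipative element — but it is not a physiologically
validated gait model: feet never plantarflex, the trunk does not rotate,
arms are absent, impacts have no high-frequency transient beyond the
half-sine onset, and soft tissue is a single linear oscillator at one
location. Passing the recovery tests shows the pipeline's bookkeeping and
numerics are correct at realistic signal scales; it does not certify
accuracy on real runners, where marker artefacts, anthropometric-table
error and multi-site soft-tissue dynamics add systematic components the
generator does not emulate.

## Numerical choices and degenerate inputs

Trapezoidal integration throughout (matching the CoM integration scheme);
half-open, 0-based sample intervals on the force grid; ties in the
compression split break to the earliest index; spring fits require ≥ 10
valid frames and a full-rank design (errors otherwise); contacts with
monotone leg length are excluded from `Δ_area` with a warning; segment
lengths must be > 1 cm with < 5% coefficient of variation (rigid-pair
check); marker gaps are linearly interpolated before spline oversampling
and flagged by `validate_trial`. The Fisher interval degenerates to a point
at |r| = 1 with a warning rather than an error.

## Known limitations

* 2-D sagittal mechanics only; the lateral GRF component and
  frontal/transverse moments are out of scope.
* The COP is accepted as an input column (clamped below 300 N); no
  transducer-geometry reconstruction is attempted.
* The soft-tissue residual inherits every inverse-dynamics assumption
  (rigid segments, hinge joints, marker-defined joint centres, table
  anthropometry); on real data it is an estimate, not a measurement.
* Walking (double support) is not supported; the gait-event logic assumes
  running.
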