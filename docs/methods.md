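# Methods

`llte` implements a quantitative design framework for passive
energy-storage-and-return (ESR) prosthetic feet.  The central idea is that a
prosthetic foot's mechanical function can be designed *predictively*: given
a target walking pattern (kinetics and lower-leg kinematics) and a
constitutive model of the foot, one can simulate the lower-leg trajectory
the foot would produce under the target loads and tune the foot's geometry
and stiffness until that trajectory matches the target.  This note records
the models, conventions, numerical choices and known limitations.

## The lower leg trajectory error (LLTE)

For a set of N stance instances, the scalar objective is

    LLTE = sqrt( (1/N) * sum_n [ ((x_n^model - x_n^ref) / x_bar)^2
                               + ((y_n^model - y_n^ref) / y_bar)^2
                               + ((th_n^model - th_n^ref) / th_bar)^2 ] )

where `(x, y)` is the sagittal knee-point position, `th` the shank angle
from vertical, and each normalizer is the mean *absolute* value of the
corresponding reference variable over the instances considered.  The mean
absolute value (rather than the signed mean) is used because the signed
mean of `x_knee` is close to zero over a symmetric stance and would blow
the term up.  A stance frame whose pose cannot be resolved contributes a
squared penalty of 10^2 per frame, so infeasible designs still rank.

Nine representative instances at 8, 20, 27, 36, 50, 62, 75, 80 and 82% of
stance (0% = heel strike, 100% = toe-off) stand in for the full stance by
default; their sufficiency is re-derived on a reduced analytic problem (see
below).

## Reference gait and its synthesis

The framework consumes a stance-phase reference table: fore-aft and
vertical GRF, CoP progression (heel-relative), sagittal knee position,
shank angle and knee moment, plus the body parameters it was recorded at.
Published able-bodied curves can be supplied as CSV; the bundled generator
synthesizes an able-bodied-like table so every part of the pipeline is
testable without licensed data.

Generator construction (defaults: 70 kg, 0.26 m foot, 0.50 m lower leg,
101 samples):

* **Vertical GRF** — two-harmonic M-shape `1.2 sin(pi s) + 0.4 sin(3 pi s)`
  body weights, giving two peaks of ~1.13 BW and a mid-stance valley of
  0.8 BW; **fore-aft GRF** — `-0.16 sin(2 pi s)` BW (braking then
  propulsion).  A small seeded Fourier perturbation (1% BW, vanishing at
  both stance ends) stands in for inter-subject variability.
* **CoP** — smooth ease-in/out `B(u) = u^3 (4 - 3u)` with `u = s / 0.70`,
  scaled to 83% of foot length.  The CoP therefore dwells near the heel
  early, crosses the ankle station mid-stance, and is *stationary* at the
  effective toe from 70% of stance onward.  The stationarity at both ends
  is not cosmetic: the contact model resolves heel-strike and toe-off poses
  by rotation about a stationary CoP, so a reference whose CoP still
  progresses during those phases would violate the framework's own
  assumptions.
* **Lower-leg trajectory** — a three-phase ankle-foot model: the foot lands
  toe-up (-12 deg pitch) and pitches down about the heel by 12% of stance;
  mid-stance the foot is flat and the ankle stationary; from 60% the heel
  rises about the (frozen) CoP up to +35 deg pitch.  The knee sits at shank
  length from the moving ankle along the shank direction, with the shank
  angle sweeping -15 to +25 deg as an S-curve.  Over the single-support
  portion this reproduces the typical able-bodied knee excursion; the
  trajectory is kinematically consistent with rolling contact, which is
  what makes the design problem well-posed.
* **Knee moment** — computed as `(CoP - knee) x GRF` at every sample, so
  the table is dynamically consistent by construction (the flat-phase
  identity holds to round-off).

Scaling to a user multiplies GRFs by the body-mass ratio, CoP by the
foot-length ratio, knee coordinates by the lower-leg-length ratio, and knee
moments by mass ratio x leg ratio (force times body-geometry lever); the
shank angle is dimensionless.  Scaling is exactly invertible.

What the generator does **not** emulate: measurement noise and soft-tissue
artifact, inter-stride variability, out-of-sagittal components, and the
subtler timing structure of real CoP progression.  Tests passing on this
generator demonstrate correctness of the computations, not clinical
validity on real recordings.

## Parametric foot model

The foot is a 2-D extruded compliant structure described by three wide
Bezier curves over six control circles C1..C6: a cubic keel C1->C4, linear
forefoot C4->C5 and linear heel C4->C6.  Circle centers are the Bezier
control points of the centerline; circle radii are Bernstein-interpolated
along the parameter to give the local half-thickness; the boundary is the
centerline offset by the half-thickness along the local normal (the
standard wide-Bezier construction; the offset-normal choice is documented
here because alternative tangent-circle constructions exist).

Of the 18 scalars, 11 are free design variables (`C1.d, C2.x, C2.y, C2.d,
C3.x, C3.y, C3.d, C4.x, C4.d, C5.d, C6.d`).  The rest are fixed: C1 (the
ankle, where the pylon attaches) at the origin; C5/C6 abscissae at the toe
and heel extremities with the ankle at 25% of foot length from the heel
(configurable; 25% is the conventional able-bodied ankle station); C4, C5,
C6 resting on the ground line `y = -h_ank`.  Default bounds keep designs
within roughly a biological-foot envelope (`L_foot` by `h_ank + 2 cm`) and
thicknesses within 6-45 mm.  The out-of-plane extrusion width defaults to
60 mm.

Self-intersection screening works on the offset boundary polylines: a
segment whose own offsets cross (over-thick tight bend) is rejected, as is
any crossing between two segments' boundaries outside the junction
neighborhood at C4 where the three branches legitimately merge into one
solid part (neighborhood radius: max of 4 circle radii and 20% of the
shorter segment's arc length).

## Structural solver

Plane frame elements (2 nodes, 3 DOF/node: u, v, rotation) with axial and
Euler-Bernoulli bending response; shear deformation neglected (slenderness
above 10 for all feasible designs); self-weight and inertia neglected
(stance loading is quasi-static for these structures).  Geometric
nonlinearity uses a corotational formulation: the element chord rotation is
removed from the nodal rotations, local deformational quantities
(elongation, end rotations) feed the linear section laws, and the tangent
includes the geometric stiffness terms.  Loads ramp in 10 increments with
full Newton iterations to a relative force residual of 1e-6 (at most 50
iterations per increment); an absolute Newton-update floor of 1e-12
terminates cleanly for near-rigid structures where the force residual
stalls at round-off.  The mesh allocates 300 elements (mesh-convergence
tested: tip deflection changes < 1% vs 600) proportionally to segment arc
length, with area `w t` and inertia `w t^3 / 12` from the local thickness.

Bending stiffness and bending stress use the flexural modulus/yield, axial
terms the tensile modulus/yield: the structure is bending-dominated, and
the flexural constants are measured in the deformation mode that governs.
This choice is configurable.  Stress recovery is extreme-fiber:
`|N/A| + |M c / I|` per element end; the safety check compares the peak
against flexural yield / 1.75 (the prescribed factor covering unmodelled
loading).

## Contact kinematics and pose resolution

The shank is rigidly attached at C1; the virtual "knee" sits vertically
above the ankle at the lower-leg length from the ground when the foot is
flat and unloaded.  Sign conventions: +x walking direction, +y up, foot
rotation `phi` counterclockwise-positive, `theta_shank = -phi` (positive
when the knee is anterior to the ankle).

* **Flat contact** (between the regime boundaries, default 10-70% of
  stance): the GRF is applied at the sole material point at the CoP
  station; `phi` is the root of `tangent(phi) + phi = 0` where `tangent`
  is the deformed sole tangent angle at the loaded point.  The loaded point
  is then placed at `(cop_x, 0)` and the knee follows rigidly.
* **Line contact** (heel strike / toe-off): the CoP is stationary at its
  extreme station (near the heel tip early; at the *effective* toe — about
  83% of foot length, short of the geometric toe — late) and tangency no
  longer constrains the orientation.  `phi` is the root of
  `implied_knee_moment(phi) - reference_moment`, with the pivot at the sole
  material point under the CoP.

Both residuals are solved by bracketing (a narrow window around the warm
start, widening to a 1-degree grid over +/-45 degrees) and Brent's method
(xtol 1e-10 rad); each iterate re-runs the structural solve with the load
rotated into the foot frame.  Frames are solved in stance order with the
previous orientation as warm start, and the root branch nearest the warm
start is taken when several exist.  For a near-rigid foot the whole
procedure collapses to geometry-only rigid rolling, which the tests verify
to 1e-6 m / 1e-4 deg.

A consequence worth noting: for a *flat* rigid sole the material-point
contact model keeps the ankle stationary through the flat phase — a rigid
jointless foot cannot advance the leg, which is precisely why rigid feet
score poorly on the trajectory error and compliant keels score well.

## Reduced analytic model and instance sufficiency

Deciding how many stance instances the objective needs is done on a cheap
analytic model (as the framework's own development did): a rigid ankle
block with two uniform cantilever beams (forefoot and heel) whose sole
slope and deflection under a transverse load are closed-form
(`psi = F l^2 / 2EI`, `delta = F l^3 / 3EI`), driving exactly the same
contact-pose construction.  The two free variables are thickness scales of
the two beams (nominal sections 8 mm keel / 5.5 mm heel at 60 mm width,
chosen so unit scales sit near the balance point of the synthetic
reference; bounds 0.5-2.0).

On this problem, a 50x50 exhaustive grid search over the nine instances
versus all percents 1-99 gives optima agreeing within ~2.5% per variable,
and the full-set optimum's LLTE changes by < 0.5% when evaluated on the
nine — the basis for using nine instances in the expensive FEA-backed
optimization (a roughly tenfold cost reduction).

## Optimization

A real-coded genetic algorithm over genes scaled to [0, 1] by the bounds:
tournament selection (size 3), blend crossover (alpha 0.5, rate 0.9),
per-gene Gaussian mutation (sigma 0.1, rate 0.15), single-individual
elitism; population 50 and 60 generations by default; bit-reproducible for
a fixed seed; optional warm start from a baseline design.  Constraint
handling is by static penalties: out-of-bounds and self-intersecting
candidates short-circuit (no FEA) to a penalty of 1e3 scaled by violation
magnitude; stress violations add `10 x (max_stress/allowable - 1)` on top
of the true trajectory error so overstressed designs still rank by
kinematic quality.  Feasibility of the reported optimum is re-checked
outside the penalty path.

## Gait-analysis layer

Implements the evaluation metrics for marker (120 Hz) + force-plate
(960 Hz) step recordings, axes x forward / y up / z lateral:

* fourth-order zero-phase Butterworth filtering (6 Hz kinematic, 12 Hz
  kinetic); kinetic series that are undefined outside ground contact (CoP)
  are filtered within the stance segment only;
* stance detection at a 40 N vertical-GRF threshold with sub-10 ms chatter
  merging; percent-of-stance normalization by linear interpolation;
* a virtual knee marker vertically above the ankle at calibration, rotated
  rigidly with the shank (constant sagittal offset angle);
* walking speed (mean sacrum velocity along travel), Froude number
  `v^2/(g L)` with L the hip-to-floor leg length, stance-time symmetry
  index `SI = 100 (1 - |X_P - X_S| / (0.5 |X_P + X_S|))`, step width
  (lateral ankle separation at contacts), frontal-plane trunk sway range;
* foot-shank angle from the heel-toe and ankle-knee segments (sagittal
  projection), neutral defined over swing, dorsiflexion positive;
* roll-over shape: CoP from heel strike to opposite heel strike in the
  shank-fixed frame, algebraic least-squares circle fit, radius normalized
  by lower-leg length; effective foot length = heel-to-CoP distance at
  opposite heel contact; EFLR = effective / physical foot length
  (able-bodied comparison values: 0.31 m/m radius, 0.81 EFLR);
* unified-deformable distal shank power
  `P = F . v_cop + M_free * omega`, with `v_cop` the velocity of the shank
  material point instantaneously at the CoP.  "Energy return" integrates
  the positive power from its final negative-to-positive crossing to
  toe-off, per kg.  The plain net time integral is also reported: for an
  elastic foot it is near zero, and the positive-phase reading matches the
  physical meaning of energy stored and returned.  This interpretation is
  flagged as such;
* step-to-step transition work: CoM velocity by integrating
  `(sum GRF - weight)/m` over a stride with periodicity constraints (mean
  forward velocity = walking speed, zero-mean vertical velocity);
  collision = negative-power integral of the leading limb over double
  support, propulsion = positive-power integral of the trailing limb;
  double-support windows bounded by the 40 N contact events;
* deviation scores: per-leg NRMSE of the six channels against the
  reference (GRFs / body weight, CoP / foot length, knee coordinates /
  lower-leg length, shank angle / reference angle range), totalled over
  both legs (12 terms).

The recording generator builds a rigid rolling-rocker leg per side
(programmable rocker radius, stance times, walking speed, trunk sway,
dorsiflexion profile, step width) with an optional elastic compression mode
calibrated by quadrature to a prescribed energy budget, and stores the
analytic ground truth of every metric on the recording.  Marker data are
noise-free by default; the intact side leads so the first prosthetic step
has a complete double support on record.

## Numerical and design choices, in brief

* Interpolation of gait channels is piecewise-linear in stance percent.
* Regime boundaries default to heel contact below 10% and toe contact above
  70% of stance, matching where the synthetic CoP is stationary; both are
  configuration.
* Angle units: degrees at all public interfaces, radians internally.
* The DXF/SVG outline export writes the closed outer boundary (union of
  the three thick segments) in millimetres.
* Problem sizes used by the shipped checks (chosen to keep a full run on a
  single CPU comfortable): 100-120 elements for solver-backed tests, the
  full 300 for meshing/convergence checks; GA budgets of 30-40 individuals
  for contract tests and a 6x3 warm-started budget for the end-to-end
  round.

## Known limitations

* The framework is sagittal-plane only; frontal/transverse behaviour,
  multi-axial feet and socket compliance are out of scope.
* Contact is an idealized point load at the CoP with no-slip; distributed
  pressure and friction limits are not modelled.
* The line-contact moment-matching pose can deviate substantially from an
  able-bodied reference near toe-off: a jointless foot must over-rotate to
  advance the knee, which is a genuine property of passive prostheses and
  the main contributor to nonzero trajectory errors of optimized designs.
* Material behaviour is linear elastic; plasticity, viscoelasticity and
  fatigue are not modelled (the 1.75 safety factor covers unmodelled
  loading only in the static sense).
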