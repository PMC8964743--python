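# llte

Design and evaluation of passive energy-storage-and-return (ESR) prosthetic
feet with the **lower leg trajectory error (LLTE)** framework.

Most prosthetic feet are designed iteratively, one mechanical property at a
time.  The LLTE framework is predictive instead: given a target walking
pattern — stance-phase ground reaction forces (GRF), center-of-pressure
(CoP) progression and lower-leg kinematics, scaled to the user's body — and
a structural model of a candidate foot, it simulates the lower-leg
trajectory that foot would produce under the target loads and optimizes the
foot's shape and stiffness until the simulated trajectory matches the
target.  The scalar objective over N stance instances is

    LLTE = sqrt( (1/N) * sum_n [ ((x_knee,n^model - x_knee,n^ref)/x_bar)^2
                               + ((y_knee,n^model - y_knee,n^ref)/y_bar)^2
                               + ((theta_n^model  - theta_n^ref )/theta_bar)^2 ] )

with each normalizer the mean |reference| of that variable over the
instances considered.  The package is aimed at rehabilitation-engineering
researchers and prosthetics designers who want a fully scriptable,
testable implementation of the pipeline.

What is inside:

* `llte.gait` — stance-phase reference gait tables: CSV I/O, a synthetic
  able-bodied generator, body-parameter scaling, resampling into load
  cases (nine representative instances at 8-82% of stance by default);
* `llte.parametrization` — the wide-Bezier foot model: 11 free design
  variables over six control circles, geometry evaluation,
  self-intersection screening, frame meshing, SVG/DXF outline export;
* `llte.solver` — corotational plane-frame finite elements for the
  quasi-static large-deflection response, stress recovery and the
  yield/1.75 safety check (Nylon 6/6 constants included);
* `llte.engine` — contact kinematics (flat-foot tangency; heel/toe
  line-contact resolved with the reference knee moment) and the LLTE
  metric;
* `llte.analytic` — a closed-form two-beam foot model for cheap
  instance-selection studies;
* `llte.optimize` — constrained real-coded genetic algorithm (bounds,
  stress, self-intersection), grid-search oracle, instance-set comparison;
* `llte.analysis` — gait metrics for marker + force-plate recordings:
  Butterworth filtering, stance detection, walking speed / Froude number /
  symmetry index / step width / trunk sway, foot angles, roll-over shape
  and effective foot length ratio, unified-deformable foot power and
  energy return, CoM collision/propulsion work, NRMSE deviation scores —
  plus a synthetic recording generator with known ground truth.

## Worked example

Evaluate a candidate foot for a 70 kg user (0.26 m foot, 0.50 m lower leg,
8 cm build height) against the synthetic able-bodied reference:

```python
import numpy as np
import llte
from llte.solver import NYLON_66

user = llte.UserCharacteristics(body_mass=70, foot_length=0.26,
                                lower_leg_length=0.50, residuum_length=0.30,
                                build_height_h_ank=0.08)
ref = llte.synthesize_reference_gait(seed=1)
cases = llte.resample_stance(ref)          # the nine stance instances

vars11 = np.array([0.020, 0.03, -0.02, 0.020, 0.08, -0.04,
                   0.018, 0.12, 0.016, 0.012, 0.016])
design = llte.complete_design(vars11, user)
traj = llte.compute_trajectory(design, NYLON_66, cases, user, n_elements=300)
value = llte.compute_llte(traj, ref, traj.percents)
print(f"LLTE = {value.value:.3f}")
print(f"peak stress = {np.nanmax(traj.max_stress)/1e6:.1f} MPa "
      f"(allowable {NYLON_66.flexural_yield/1.75/1e6:.1f} MPa)")
```

prints

```
LLTE = 0.476
peak stress = 50.4 MPa (allowable 52.6 MPa)
```

An LLTE of 0.476 means the root-mean normalized pose deviation across the
nine instances is about 48% of the mean reference magnitudes — a feasible
but unoptimized starting design (optimized user-specific feet reach a few
tenths).  The stress check confirms the design survives all nine loadings
with the 1.75 safety factor.  From here,
`llte.optimize.optimize_design(FEAObjective(...), OptimizationConfig(...))`
searches the 11-variable space for lower LLTE under the same constraints,
and `llte.export_outline(...)` writes a manufacturable outline in mm.

The same pipeline is available from the shell:

```bash
llte simulate-gait --seed 1 --out ref.csv
llte design --gait ref.csv --user user.json --seed 1 --out result/
llte evaluate --design result/best_design.json --gait ref.csv --user user.json
```

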