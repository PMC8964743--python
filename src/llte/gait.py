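"""Stance-phase reference gait data: loading, synthesis, scaling and resampling.

The design framework consumes a *reference gait*: stance-phase ground
reaction forces (GRF), center-of-pressure (CoP) progression, sagittal knee
position, shank angle and knee moment, recorded (or synthesized) together
with the body parameters of the subject they belong to.  Stance percent runs
0 (heel strike) to 100 (toe-off).

Sign conventions (sagittal plane): +x is the walking direction, +y is up.
``theta_shank`` is the shank angle from vertical in degrees, positive when
the knee is anterior to the ankle.  Moments are positive counterclockwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceGait",
    "UserCharacteristics",
    "LoadCase",
    "GaitSynthesisConfig",
    "RegimeZones",
    "NINE_INSTANCE_PERCENTS",
    "read_gait_table",
    "write_gait_table",
    "synthesize_reference_gait",
    "knee_moment_from_kinetics",
    "scale_to_user",
    "resample_stance",
    "reference_pose_at",
]

#: The nine representative stance-phase instances used by default for the
#: trajectory-error evaluation (percent of stance, 0 = heel strike).
NINE_INSTANCE_PERCENTS = (8.0, 20.0, 27.0, 36.0, 50.0, 62.0, 75.0, 80.0, 82.0)

# canonical CSV column names (units embedded)
_COLUMNS = {
    "stance_percent": "stance_percent",
    "grf_x": "grf_x_N",
    "grf_y": "grf_y_N",
    "cop_x": "cop_x_m",
    "knee_x": "knee_x_m",
    "knee_y": "knee_y_m",
    "theta_shank": "theta_shank_deg",
    "knee_moment": "knee_moment_Nm",
}


class GaitValidationError(ValueError):
    """A gait table violates a structural invariant."""


class GaitSchemaError(KeyError):
    """A gait table file is missing required columns or metadata."""


@dataclass
class ReferenceGait:
    """Stance-phase kinetic and kinematic curves plus recording-subject body parameters.

    All arrays share one length (>= 2) and are sampled on a strictly
    increasing ``stance_percent`` grid spanning [0, 100].
    """

    stance_percent: np.ndarray  # % of stance, strictly increasing, [0, 100]
    grf_x: np.ndarray  # fore-aft GRF, N (+ anterior)
    grf_y: np.ndarray  # vertical GRF, N (+ up), >= 0
    cop_x: np.ndarray  # CoP position, m, heel-relative, non-decreasing
    knee_x: np.ndarray  # sagittal knee point, m
    knee_y: np.ndarray  # sagittal knee point, m
    theta_shank: np.ndarray  # shank angle from vertical, deg
    knee_moment: np.ndarray  # sagittal knee moment, N*m (+ CCW)
    body_mass: float  # kg
    foot_length: float  # m
    lower_leg_length: float  # m (knee point to ground, foot flat, unloaded)

    def __post_init__(self) -> None:
        for name in _COLUMNS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def validate(self) -> None:
        n = self.stance_percent.size
        if n < 2:
            raise GaitValidationError("gait table needs at least 2 samples")
        for name in _COLUMNS:
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise GaitValidationError(f"column {name!r} has wrong length")
            if not np.all(np.isfinite(arr)):
                raise GaitValidationError(f"column {name!r} has non-finite values")
        sp = self.stance_percent
        if not np.all(np.diff(sp) > 0):
            raise GaitValidationError("stance_percent must be strictly increasing")
        if sp[0] < 0 or sp[-1] > 100 or not (sp[0] == 0 and sp[-1] == 100):
            raise GaitValidationError("stance_percent must span [0, 100]")
        if np.any(np.diff(self.cop_x) < -1e-12):
            raise GaitValidationError("cop_x must be non-decreasing (heel to toe)")
        if np.any(self.grf_y < 0):
            raise GaitValidationError("grf_y must be non-negative throughout stance")
        for p, v in (("body_mass", self.body_mass),
                     ("foot_length", self.foot_length),
                     ("lower_leg_length", self.lower_leg_length)):
            if not (np.isfinite(v) and v > 0):
                raise GaitValidationError(f"{p} must be strictly positive")

    def __len__(self) -> int:
        return int(self.stance_percent.size)


@dataclass(frozen=True)
class UserCharacteristics:
    """Body parameters of the prosthesis user the design is scaled to."""

    body_mass: float  # kg
    foot_length: float  # m
    lower_leg_length: float  # m, knee point to ground
    residuum_length: float  # m, below-knee residual limb length
    build_height_h_ank: float  # m, prosthesis build height (ankle origin above ground)

    def __post_init__(self) -> None:
        vals = (self.body_mass, self.foot_length, self.lower_leg_length,
                self.residuum_length, self.build_height_h_ank)
        if any(not (np.isfinite(v) and v > 0) for v in vals):
            raise GaitValidationError("all user characteristics must be strictly positive")
        if self.build_height_h_ank + self.residuum_length > self.lower_leg_length + 1e-12:
            raise GaitValidationError(
                "build height + residuum length must not exceed lower leg length")


#: regimes a stance instance can be in
HEEL_LINE_CONTACT = "heel_line_contact"
FLAT_CONTACT = "flat_contact"
TOE_LINE_CONTACT = "toe_line_contact"


@dataclass(frozen=True)
class RegimeZones:
    """Stance-percent boundaries separating line-contact from flat-foot phases.

    Early stance (before ``heel_max`` %) the foot is in line contact at the
    heel; after ``toe_min`` % the heel has lifted and contact is a line at
    the toe; in between the foot is flat on the ground.
    """

    heel_max: float = 10.0
    toe_min: float = 70.0

    def regime(self, percent: float) -> str:
        if percent < self.heel_max:
            return HEEL_LINE_CONTACT
        if percent > self.toe_min:
            return TOE_LINE_CONTACT
        return FLAT_CONTACT


@dataclass(frozen=True)
class LoadCase:
    """One stance instance: applied kinetics plus the contact regime."""

    stance_percent: float
    grf: np.ndarray  # (2,) N, lab frame
    cop_x: float  # m, heel-relative
    knee_moment: float  # N*m
    regime: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "grf", np.asarray(self.grf, dtype=float))
        if self.grf.shape != (2,):
            raise GaitValidationError("LoadCase grf must be a 2-vector")
        if self.regime not in (HEEL_LINE_CONTACT, FLAT_CONTACT, TOE_LINE_CONTACT):
            raise GaitValidationError(f"unknown regime {self.regime!r}")


def knee_moment_from_kinetics(knee_xy, grf, cop_x: float) -> float:
    """Sagittal knee moment implied by the GRF acting at the CoP.

    Returns the 2-D cross product ``(cop - knee) x grf`` with the CoP on the
    ground at ``(cop_x, 0)``.  Positive counterclockwise with +x the walking
    direction.
    """
    knee_xy = np.asarray(knee_xy, dtype=float)
    grf = np.asarray(grf, dtype=float)
    dx = cop_x - knee_xy[0]
    dy = -knee_xy[1]
    return float(dx * grf[1] - dy * grf[0])


# ---------------------------------------------------------------------------
# file I/O


def read_gait_table(path, layout: dict | None = None) -> ReferenceGait:
    """Read a stance-phase gait table (CSV + JSON sidecar) into a :class:`ReferenceGait`.

    ``layout`` optionally maps canonical field names (``grf_x`` ...) to the
    column names used in the file; by default the documented
    ``grf_x_N, grf_y_N, cop_x_m, ...`` layout is expected.  The JSON sidecar
    ``<stem>.json`` must provide ``body_mass_kg``, ``foot_length_m`` and
    ``lower_leg_length_m``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    columns = dict(_COLUMNS)
    if layout:
        columns.update(layout)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in columns.values() if c not in df.columns]
    if missing:
        raise GaitSchemaError(f"gait table {path} missing columns: {missing}")
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise GaitSchemaError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("body_mass_kg", "foot_length_m", "lower_leg_length_m"):
        if key not in meta:
            raise GaitSchemaError(f"sidecar {sidecar} missing {key!r}")
    return ReferenceGait(
        **{name: df[col].to_numpy(dtype=float) for name, col in columns.items()},
        body_mass=float(meta["body_mass_kg"]),
        foot_length=float(meta["foot_length_m"]),
        lower_leg_length=float(meta["lower_leg_length_m"]),
    )


def write_gait_table(ref: ReferenceGait, path) -> Path:
    """Write ``ref`` as CSV plus JSON sidecar (inverse of :func:`read_gait_table`)."""
    path = Path(path)
    df = pd.DataFrame({col: getattr(ref, name) for name, col in _COLUMNS.items()})
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "body_mass_kg": ref.body_mass,
        "foot_length_m": ref.foot_length,
        "lower_leg_length_m": ref.lower_leg_length,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


# ---------------------------------------------------------------------------
# synthesis


@dataclass(frozen=True)
class GaitSynthesisConfig:
    """Shape parameters of the synthetic able-bodied reference gait.

    The defaults emulate published able-bodied level-ground walking at a
    self-selected speed: a double-peaked vertical GRF (~1.13 body weight
    peaks with a mid-stance valley), braking-then-propulsive fore-aft GRF,
    monotone heel-to-toe CoP progression reaching ~83% of foot length, and a
    smooth shank rotation from about -15 deg to +25 deg.  The knee moment is
    computed from the kinematics and kinetics so the whole table is
    dynamically consistent.
    """

    body_mass: float = 70.0  # kg
    foot_length: float = 0.26  # m
    lower_leg_length: float = 0.50  # m
    n_samples: int = 101
    grf_peak_bw: float = 1.2  # first-harmonic vertical amplitude, body weights
    grf_valley_bw: float = 0.4  # third-harmonic amplitude (controls the valley)
    grf_ap_bw: float = 0.16  # fore-aft amplitude, body weights
    cop_excursion: float = 0.83  # final CoP station, fraction of foot length
    cop_plateau: float = 0.70  # stance fraction by which CoP progression completes
    # (the CoP is stationary at the effective toe during late-stance line contact)
    theta_start_deg: float = -15.0
    theta_end_deg: float = 25.0
    ankle_fraction: float = 0.25  # ankle station from the heel, fraction of foot length
    ankle_height: float = 0.08  # m, anatomical ankle joint center above ground
    heel_strike_pitch_deg: float = -12.0  # foot pitch at landing (toe up)
    toe_off_pitch_deg: float = 35.0  # heel-rise pitch approaching toe-off
    noise_bw: float = 0.01  # smooth stochastic GRF perturbation, body weights

    def __post_init__(self) -> None:
        if min(self.body_mass, self.foot_length, self.lower_leg_length) <= 0:
            raise GaitValidationError("body parameters must be strictly positive")
        if self.n_samples < 2:
            raise GaitValidationError("need at least 2 samples")
        if not 0.3 <= self.cop_plateau <= 1.0:
            raise GaitValidationError("cop_plateau must lie in [0.3, 1.0]")


def synthesize_reference_gait(config: GaitSynthesisConfig | None = None,
                              seed: int = 0) -> ReferenceGait:
    """Generate a dynamically consistent synthetic stance-phase reference gait.

    Deterministic for a given ``(config, seed)``.  The seed drives only a
    small smooth perturbation of the GRF curves (zero at heel strike and
    toe-off), standing in for inter-subject variation.
    """
    cfg = config or GaitSynthesisConfig()
    rng = np.random.default_rng(seed)
    s = np.linspace(0.0, 1.0, cfg.n_samples)
    bw = cfg.body_mass * 9.81

    # vertical GRF: two-harmonic M-shape, peaks ~ (peak+valley)/sqrt(2) BW
    grf_y = bw * (cfg.grf_peak_bw * np.sin(np.pi * s)
                  + cfg.grf_valley_bw * np.sin(3 * np.pi * s))
    # fore-aft: braking then propulsion
    grf_x = -bw * cfg.grf_ap_bw * np.sin(2 * np.pi * s)

    # smooth seeded perturbation, vanishing at both stance ends
    if cfg.noise_bw > 0:
        for arr, scale in ((grf_y, 1.0), (grf_x, 0.5)):
            coef = rng.normal(0.0, cfg.noise_bw * scale * bw, size=3)
            arr += sum(c * np.sin((k + 1) * np.pi * s) for k, c in enumerate(coef))
    grf_y = np.clip(grf_y, 0.0, None)

    # CoP: dwells near the heel through the heel-contact phase, crosses the
    # ankle station mid-stance, and saturates at the effective toe by
    # cop_plateau (the CoP is near-stationary during both line-contact
    # phases, as the contact model assumes); smooth ease-in/out
    u = np.clip(s / cfg.cop_plateau, 0.0, 1.0)
    cop_x = cfg.cop_excursion * cfg.foot_length * u**3 * (4.0 - 3.0 * u)
    cop_x[0] = 0.0

    # shank angle: smooth S-curve between the end angles
    smooth = 3 * s**2 - 2 * s**3
    theta = cfg.theta_start_deg + (cfg.theta_end_deg - cfg.theta_start_deg) * smooth
    th = np.radians(theta)

    # lower-leg trajectory from a three-phase able-bodied ankle-foot model:
    # the foot lands toe-up and pitches down about the heel, stays flat with
    # a stationary ankle through mid-stance, then the heel rises about the
    # (by then stationary) CoP; the knee sits at shank length from the
    # moving ankle along the shank direction
    leg = cfg.lower_leg_length
    shank = leg - cfg.ankle_height

    def _smooth(x):
        x = np.clip(x, 0.0, 1.0)
        return 3 * x**2 - 2 * x**3

    psi = np.radians(cfg.heel_strike_pitch_deg) * (1.0 - _smooth(s / 0.12)) \
        + np.radians(cfg.toe_off_pitch_deg) * _smooth((s - 0.6) / 0.4)
    a0x = cfg.ankle_fraction * cfg.foot_length
    rx = a0x - cop_x  # ankle offset from the current contact point
    ry = cfg.ankle_height
    cpsi, spsi = np.cos(psi), np.sin(psi)
    # clockwise foot pitch about the contact (heel rise for psi > 0)
    ankle_x = cop_x + cpsi * rx + spsi * ry
    ankle_y = -spsi * rx + cpsi * ry
    knee_x = ankle_x + shank * np.sin(th)
    knee_y = ankle_y + shank * np.cos(th)

    moment = np.array([
        knee_moment_from_kinetics((kx, ky), (fx, fy), cx)
        for kx, ky, fx, fy, cx in zip(knee_x, knee_y, grf_x, grf_y, cop_x)
    ])

    return ReferenceGait(
        stance_percent=100.0 * s,
        grf_x=grf_x, grf_y=grf_y, cop_x=cop_x,
        knee_x=knee_x, knee_y=knee_y,
        theta_shank=theta, knee_moment=moment,
        body_mass=cfg.body_mass, foot_length=cfg.foot_length,
        lower_leg_length=cfg.lower_leg_length,
    )


# ---------------------------------------------------------------------------
# scaling & resampling


def scale_to_user(ref: ReferenceGait, user: UserCharacteristics) -> ReferenceGait:
    """Scale a reference gait to a user's body characteristics.

    GRFs scale with body mass, CoP locations with foot length and the lower
    leg trajectory (knee coordinates) with lower leg length; the shank angle
    is dimensionless and kept.  Knee moments scale with
    ``mass_ratio * lower_leg_ratio`` (force times body-geometry lever arm).
    """
    if min(ref.body_mass, ref.foot_length, ref.lower_leg_length) <= 0:
        raise GaitValidationError("reference body parameters must be positive")
    mass_r = user.body_mass / ref.body_mass
    foot_r = user.foot_length / ref.foot_length
    leg_r = user.lower_leg_length / ref.lower_leg_length
    return ReferenceGait(
        stance_percent=ref.stance_percent.copy(),
        grf_x=ref.grf_x * mass_r,
        grf_y=ref.grf_y * mass_r,
        cop_x=ref.cop_x * foot_r,
        knee_x=ref.knee_x * leg_r,
        knee_y=ref.knee_y * leg_r,
        theta_shank=ref.theta_shank.copy(),
        knee_moment=ref.knee_moment * (mass_r * leg_r),
        body_mass=user.body_mass,
        foot_length=user.foot_length,
        lower_leg_length=user.lower_leg_length,
    )


def _interp(ref: ReferenceGait, name: str, percents: np.ndarray) -> np.ndarray:
    return np.interp(percents, ref.stance_percent, getattr(ref, name))


def resample_stance(ref: ReferenceGait,
                    percents=None,
                    zones: RegimeZones | None = None) -> list[LoadCase]:
    """Linearly interpolate the gait table at the requested stance percents.

    Returns one :class:`LoadCase` per percent, with the contact regime
    assigned from ``zones``.  The default percents are the nine
    representative instances at 8, 20, 27, 36, 50, 62, 75, 80 and 82% of
    stance.
    """
    if percents is None:
        percents = NINE_INSTANCE_PERCENTS
    percents = np.asarray(percents, dtype=float)
    if percents.size == 0:
        raise GaitValidationError("percents list must not be empty")
    if np.any(percents < 0) or np.any(percents > 100):
        raise GaitValidationError("percents must lie within [0, 100]")
    zones = zones or RegimeZones()
    cols = {name: _interp(ref, name, percents)
            for name in ("grf_x", "grf_y", "cop_x", "knee_moment")}
    return [
        LoadCase(stance_percent=float(p),
                 grf=np.array([cols["grf_x"][i], cols["grf_y"][i]]),
                 cop_x=float(cols["cop_x"][i]),
                 knee_moment=float(cols["knee_moment"][i]),
                 regime=zones.regime(float(p)))
        for i, p in enumerate(percents)
    ]


def reference_pose_at(ref: ReferenceGait, percents) -> dict[str, np.ndarray]:
    """Interpolated reference lower-leg pose (knee_x, knee_y, theta_shank) at ``percents``."""
    percents = np.asarray(percents, dtype=float)
    return {name: _interp(ref, name, percents)
            for name in ("knee_x", "knee_y", "theta_shank")}
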