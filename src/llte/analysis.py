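"""Gait-analysis computations on marker + force-plate step recordings.

Implements the evaluation metrics used to assess prosthetic feet during
over-ground walking: stance detection, stance-percent normalization,
spatiotemporal parameters (walking speed, Froude number, stance-time
symmetry index, step width, trunk sway), foot-shank angles, roll-over shape
radius and effective foot length ratio, unified-deformable-segment foot
power and energy return, step-to-step transition (collision/propulsion)
work of the center of mass, and normalized-RMSE deviation scores against a
reference walking pattern.

Axes: x is the direction of travel, y is up, z is lateral.  Marker data are
sampled at 120 Hz and force-plate data at 960 Hz by convention (both rates
are carried explicitly).  Kinematic series are low-pass filtered at 6 Hz
and kinetic series at 12 Hz with a fourth-order zero-phase (bidirectional)
Butterworth filter before event detection; ground contact is defined by a
40 N vertical GRF threshold.

A synthetic step-recording generator with known ground truth for every
metric is included for testing; see :func:`synthesize_step_recording`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .gait import ReferenceGait, UserCharacteristics

__all__ = [
    "PlateSeries",
    "StepRecording",
    "GaitSummary",
    "DeviationScore",
    "RecordingConfig",
    "lowpass_filter",
    "detect_stance",
    "normalize_to_stance",
    "virtual_knee_correction",
    "spatiotemporal",
    "foot_angles",
    "rollover",
    "foot_power_and_energy",
    "com_transition_work",
    "deviation_scores",
    "synthesize_step_recording",
    "PROSTHETIC",
    "INTACT",
]

PROSTHETIC = "prosthetic"
INTACT = "intact"
GRAVITY = 9.81


@dataclass
class PlateSeries:
    """Force-plate output for one limb: GRF, CoP and free moment."""

    grf: np.ndarray  # (T, 3) N
    cop: np.ndarray  # (T, 3) m (y = 0 on the ground)
    free_moment: np.ndarray  # (T,) N*m, sagittal couple (about z)


@dataclass
class StepRecording:
    """Marker trajectories plus per-limb force-plate series for >= 1 stride."""

    marker_time: np.ndarray  # (Tm,) s
    markers: dict[str, np.ndarray]  # name -> (Tm, 3) m
    plate_time: np.ndarray  # (Tp,) s
    plates: dict[str, PlateSeries]  # side -> series
    marker_rate: float  # Hz
    plate_rate: float  # Hz
    body_mass: float  # kg
    foot_length: float  # m
    lower_leg_length: float  # m
    leg_length: float  # m, hip (greater trochanter) to floor, for Froude
    ground_truth: dict = field(default_factory=dict)

    def marker(self, side: str, name: str) -> np.ndarray:
        return self.markers[f"{side}_{name}"]


@dataclass(frozen=True)
class GaitSummary:
    walking_speed: float  # m/s
    froude: float
    stance_symmetry: float  # %, 100 = perfect
    step_width: float  # m
    trunk_sway_range: float  # deg
    peak_dorsiflexion: float  # deg
    peak_plantarflexion: float  # deg
    neutral_angle: float  # deg
    rollover_radius: float  # m/m (normalized by lower leg length)
    eflr: float  # effective foot length / foot length
    energy_return: float  # J/kg
    peak_push_off_power: float  # W/kg
    collision_work: dict  # side -> J/kg
    propulsion_work: dict  # side -> J/kg


@dataclass(frozen=True)
class DeviationScore:
    """Per-leg NRMSE deviations from the reference pattern, and their total."""

    per_leg: dict  # side -> {channel: nrmse}
    total: float

    CHANNELS = ("grf_x", "grf_y", "cop_x", "knee_x", "knee_y", "theta_shank")


# ---------------------------------------------------------------------------
# signal processing primitives


def lowpass_filter(series: np.ndarray, sample_rate: float, cutoff_hz: float,
                   order: int = 4) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (forward-backward).

    Defaults follow the standard gait pipeline: 6 Hz for kinematic and
    12 Hz for kinetic data, order 4 applied bidirectionally.
    """
    if cutoff_hz >= sample_rate / 2.0:
        raise ValueError("cutoff must be below the Nyquist frequency")
    if sample_rate <= 2.0 * cutoff_hz:
        raise ValueError("sample rate must exceed twice the cutoff")
    b, a = butter(order, cutoff_hz / (sample_rate / 2.0), btype="low")
    return filtfilt(b, a, np.asarray(series, dtype=float), axis=0)


def detect_stance(grf_vertical: np.ndarray, sample_rate: float,
                  threshold_N: float = 40.0) -> list[tuple[int, int]]:
    """Maximal sample intervals with vertical GRF >= threshold.

    Returns ``(start, stop)`` index pairs (stop exclusive).  Gaps shorter
    than 10 ms between intervals (signal chatter near the threshold) are
    merged.
    """
    above = np.asarray(grf_vertical, dtype=float) >= threshold_N
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = list(edges[~above[edges]] + 1)
    stops = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(above.size)
    intervals = list(zip(starts, stops))
    min_gap = int(round(0.010 * sample_rate))
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        if s - merged[-1][1] <= min_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def normalize_to_stance(series: np.ndarray, interval: tuple[int, int],
                        n_points: int = 100) -> np.ndarray:
    """Resample ``series`` over ``interval`` onto a 0-100% stance grid."""
    s, e = interval
    if e - s < 2:
        raise ValueError("stance interval must span at least 2 samples")
    series = np.asarray(series, dtype=float)
    seg = series[s:e]
    src = np.linspace(0.0, 100.0, seg.shape[0])
    dst = np.linspace(0.0, 100.0, n_points)
    if seg.ndim == 1:
        return np.interp(dst, src, seg)
    return np.column_stack([np.interp(dst, src, seg[:, k]) for k in range(seg.shape[1])])


def virtual_knee_correction(knee_marker: np.ndarray, ankle_marker: np.ndarray,
                            calibration_frame: int) -> np.ndarray:
    """Virtual knee marker vertically above the ankle at calibration.

    At the calibration frame (foot flat and unloaded) the physical knee
    marker generally sits at a sagittal offset angle from the vertical
    through the ankle.  The virtual marker keeps the physical knee-ankle
    distance but removes that offset; the offset angle is held constant, so
    the virtual point rotates rigidly with the shank thereafter.
    """
    knee = np.asarray(knee_marker, dtype=float)
    ankle = np.asarray(ankle_marker, dtype=float)
    r0 = knee[calibration_frame] - ankle[calibration_frame]
    d0 = np.hypot(r0[0], r0[1])
    if d0 < 1e-12:
        raise ValueError("knee and ankle markers coincide at calibration")
    offset = np.arctan2(r0[0], r0[1])  # sagittal angle from vertical
    c, s = np.cos(-offset), np.sin(-offset)
    rel = knee - ankle
    out = knee.copy()
    out[:, 0] = ankle[:, 0] + c * rel[:, 0] + s * rel[:, 1]
    out[:, 1] = ankle[:, 1] - s * rel[:, 0] + c * rel[:, 1]
    return out


# ---------------------------------------------------------------------------
# spatiotemporal & angles


def _stance_intervals(rec: StepRecording, side: str,
                      filtered: bool = True) -> list[tuple[int, int]]:
    fy = rec.plates[side].grf[:, 1]
    if filtered:
        fy = lowpass_filter(fy, rec.plate_rate, 12.0)
    return detect_stance(fy, rec.plate_rate)


def _symmetry_index(x_p: float, x_s: float) -> float:
    denom = 0.5 * abs(x_p + x_s)
    if denom < 1e-12:
        raise ValueError("symmetry index undefined for zero total stance time")
    return 100.0 * (1.0 - abs(x_p - x_s) / denom)


def spatiotemporal(rec: StepRecording):
    """Walking speed, Froude number, stance symmetry, step width, trunk sway.

    Speed is the average sacrum velocity along the direction of travel;
    ``Fr = v^2 / (g L)`` with L the hip-to-floor leg length; the symmetry
    index uses the mean stance times of the prosthetic and intact sides;
    step width is the average lateral ankle-to-ankle distance at foot
    contact; trunk sway is the range of the frontal-plane lean angle of the
    shoulders-sacrum frame.
    """
    sacrum = lowpass_filter(rec.markers["sacrum"], rec.marker_rate, 6.0)
    duration = rec.marker_time[-1] - rec.marker_time[0]
    speed = float((sacrum[-1, 0] - sacrum[0, 0]) / duration)
    froude = speed**2 / (GRAVITY * rec.leg_length)

    stances = {side: _stance_intervals(rec, side) for side in (PROSTHETIC, INTACT)}
    times = {}
    for side, iv in stances.items():
        if not iv:
            raise ValueError(f"no stance detected on the {side} side")
        times[side] = float(np.mean([(e - s) / rec.plate_rate for s, e in iv]))
    si = _symmetry_index(times[PROSTHETIC], times[INTACT])

    # step width: lateral ankle separation at each contact event
    widths = []
    for side, iv in stances.items():
        other = INTACT if side == PROSTHETIC else PROSTHETIC
        for s, _ in iv:
            t0 = rec.plate_time[s]
            k = int(np.argmin(np.abs(rec.marker_time - t0)))
            widths.append(abs(rec.marker(side, "ankle")[k, 2]
                              - rec.marker(other, "ankle")[k, 2]))
    step_width = float(np.mean(widths))

    mid_sh = 0.5 * (rec.markers["shoulder_l"] + rec.markers["shoulder_r"])
    mid_sh = lowpass_filter(mid_sh, rec.marker_rate, 6.0)
    trunk = mid_sh - sacrum
    lean = np.degrees(np.arctan2(trunk[:, 2], trunk[:, 1]))  # frontal plane
    sway_range = float(lean.max() - lean.min())

    return {
        "walking_speed": speed,
        "froude": float(froude),
        "stance_symmetry": float(si),
        "step_width": step_width,
        "trunk_sway_range": sway_range,
        "stance_times": times,
    }


def foot_angles(rec: StepRecording, side: str = PROSTHETIC):
    """Peak dorsiflexion/plantarflexion (deg, relative to neutral) and neutral angle.

    The foot-shank angle is the sagittal-plane angle between the foot
    segment (heel -> toe) and the shank segment (ankle -> knee); the
    neutral angle is its mean during swing, when the prosthesis is
    unloaded.  Dorsiflexion (foot toward the shin) is positive.
    """
    heel = lowpass_filter(rec.marker(side, "heel"), rec.marker_rate, 6.0)
    toe = lowpass_filter(rec.marker(side, "toe"), rec.marker_rate, 6.0)
    ankle = lowpass_filter(rec.marker(side, "ankle"), rec.marker_rate, 6.0)
    knee = lowpass_filter(rec.marker(side, "knee"), rec.marker_rate, 6.0)
    foot_v = toe - heel
    shank_v = knee - ankle
    ang_foot = np.arctan2(foot_v[:, 1], foot_v[:, 0])
    ang_shank = np.arctan2(shank_v[:, 1], shank_v[:, 0])
    alpha = np.degrees(ang_shank - ang_foot)  # segment-to-segment angle

    stance = _stance_intervals(rec, side)
    in_stance = np.zeros(rec.marker_time.size, dtype=bool)
    for s, e in stance:
        t0, t1 = rec.plate_time[s], rec.plate_time[min(e, rec.plate_time.size - 1)]
        in_stance |= (rec.marker_time >= t0) & (rec.marker_time <= t1)
    swing = ~in_stance
    if not swing.any():
        raise ValueError("no swing samples available to define the neutral angle")
    neutral = float(np.mean(alpha[swing]))
    dorsi = neutral - alpha  # foot toward shin closes the segment angle
    return {
        "peak_dorsiflexion": float(np.max(dorsi[in_stance])),
        "peak_plantarflexion": float(np.max(-dorsi[in_stance])),
        "neutral_angle": neutral,
        "angle_series": alpha,
        "dorsiflexion_series": dorsi,
    }


# ---------------------------------------------------------------------------
# roll-over shape, foot power, CoM work


def _fit_circle(xy: np.ndarray):
    """Algebraic least-squares circle fit; returns (center, radius)."""
    if xy.shape[0] < 3:
        raise ValueError("need at least 3 points for a circle fit")
    x, y = xy[:, 0], xy[:, 1]
    if np.ptp(x) < 1e-9 and np.ptp(y) < 1e-9:
        raise ValueError("degenerate roll-over shape: CoP does not progress")
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r = np.sqrt(c + cx**2 + cy**2)
    return np.array([cx, cy]), float(r)


def _marker_index(rec: StepRecording, t: float) -> int:
    return int(np.argmin(np.abs(rec.marker_time - t)))


def _resample_to(t_src: np.ndarray, values: np.ndarray,
                 t_query: np.ndarray) -> np.ndarray:
    """Linear resampling of a marker-rate series onto plate-rate times."""
    return np.interp(t_query, t_src, values)


def _filter_in_stance(series: np.ndarray, rate: float, cutoff: float,
                      interval: tuple[int, int]) -> np.ndarray:
    """Low-pass filter a kinetic series over one stance interval only.

    The CoP is undefined (zero) outside ground contact, so filtering across
    the stance edges would smear spurious steps into the window.
    """
    out = np.array(series, dtype=float, copy=True)
    s, e = interval
    out[s:e] = lowpass_filter(series[s:e], rate, cutoff)
    return out


def rollover(rec: StepRecording, side: str = PROSTHETIC):
    """Roll-over shape radius (normalized), effective foot length and EFLR.

    The CoP from heel strike to the *opposite* heel strike is transformed
    into a shank-fixed sagittal frame (origin at the ankle, y along the
    shank) and fitted with a least-squares circle; the radius is normalized
    by the lower leg length.  The effective foot length is the heel-to-CoP
    distance at opposite heel contact, and the EFLR its ratio to the
    physical foot length.
    """
    own = _stance_intervals(rec, side)
    other = _stance_intervals(rec, INTACT if side == PROSTHETIC else PROSTHETIC)
    if not own or not other:
        raise ValueError("need stance events on both sides")
    s0, e0 = own[0]
    t_hs = rec.plate_time[s0]
    later = [iv for iv in other if rec.plate_time[iv[0]] > t_hs + 0.05]
    if not later:
        raise ValueError("no opposite heel strike after the analyzed heel strike")
    t_ohs = rec.plate_time[later[0][0]]

    plate = rec.plates[side]
    cop = _filter_in_stance(plate.cop, rec.plate_rate, 12.0, (s0, e0))
    ankle = lowpass_filter(rec.marker(side, "ankle"), rec.marker_rate, 6.0)
    knee = lowpass_filter(rec.marker(side, "knee"), rec.marker_rate, 6.0)

    mask = (rec.plate_time >= t_hs) & (rec.plate_time <= t_ohs)
    tq = rec.plate_time[mask]
    ax = _resample_to(rec.marker_time, ankle[:, 0], tq)
    ay = _resample_to(rec.marker_time, ankle[:, 1], tq)
    sx = _resample_to(rec.marker_time, (knee - ankle)[:, 0], tq)
    sy = _resample_to(rec.marker_time, (knee - ankle)[:, 1], tq)
    th = np.arctan2(sx, sy)  # shank tilt from vertical
    rx = cop[mask, 0] - ax
    ry = cop[mask, 1] - ay
    c, s = np.cos(th), np.sin(th)
    # lab -> shank frame: rotate so the shank maps onto the +y axis
    pts = np.column_stack([c * rx - s * ry, s * rx + c * ry])
    _, radius = _fit_circle(pts)

    k_ohs = _marker_index(rec, t_ohs)
    j_ohs = int(np.argmin(np.abs(rec.plate_time - t_ohs)))
    heel = rec.marker(side, "heel")[k_ohs]
    efl = float(abs(cop[j_ohs, 0] - heel[0]))
    return {
        "radius": radius / rec.lower_leg_length,
        "effective_foot_length": efl,
        "eflr": efl / rec.foot_length,
    }


def foot_power_and_energy(rec: StepRecording, side: str = PROSTHETIC):
    """Distal shank (unified deformable segment) power, energy return and
    peak push-off power, normalized to body mass.

    ``P = F . v_cop + M_free * omega`` where ``v_cop`` is the velocity of
    the shank-rigid-body material point instantaneously at the CoP.  The
    energy returned is the time integral of the positive power from its
    final negative-to-positive crossing to toe-off; the net stance work is
    also reported.  A missing free moment is treated as zero and flagged.
    """
    stance = _stance_intervals(rec, side)
    if not stance:
        raise ValueError("no stance interval")
    s0, e0 = stance[0]
    plate = rec.plates[side]
    grf = lowpass_filter(plate.grf, rec.plate_rate, 12.0)
    cop = _filter_in_stance(plate.cop, rec.plate_rate, 12.0, (s0, e0))
    if plate.free_moment is None:
        mfree = np.zeros(rec.plate_time.size)
        flagged = True
    else:
        mfree = lowpass_filter(plate.free_moment, rec.plate_rate, 12.0)
        flagged = False

    ankle = lowpass_filter(rec.marker(side, "ankle"), rec.marker_rate, 6.0)
    knee = lowpass_filter(rec.marker(side, "knee"), rec.marker_rate, 6.0)
    dt_m = 1.0 / rec.marker_rate
    v_ankle = np.gradient(ankle, dt_m, axis=0)
    shank = knee - ankle
    theta = np.unwrap(np.arctan2(shank[:, 1], shank[:, 0]))
    omega = np.gradient(theta, dt_m)

    tt = rec.plate_time[s0:e0]
    ax = _resample_to(rec.marker_time, ankle[:, 0], tt)
    ay = _resample_to(rec.marker_time, ankle[:, 1], tt)
    vx = _resample_to(rec.marker_time, v_ankle[:, 0], tt)
    vy = _resample_to(rec.marker_time, v_ankle[:, 1], tt)
    om = _resample_to(rec.marker_time, omega, tt)
    rx = cop[s0:e0, 0] - ax
    ry = cop[s0:e0, 1] - ay
    # velocity of the shank material point instantaneously at the CoP
    vcx = vx - om * ry
    vcy = vy + om * rx
    power = (grf[s0:e0, 0] * vcx + grf[s0:e0, 1] * vcy
             + mfree[s0:e0] * om) / rec.body_mass

    net_work = float(np.trapezoid(power, tt))
    # final negative-to-positive crossing
    sign = power > 0
    crossings = np.flatnonzero(~sign[:-1] & sign[1:])
    start = int(crossings[-1]) + 1 if crossings.size else 0
    energy_return = float(np.trapezoid(np.clip(power[start:], 0.0, None), tt[start:]))
    peak = float(np.max(power[start:])) if start < power.size else 0.0
    return {
        "power": power,
        "time": tt,
        "energy_return": energy_return,
        "net_work": net_work,
        "peak_push_off_power": peak,
        "free_moment_missing": flagged,
    }


def com_transition_work(rec: StepRecording):
    """Collision and propulsion work per limb over the step-to-step transitions.

    The CoM velocity is obtained by integrating ``(sum(GRF) - weight)/mass``
    over one stride with periodicity constraints (mean forward velocity
    equal to the walking speed, zero mean vertical velocity).  Per-limb
    external power is ``GRF_limb . v_com``; collision work integrates the
    negative power of the leading limb over double support, propulsion the
    positive power of the trailing limb.  Results in J/kg.
    """
    iv_p = _stance_intervals(rec, PROSTHETIC)
    iv_i = _stance_intervals(rec, INTACT)
    if len(iv_p) < 2:
        raise ValueError("need a full stride (two stances of the same leg)")
    s_start, s_end = iv_p[0][0], iv_p[1][0]  # one stride
    t = rec.plate_time[s_start:s_end]
    dt = 1.0 / rec.plate_rate

    grf = {side: lowpass_filter(rec.plates[side].grf[:, :2], rec.plate_rate, 12.0)
           for side in (PROSTHETIC, INTACT)}
    total = grf[PROSTHETIC][s_start:s_end] + grf[INTACT][s_start:s_end]
    acc = total / rec.body_mass
    acc[:, 1] -= GRAVITY
    v = np.cumsum(acc, axis=0) * dt
    speed = spatiotemporal(rec)["walking_speed"]
    v[:, 0] += speed - v[:, 0].mean()
    v[:, 1] -= v[:, 1].mean()

    # double-support windows inside the stride
    intervals = {PROSTHETIC: iv_p, INTACT: iv_i}

    def support_mask(side):
        mask = np.zeros(rec.plate_time.size, dtype=bool)
        for s, e in intervals[side]:
            mask[s:e] = True
        return mask[s_start:s_end]

    both = support_mask(PROSTHETIC) & support_mask(INTACT)
    collision = {PROSTHETIC: 0.0, INTACT: 0.0}
    propulsion = {PROSTHETIC: 0.0, INTACT: 0.0}
    # label each double-support run by its leading (just-landed) limb
    runs = []
    j = 0
    while j < both.size:
        if both[j]:
            k = j
            while k < both.size and both[k]:
                k += 1
            runs.append((j, k))
            j = k
        else:
            j += 1
    for a, b in runs:
        j_abs = s_start + a
        # leading limb: the one whose stance started most recently
        def last_start(side):
            starts = [s for s, e in intervals[side] if s <= j_abs]
            return max(starts) if starts else -np.inf
        lead = PROSTHETIC if last_start(PROSTHETIC) > last_start(INTACT) else INTACT
        trail = INTACT if lead == PROSTHETIC else PROSTHETIC
        for side, bucket, keep in ((lead, collision, "neg"), (trail, propulsion, "pos")):
            p = np.einsum("ij,ij->i", grf[side][s_start + a:s_start + b], v[a:b])
            p = np.clip(p, None, 0.0) if keep == "neg" else np.clip(p, 0.0, None)
            bucket[side] += float(np.trapezoid(p, dx=dt)) / rec.body_mass
    return {"collision": collision, "propulsion": propulsion}


def deviation_scores(measured: dict, ref: ReferenceGait,
                     user: UserCharacteristics) -> DeviationScore:
    """NRMSE deviation of a percent-normalized step from the reference pattern.

    ``measured`` maps each leg to a dict of the six channels (``grf_x``,
    ``grf_y``, ``cop_x``, ``knee_x``, ``knee_y``, ``theta_shank``) sampled
    on the same stance-percent grid as the reference comparison curves.
    GRFs are normalized by body weight, CoP by foot length, knee
    coordinates by lower leg length and the shank angle by the reference
    angle range; the total is the sum over both legs and all six scores.
    """
    from .gait import _interp  # same linear interpolation as resampling

    bw = user.body_mass * GRAVITY
    theta_range = float(np.ptp(ref.theta_shank))
    normalizers = {
        "grf_x": bw, "grf_y": bw,
        "cop_x": user.foot_length,
        "knee_x": user.lower_leg_length, "knee_y": user.lower_leg_length,
        "theta_shank": theta_range,
    }
    per_leg = {}
    total = 0.0
    for leg, channels in measured.items():
        n = len(next(iter(channels.values())))
        grid = np.linspace(0.0, 100.0, n)
        scores = {}
        for ch in DeviationScore.CHANNELS:
            if ch not in channels:
                raise ValueError(f"measured data for {leg!r} missing channel {ch!r}")
            arr = np.asarray(channels[ch], dtype=float)
            if arr.shape != (n,):
                raise ValueError("channel grids do not match")
            ref_curve = _interp(ref, ch, grid)
            rmse = float(np.sqrt(np.mean((arr - ref_curve) ** 2)))
            scores[ch] = rmse / normalizers[ch]
            total += scores[ch]
        per_leg[leg] = scores
    return DeviationScore(per_leg=per_leg, total=float(total))


# ---------------------------------------------------------------------------
# synthetic recording generator


@dataclass(frozen=True)
class RecordingConfig:
    """Programmed gait features of the synthetic step recording.

    The generator builds a rigid rolling-rocker leg model per side (the
    roll-over shape of the ankle-foot system is a circular arc of
    ``rocker_radius``), with an optional elastic compression mode that
    stores and returns a prescribed energy budget through the distal
    structure.  All derived ground truths are stored on the recording.
    """

    body_mass: float = 70.0  # kg
    foot_length: float = 0.26  # m
    lower_leg_length: float = 0.44  # m
    leg_length: float = 0.90  # m, hip to floor
    walking_speed: float = 1.18  # m/s, able-bodied self-selected
    stride_time: float = 1.10  # s
    stance_time_prosthetic: float = 0.62  # s
    stance_time_intact: float = 0.62  # s
    rocker_radius: float = 0.15  # m
    step_width: float = 0.12  # m
    trunk_sway_amp: float = 2.0  # deg
    dorsiflexion_peak: float = 11.0  # deg
    elastic_work_budget: float = 0.0  # J/kg returned per prosthetic-side step
    theta_start: float = -15.0  # deg, shank angle at heel strike
    theta_end: float = 25.0  # deg, at toe-off
    grf_peak_bw: float = 1.2
    grf_valley_bw: float = 0.4
    grf_ap_bw: float = 0.16
    marker_rate: float = 120.0
    plate_rate: float = 960.0
    n_strides: float = 2.6
    noise_m: float = 0.0  # marker noise amplitude

    def __post_init__(self) -> None:
        if self.elastic_work_budget < 0:
            raise ValueError("elastic work budget must be non-negative")
        if min(self.body_mass, self.foot_length, self.lower_leg_length,
               self.walking_speed, self.stride_time) <= 0:
            raise ValueError("all body/gait parameters must be positive")
        if max(self.stance_time_prosthetic, self.stance_time_intact) >= self.stride_time:
            raise ValueError("stance time must be below the stride time")


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return 3 * x**2 - 2 * x**3


def _grf_shape(tau, cfg: RecordingConfig):
    """Dimensionless double-bump vertical and sinusoidal fore-aft shapes."""
    fy = cfg.grf_peak_bw * np.sin(np.pi * tau) + cfg.grf_valley_bw * np.sin(3 * np.pi * tau)
    fx = -cfg.grf_ap_bw * np.sin(2 * np.pi * tau)
    return np.clip(fy, 0.0, None), fx


def synthesize_step_recording(config: RecordingConfig | None = None,
                              seed: int = 0) -> StepRecording:
    """Generate a marker + force-plate recording with known ground truth.

    Deterministic per ``(config, seed)``.  Ground truths stored on the
    recording: stance intervals (threshold-crossing times), walking speed,
    stance-time symmetry index, rocker radius, trunk sway range,
    dorsiflexion peak and the elastic energy budget.
    """
    cfg = config or RecordingConfig()
    rng = np.random.default_rng(seed)
    T = cfg.n_strides * cfg.stride_time
    t_m = np.arange(0.0, T, 1.0 / cfg.marker_rate)
    t_p = np.arange(0.0, T, 1.0 / cfg.plate_rate)

    sides = (PROSTHETIC, INTACT)
    stance_time = {PROSTHETIC: cfg.stance_time_prosthetic,
                   INTACT: cfg.stance_time_intact}
    z_side = {PROSTHETIC: +cfg.step_width / 2.0, INTACT: -cfg.step_width / 2.0}
    # the intact side leads so the prosthetic heel strike lands during an
    # intact stance already on record (full double support available)
    first_hs = {INTACT: 0.15, PROSTHETIC: 0.15 + cfg.stride_time / 2.0}

    bw = cfg.body_mass * GRAVITY
    # calibrate the vertical amplitude so the stride-mean total GRF is one BW
    tau_fine = np.linspace(0, 1, 2001)
    fy_shape, _ = _grf_shape(tau_fine, cfg)
    shape_mean = float(np.trapezoid(fy_shape, tau_fine))
    total_stance = stance_time[PROSTHETIC] + stance_time[INTACT]
    amp = bw * cfg.stride_time / (shape_mean * total_stance)

    R = cfg.rocker_radius
    th0, th1 = np.radians(cfg.theta_start), np.radians(cfg.theta_end)
    h_ankle = 0.08  # ankle marker height above ground at neutral
    knee_h = h_ankle + cfg.lower_leg_length * 0.8

    # per-side stance windows within the recording
    def stance_windows(side):
        out = []
        t0 = first_hs[side]
        while t0 + stance_time[side] < T:
            out.append((t0, t0 + stance_time[side]))
            t0 += cfg.stride_time
        return out

    windows = {side: stance_windows(side) for side in sides}

    # forward progression: rocker roll advances R*(th1-th0) per stance; the
    # remaining stride length is covered during swing
    stride_len = cfg.walking_speed * cfg.stride_time

    # elastic compression amplitude from the requested energy budget
    if cfg.elastic_work_budget > 0:
        st = stance_time[PROSTHETIC]
        tt = np.linspace(0, st, 4001)
        tau = tt / st
        fy = amp * _grf_shape(tau, cfg)[0]
        ddot_unit = (np.pi / st) * np.cos(np.pi * tau)  # d/dt of sin(pi tau)
        p_unit = -fy * ddot_unit  # power per unit compression amplitude
        e_unit = float(np.trapezoid(np.clip(p_unit, 0.0, None), tt))
        delta0 = cfg.elastic_work_budget * cfg.body_mass / e_unit
    else:
        delta0 = 0.0

    def leg_state(side, t):
        """Rocker-center x, shank angle, compression at marker/any time t."""
        wins = windows[side]
        roll_len = R * (th1 - th0)
        # anchor: rocker-center x at each heel strike tracks body progression
        xc_hs = [cfg.walking_speed * first_hs[side] + stride_len * k
                 for k in range(len(wins) + 1)]
        for k, (a, b) in enumerate(wins):
            if t < a:  # swing before this stance (or lead-in)
                if k == 0:
                    return xc_hs[0], th0, 0.0, False
                pa, pb = wins[k - 1][1], a
                u = _smoothstep((t - pa) / (pb - pa))
                x = (xc_hs[k - 1] + roll_len) + u * (xc_hs[k] - xc_hs[k - 1] - roll_len)
                th = th1 + u * (th0 - th1)
                return x, th, 0.0, False
            if a <= t <= b:
                tau = (t - a) / (b - a)
                th = th0 + (th1 - th0) * _smoothstep(tau)
                x = xc_hs[k] + R * (th - th0)
                comp = (delta0 * np.sin(np.pi * tau)
                        if side == PROSTHETIC else 0.0)
                return x, th, comp, True
        # tail after final stance
        return xc_hs[len(wins) - 1] + roll_len, th1, 0.0, False

    markers = {}
    for side in sides:
        z = z_side[side]
        n = t_m.size
        ankle = np.zeros((n, 3))
        knee = np.zeros((n, 3))
        shank_m = np.zeros((n, 3))
        heel = np.zeros((n, 3))
        toe = np.zeros((n, 3))
        for i, t in enumerate(t_m):
            xc, th, comp, in_st = leg_state(side, t)
            c, s = np.cos(th), np.sin(th)
            center = np.array([xc, R - comp])

            def body_pt(off):
                ox, oy = off
                return center + np.array([c * ox + s * oy, -s * ox + c * oy])

            a_pt = body_pt((0.0, h_ankle - R))
            k_pt = body_pt((0.0, knee_h - R))
            ankle[i, :2], ankle[i, 2] = a_pt, z
            knee[i, :2], knee[i, 2] = k_pt, z
            shank_m[i, :2], shank_m[i, 2] = body_pt((0.0, (h_ankle + knee_h) / 2 - R)), z
            # foot segment pitched about the ankle: dorsiflexion closes the
            # foot-shank angle, zero deviation during swing (foot rigid with shank)
            if in_st:
                a0, b0 = next((a, b) for a, b in windows[side] if a <= t <= b)
                tau = (t - a0) / (b0 - a0)
                dorsi = np.radians(cfg.dorsiflexion_peak) * np.sin(np.pi * tau) ** 2
            else:
                dorsi = 0.0
            g = th - dorsi  # forward-tilt foot pitch (same convention as body_pt)
            cg, sg = np.cos(g), np.sin(g)
            for arr, (ox, oy) in ((heel, (-0.25 * cfg.foot_length, -h_ankle)),
                                  (toe, (0.75 * cfg.foot_length, -h_ankle))):
                pt = a_pt + np.array([cg * ox + sg * oy, -sg * ox + cg * oy])
                arr[i, :2], arr[i, 2] = pt, z
        for name, arr in (("ankle", ankle), ("knee", knee), ("shank", shank_m),
                          ("heel", heel), ("toe", toe)):
            if cfg.noise_m > 0:
                arr = arr + rng.normal(0.0, cfg.noise_m, arr.shape)
            markers[f"{side}_{name}"] = arr

    # trunk markers
    n = t_m.size
    phase = 2 * np.pi * t_m / cfg.stride_time
    sacrum = np.zeros((n, 3))
    sacrum[:, 0] = cfg.walking_speed * t_m + 0.004 * np.sin(phase)
    sacrum[:, 1] = 0.95 + 0.01 * np.sin(2 * phase)
    sacrum[:, 2] = 0.01 * np.sin(phase)
    sway = np.radians(cfg.trunk_sway_amp) * np.sin(phase)
    trunk_len, half_sh = 0.50, 0.20
    mid = sacrum + np.column_stack([np.zeros(n), trunk_len * np.cos(sway),
                                    trunk_len * np.sin(sway)])
    lat = np.column_stack([np.zeros(n), -half_sh * np.sin(sway),
                           half_sh * np.cos(sway)])
    markers["shoulder_l"] = mid + lat
    markers["shoulder_r"] = mid - lat
    markers["sacrum"] = sacrum

    # force plates
    plates = {}
    truth_intervals = {}
    for side in sides:
        grf = np.zeros((t_p.size, 3))
        cop = np.zeros((t_p.size, 3))
        cop[:, 2] = z_side[side]
        for a, b in windows[side]:
            mask = (t_p >= a) & (t_p <= b)
            tau = (t_p[mask] - a) / (b - a)
            fy, fx = _grf_shape(tau, cfg)
            grf[mask, 0] = amp * fx
            grf[mask, 1] = amp * fy
            for j in np.flatnonzero(mask):
                xc, th, comp, _ = leg_state(side, t_p[j])
                cop[j, 0] = xc  # contact point below the rocker center
        plates[side] = PlateSeries(grf=grf, cop=cop,
                                   free_moment=np.zeros(t_p.size))
        # ground-truth threshold crossings of the unfiltered shape
        ivs = []
        for a, b in windows[side]:
            tau_c = _crossing_tau(amp, cfg, 40.0)
            ivs.append((a + tau_c * (b - a), b - tau_c * (b - a)))
        truth_intervals[side] = ivs

    truth = {
        "stance_intervals": truth_intervals,
        "walking_speed": cfg.walking_speed,
        "stance_symmetry": _symmetry_index(cfg.stance_time_prosthetic,
                                           cfg.stance_time_intact),
        "rocker_radius": R,
        "rocker_radius_normalized": R / cfg.lower_leg_length,
        "trunk_sway_range": 2.0 * cfg.trunk_sway_amp,
        "dorsiflexion_peak": cfg.dorsiflexion_peak,
        "elastic_work_budget": cfg.elastic_work_budget,
    }
    return StepRecording(
        marker_time=t_m, markers=markers, plate_time=t_p, plates=plates,
        marker_rate=cfg.marker_rate, plate_rate=cfg.plate_rate,
        body_mass=cfg.body_mass, foot_length=cfg.foot_length,
        lower_leg_length=cfg.lower_leg_length, leg_length=cfg.leg_length,
        ground_truth=truth,
    )


def _crossing_tau(amp: float, cfg: RecordingConfig, threshold: float) -> float:
    """Stance fraction at which the vertical GRF shape crosses ``threshold``."""
    from scipy.optimize import brentq

    def f(tau):
        return amp * _grf_shape(np.array([tau]), cfg)[0][0] - threshold

    return float(brentq(f, 1e-9, 0.3, xtol=1e-12))
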