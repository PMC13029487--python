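"""Biomechanically parameterized generator of labeled multimodal gait signals.

The generator emulates the signal structure documented for eight daily
activities recorded with a 12-sensor plantar-pressure insole pair and four
lower-limb inertial nodes at 100 Hz:

* dynamic gaits are periodic at the activity cadence, with a per-foot gait
  cycle of ``1 / cadence`` seconds, near-zero plantar pressure during the
  swing phase, a stance phase of ~60% of the cycle for level walking, a
  dual-support period of 10-20% for walking that disappears for running,
  and left/right thigh roll oscillating ~180 degrees out of phase;
* sit-to-stand reproduces the centre-of-gravity transfer wave (heel rise,
  rapid heel drop with a simultaneous forefoot surge, heel restabilization),
  and stand-to-sit its distinct counterpart (heel overshoot with a rapid
  forefoot decay) -- deliberately not a time-mirror of sit-to-stand;
* standing/sitting are constant loading plus noise, with standing pressure
  far above sitting pressure and a heel-dominant distribution.

Waveform kernels (raised-cosine bursts and smoothstep ramps) are smooth,
amplitude-controlled modelling choices; they are not claimed to be measured
pressure profiles.  Noise is additive Gaussian, independent per channel,
with pressure clipped at zero.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .types import (
    ACTIVITIES,
    DYNAMIC_ACTIVITIES,
    RUNNING,
    SAMPLE_RATE,
    SITTING,
    SIT_TO_STAND,
    STANDING,
    STAND_TO_SIT,
    TRANSITIONS,
    WALKING,
    GaitParams,
    Recording,
    SensorLayout,
)

__all__ = [
    "circular_sensor_area",
    "force_to_pressure",
    "transduce_pressure",
    "simulate_activity",
    "simulate_session",
    "gait_phase_stats",
    "STANDING_PROFILE",
    "SITTING_PROFILE",
]

# Per-sensor loading profiles as fractions of ``pressure_peak``:
# [heel medial, heel lateral, arch, metatarsal medial, metatarsal lateral, toe]
STANDING_PROFILE = np.array([0.55, 0.50, 0.15, 0.35, 0.30, 0.20])
SITTING_PROFILE = np.array([0.060, 0.055, 0.020, 0.050, 0.045, 0.030])

# Stance-phase burst parameters: relative weight, bump centre and width on the
# normalized stance axis u in [0, 1] (heel strike -> toe off roll pattern).
_STANCE_WEIGHT = np.array([1.00, 0.90, 0.25, 0.95, 0.80, 0.60])
_STANCE_CENTER = np.array([0.20, 0.22, 0.45, 0.65, 0.65, 0.80])
_STANCE_WIDTH = np.array([0.50, 0.50, 0.60, 0.55, 0.55, 0.45])
_STANCE_FLOOR = 0.35   # baseline fraction of the burst kept over whole stance
_EDGE_RAMP = 0.08      # raised-cosine contact ramp, fraction of stance

_THIGH_PITCH_SITTING = 80.0  # deg; thigh near-horizontal on a chair
_SHANK_PITCH_SITTING = 10.0


# ---------------------------------------------------------------------------
# sensing-chain arithmetic
# ---------------------------------------------------------------------------

def circular_sensor_area(diameter_mm: float) -> float:
    """Area in m^2 of a circular pressure-sensitive zone of given diameter (mm)."""
    if diameter_mm < 0:
        raise ValueError("diameter must be nonnegative")
    r_m = diameter_mm * 1e-3 / 2.0
    return math.pi * r_m**2


def force_to_pressure(force_n: float, area_m2: float) -> float:
    """Pressure in kPa from a normal force (N) on a sensing area (m^2)."""
    if area_m2 <= 0:
        raise ValueError("area must be positive")
    if force_n < 0:
        raise ValueError("force must be nonnegative")
    return force_n / area_m2 / 1e3


def transduce_pressure(
    pressure_kpa: float | np.ndarray,
    layout: SensorLayout | None = None,
    sensor_diameter_mm: float = 7.5,
) -> float | np.ndarray:
    """Map plantar pressure to the DC voltage-divider output.

    Pressure is converted to load over the sensing area, the load to a
    resistance through the monotone decreasing piezoresistive characteristic
    ``R(F) = curve_c / (F + curve_eps)`` (unloaded resistance above 10 MOhm),
    and the resistance to ``supply * R_ref / (R_ref + R_sensor)``.  Output
    voltage therefore increases monotonically with pressure.
    """
    layout = layout or SensorLayout()
    p = np.asarray(pressure_kpa, dtype=float)
    if np.any(p < 0):
        raise ValueError("pressure must be nonnegative")
    area = circular_sensor_area(sensor_diameter_mm)
    force = p * 1e3 * area
    r_sensor = layout.curve_c / (force + layout.curve_eps)
    v = layout.supply_v * layout.divider_ohm / (layout.divider_ohm + r_sensor)
    return float(v) if np.isscalar(pressure_kpa) else v


# ---------------------------------------------------------------------------
# waveform kernels
# ---------------------------------------------------------------------------

def _hann_bump(u: np.ndarray, center: float, width: float) -> np.ndarray:
    """Raised-cosine bump on [center - width/2, center + width/2], peak 1."""
    v = (u - (center - width / 2.0)) / width
    out = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.clip(v, 0.0, 1.0)))
    out[(v <= 0.0) | (v >= 1.0)] = 0.0
    return out


def _smoothstep(s: np.ndarray) -> np.ndarray:
    s = np.clip(s, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def _contact_envelope(u: np.ndarray) -> np.ndarray:
    """Smooth trapezoid over the stance axis: cosine ramps of _EDGE_RAMP."""
    e = np.ones_like(u)
    rise = u < _EDGE_RAMP
    fall = u > 1.0 - _EDGE_RAMP
    e[rise] = 0.5 * (1.0 - np.cos(np.pi * u[rise] / _EDGE_RAMP))
    e[fall] = 0.5 * (1.0 - np.cos(np.pi * (1.0 - u[fall]) / _EDGE_RAMP))
    return e


def _stance_pressure(phase: np.ndarray, stance: float, peak: float) -> np.ndarray:
    """(6, T) pressure of one foot given its cycle phase in [0, 1)."""
    in_stance = phase < stance
    u = np.where(in_stance, phase / stance, 0.0)
    env = _contact_envelope(u) * in_stance
    out = np.zeros((6, phase.size))
    for i in range(6):
        bump = _hann_bump(u, _STANCE_CENTER[i], _STANCE_WIDTH[i])
        out[i] = peak * _STANCE_WEIGHT[i] * env * (
            _STANCE_FLOOR + (1.0 - _STANCE_FLOOR) * bump
        )
    return out


def _slow_wander(rng: np.random.Generator, n: int, sd_deg: float) -> np.ndarray:
    """Zero-mean low-frequency wander (moving-average filtered noise)."""
    if sd_deg <= 0 or n == 0:
        return np.zeros(n)
    win = int(SAMPLE_RATE)  # 1 s smoothing
    raw = rng.standard_normal(n + win)
    kernel = np.hanning(win)
    kernel /= kernel.sum()
    sm = np.convolve(raw, kernel, mode="valid")[:n]
    s = sm.std()
    return sm / s * sd_deg if s > 0 else np.zeros(n)


# ---------------------------------------------------------------------------
# activity synthesis
# ---------------------------------------------------------------------------

def _dynamic_segment(params: GaitParams, n: int, rng: np.random.Generator):
    t = np.arange(n) / SAMPLE_RATE
    cycle_hz = params.cadence  # per-foot cycle rate
    phase_l = (t * cycle_hz) % 1.0
    phase_r = (t * cycle_hz + 0.5) % 1.0

    pressure = np.empty((12, n))
    pressure[:6] = _stance_pressure(phase_l, params.stance_fraction,
                                    params.pressure_peak)
    pressure[6:] = _stance_pressure(phase_r, params.stance_fraction,
                                    params.pressure_peak)

    euler = np.zeros((4, 3, n))
    w = 2.0 * np.pi * cycle_hz * t
    thigh = params.thigh_roll_amp / 2.0
    shank = params.shank_roll_amp / 2.0
    pitch = params.pitch_activity_level / 2.0
    # left leg reference phase; right leg half a cycle behind (anti-phase)
    euler[0, 0] = thigh * np.sin(w)
    euler[1, 0] = thigh * np.sin(w + np.pi)
    euler[2, 0] = shank * np.sin(w + 0.4)
    euler[3, 0] = shank * np.sin(w + np.pi + 0.4)
    # pitch fluctuates twice per cycle (loading + push-off)
    euler[0, 1] = pitch * np.sin(2 * w)
    euler[1, 1] = pitch * np.sin(2 * w + np.pi)
    euler[2, 1] = pitch * np.sin(2 * w + 0.5)
    euler[3, 1] = pitch * np.sin(2 * w + np.pi + 0.5)
    for node in range(4):
        euler[node, 2] = _slow_wander(rng, n, 1.0 * params.yaw_stability)
    return pressure, euler


def _static_segment(params: GaitParams, n: int):
    profile = STANDING_PROFILE if params.activity == STANDING else SITTING_PROFILE
    levels = params.pressure_peak * profile
    pressure = np.repeat(np.concatenate([levels, levels])[:, None], n, axis=1)
    euler = np.zeros((4, 3, n))
    if params.activity == SITTING:
        euler[0, 1] = _THIGH_PITCH_SITTING
        euler[1, 1] = _THIGH_PITCH_SITTING
        euler[2, 1] = _SHANK_PITCH_SITTING
        euler[3, 1] = _SHANK_PITCH_SITTING
    return pressure, euler


def _transition_foot(params: GaitParams, s: np.ndarray, rising: bool) -> np.ndarray:
    """(6, n) one-foot pressure along the normalized transition axis s.

    ``rising=True`` is sit-to-stand: early heel rise, rapid heel drop with a
    simultaneous forefoot surge, heel restabilization at standing level.
    ``rising=False`` is stand-to-sit: heel overshoot above standing while the
    forefoot decays rapidly, then settling at sitting level.
    """
    peak = params.pressure_peak
    sit = peak * SITTING_PROFILE
    stand = peak * STANDING_PROFILE
    out = np.empty((6, s.size))
    if rising:
        g = _smoothstep(s)
        for i in range(6):
            out[i] = sit[i] + (stand[i] - sit[i]) * g
        heel_bump = _hann_bump(s, 0.20, 0.36)
        heel_dip = _hann_bump(s, 0.52, 0.35)
        fore_surge = _hann_bump(s, 0.55, 0.50)
        for i in (0, 1):
            out[i] += 0.25 * peak * heel_bump - 0.5 * stand[i] * heel_dip
        for i in (3, 4, 5):
            out[i] += 0.30 * peak * fore_surge * _STANCE_WEIGHT[i] / 0.95
    else:
        g_heel = _smoothstep((s - 0.30) / 0.70)
        g_fore = _smoothstep(s / 0.45)
        for i in (0, 1):
            out[i] = stand[i] + (sit[i] - stand[i]) * g_heel
        out[2] = stand[2] + (sit[2] - stand[2]) * _smoothstep(s)
        for i in (3, 4, 5):
            out[i] = stand[i] + (sit[i] - stand[i]) * g_fore
        heel_over = _hann_bump(s, 0.22, 0.44)
        for i in (0, 1):
            out[i] += 0.30 * peak * heel_over
    return np.clip(out, 0.0, None)


def _transition_ramp(params: GaitParams, n: int, rising: bool):
    """Pressure and angles of a single sit<->stand centre-of-gravity transfer."""
    s = np.linspace(0.0, 1.0, n, endpoint=False) + 0.5 / n
    foot = _transition_foot(params, s, rising)
    pressure = np.vstack([foot, foot])
    euler = np.zeros((4, 3, n))
    g = _smoothstep(s)
    thigh_pitch = _THIGH_PITCH_SITTING * ((1.0 - g) if rising else g)
    shank_pitch = _SHANK_PITCH_SITTING * ((1.0 - g) if rising else g)
    wiggle = 4.0 * _hann_bump(s, 0.5, 0.8)
    for node in (0, 1):
        euler[node, 1] = thigh_pitch
        euler[node, 0] = wiggle * (1 if node == 0 else -1)
    for node in (2, 3):
        euler[node, 1] = shank_pitch
    return pressure, euler


def _transition_cycle(params: GaitParams, rising: bool):
    """One repetition: source hold, transfer ramp, target hold, quick return.

    Uniform-label transition recordings emulate the protocol of repeatedly
    performing the action inside one recording; the short raised-cosine
    return blend brings the signals back to the source posture between
    repetitions.
    """
    sr = SAMPLE_RATE
    n_hold = int(round(0.5 * sr))
    n_ramp = int(round(params.transition_duration * sr))
    n_back = int(round(0.5 * sr))
    src = SITTING if rising else STANDING
    tgt = STANDING if rising else SITTING
    p_src, e_src = _static_segment(GaitParams(activity=src,
                                              pressure_peak=params.pressure_peak),
                                   n_hold)
    p_ramp, e_ramp = _transition_ramp(params, n_ramp, rising)
    p_tgt, e_tgt = _static_segment(GaitParams(activity=tgt,
                                              pressure_peak=params.pressure_peak),
                                   n_hold)
    # quick blend back from target posture to source posture
    b = _smoothstep(np.linspace(0.0, 1.0, n_back, endpoint=False))
    p_back = p_tgt[:, :1] + (p_src[:, :1] - p_tgt[:, :1]) * b
    e_back = e_tgt[:, :, :1] + (e_src[:, :, :1] - e_tgt[:, :, :1]) * b
    pressure = np.concatenate([p_src, p_ramp, p_tgt, p_back], axis=1)
    euler = np.concatenate([e_src, e_ramp, e_tgt, e_back], axis=2)
    return pressure, euler


def _add_noise(pressure, euler, params: GaitParams, rng: np.random.Generator):
    if params.noise_sd_pressure > 0:
        pressure = pressure + rng.normal(0.0, params.noise_sd_pressure,
                                         pressure.shape)
    if params.noise_sd_angle > 0:
        euler = euler + rng.normal(0.0, params.noise_sd_angle, euler.shape)
    pressure = np.clip(pressure, 0.0, None)
    # keep emitted angles inside the sensor's (-180, 180] output interval
    euler = (euler + 180.0) % 360.0 - 180.0
    euler[euler == -180.0] = 180.0
    return pressure, euler


def simulate_activity(
    params: GaitParams,
    duration: float,
    seed: int | None = None,
    subject_id: str = "sim",
) -> Recording:
    """Generate a uniform-label recording of one activity.

    Parameters
    ----------
    params
        Activity parameterization; ``GaitParams.for_activity`` supplies the
        documented defaults.
    duration
        Recording length in seconds (> 0).
    seed
        Overrides ``params.seed``; identical seeds give bit-identical output.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if params.activity not in ACTIVITIES:
        raise ValueError(f"unknown activity {params.activity!r}")
    if seed is None:
        seed = params.seed if params.seed is not None else 0
    rng = np.random.default_rng(seed)
    n = int(round(duration * SAMPLE_RATE))

    if params.activity in DYNAMIC_ACTIVITIES:
        pressure, euler = _dynamic_segment(params, n, rng)
    elif params.activity in (STANDING, SITTING):
        pressure, euler = _static_segment(params, n)
    else:
        rising = params.activity == SIT_TO_STAND
        p_cyc, e_cyc = _transition_cycle(params, rising)
        reps = int(np.ceil(n / p_cyc.shape[1]))
        pressure = np.tile(p_cyc, (1, reps))[:, :n]
        euler = np.tile(e_cyc, (1, 1, reps))[:, :, :n]

    pressure, euler = _add_noise(pressure, euler, params, rng)
    labels = np.full(n, params.activity, dtype=object)
    return Recording(pressure=pressure, euler=euler, labels=labels,
                     subject_id=subject_id)


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

# physically legal successions of activities inside a continuous session
_SESSION_NEXT = {
    SITTING: {SITTING, SIT_TO_STAND},
    SIT_TO_STAND: {STANDING},
    STAND_TO_SIT: {SITTING},
    STANDING: {STANDING, STAND_TO_SIT, *DYNAMIC_ACTIVITIES},
    **{d: {STANDING, *DYNAMIC_ACTIVITIES} for d in DYNAMIC_ACTIVITIES},
}


def simulate_session(
    plan: Sequence[tuple[str, float] | str],
    seed: int = 0,
    base_params: dict[str, GaitParams] | None = None,
    subject_id: str = "sim",
    insert_transitions: bool = False,
) -> Recording:
    """Concatenate activity segments into one continuous labeled session.

    ``plan`` is an ordered list of ``(activity, duration_s)`` pairs; a bare
    transition name may be given without a duration (the configured ramp
    duration is used).  Successive activities must be physically legal
    (sitting cannot be followed directly by standing or walking); with
    ``insert_transitions=True`` the missing sit<->stand transition is
    inserted automatically instead of raising.

    Transition entries inside a session are rendered as a single
    centre-of-gravity transfer ramp (no repetition tiling), so the session
    is continuous across segment boundaries.
    """
    if not plan:
        raise ValueError("plan must be nonempty")
    base_params = base_params or {}

    norm: list[tuple[str, float | None]] = []
    for item in plan:
        if isinstance(item, str):
            norm.append((item, None))
        else:
            norm.append((item[0], float(item[1])))
    for act, _ in norm:
        if act not in ACTIVITIES:
            raise ValueError(f"unknown activity {act!r}")

    expanded: list[tuple[str, float | None]] = [norm[0]]
    for act, dur in norm[1:]:
        prev = expanded[-1][0]
        if act not in _SESSION_NEXT[prev]:
            # the only repairable gaps are the missing sit<->stand transitions
            if insert_transitions and prev == SITTING and act == STANDING:
                expanded.append((SIT_TO_STAND, None))
            elif insert_transitions and prev == STANDING and act == SITTING:
                expanded.append((STAND_TO_SIT, None))
            else:
                raise ValueError(
                    f"physically illegal plan step {prev!r} -> {act!r}"
                )
        expanded.append((act, dur))

    rng = np.random.default_rng(seed)
    parts: list[Recording] = []
    for act, dur in expanded:
        params = base_params.get(act, GaitParams.for_activity(act))
        if act in TRANSITIONS:
            n = int(round((dur if dur is not None
                           else params.transition_duration) * SAMPLE_RATE))
            pressure, euler = _transition_ramp(params, n,
                                               rising=act == SIT_TO_STAND)
            pressure, euler = _add_noise(pressure, euler, params,
                                         np.random.default_rng(rng.integers(2**31)))
            labels = np.full(n, act, dtype=object)
            parts.append(Recording(pressure=pressure, euler=euler,
                                   labels=labels, subject_id=subject_id))
        else:
            if dur is None:
                raise ValueError(f"duration required for activity {act!r}")
            seg_seed = int(rng.integers(2**31))
            parts.append(simulate_activity(params, dur, seed=seg_seed,
                                           subject_id=subject_id))
    return Recording.concatenate(parts)


# ---------------------------------------------------------------------------
# gait-phase measurement (used by fidelity checks and the acceptance target)
# ---------------------------------------------------------------------------

def gait_phase_stats(
    recording: Recording, threshold_frac: float = 0.05
) -> dict[str, float]:
    """Empirical stance and dual-support fractions from foot-total pressure.

    A foot counts as loaded when its summed 6-channel pressure exceeds
    ``threshold_frac`` of the recording's peak foot-total pressure (the
    contact floor used throughout the pipeline).
    """
    left = recording.pressure[:6].sum(axis=0)
    right = recording.pressure[6:].sum(axis=0)
    floor = threshold_frac * max(left.max(), right.max())
    l_on = left > floor
    r_on = right > floor
    return {
        "stance_fraction_left": float(l_on.mean()),
        "stance_fraction_right": float(r_on.mean()),
        "stance_fraction": float((l_on.mean() + r_on.mean()) / 2.0),
        "dual_support_fraction": float((l_on & r_on).mean()),
        "contact_floor_kpa": float(floor),
    }
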