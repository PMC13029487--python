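"""Core domain containers: activities, sensor layout, gait parameters, recordings.

A :class:`Recording` is one synchronized, labeled multichannel session sampled
at 100 Hz: 12 plantar-pressure channels (6 per foot, kPa) and 12 Euler-angle
channels (4 limb nodes x roll/pitch/yaw, degrees).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

SAMPLE_RATE = 100.0  # Hz, synchronized for both modalities

# Canonical activity labels (8 classes).
STANDING = "standing"
SITTING = "sitting"
SIT_TO_STAND = "sit_to_stand"
STAND_TO_SIT = "stand_to_sit"
WALKING = "walking"
RUNNING = "running"
STAIR_ASCENT = "stair_ascent"
STAIR_DESCENT = "stair_descent"

STATIC_ACTIVITIES = (STANDING, SITTING, SIT_TO_STAND, STAND_TO_SIT)
DYNAMIC_ACTIVITIES = (WALKING, RUNNING, STAIR_ASCENT, STAIR_DESCENT)
ACTIVITIES = STATIC_ACTIVITIES + DYNAMIC_ACTIVITIES

TRANSITIONS = (SIT_TO_STAND, STAND_TO_SIT)

# IMU node order used everywhere a flat 12-channel angle block appears.
IMU_NODES = ("l_thigh", "r_thigh", "l_shank", "r_shank")
ANGLE_NAMES = ("roll", "pitch", "yaw")

PRESSURE_CHANNELS = tuple(f"{side}{i}" for side in "LR" for i in range(1, 7))


def _default_foot_coords() -> np.ndarray:
    """Right-foot sensor coordinates in mm (x medial->lateral, y posterior->anterior).

    Six sensors per foot: two heel, one arch, two metatarsal, one toe.  The
    positions are a stated convention (configurable), not measured ground
    truth.
    """
    return np.array(
        [
            [-12.0, -95.0],  # heel medial
            [14.0, -95.0],   # heel lateral
            [18.0, -30.0],   # arch (lateral midfoot)
            [-18.0, 45.0],   # metatarsal medial
            [15.0, 40.0],    # metatarsal lateral
            [-5.0, 95.0],    # hallux / toe
        ]
    )


@dataclass(frozen=True)
class SensorLayout:
    """Geometry and electrical model of the 12-sensor piezoresistive array.

    The transduction chain is: load (N) -> resistance via a monotone
    decreasing characteristic R(F) = curve_c / (F + curve_eps) -> DC voltage
    divider against ``divider_ohm`` at ``supply_v``.  ``curve_c`` and
    ``curve_eps`` are chosen so that the unloaded resistance exceeds 10 MOhm.
    """

    foot_coords_mm: np.ndarray = field(default_factory=_default_foot_coords)
    foot_offset_mm: float = 60.0  # half the stance width; left foot at -x
    divider_ohm: float = 20_000.0
    supply_v: float = 3.3
    curve_c: float = 1.0e5   # Ohm * N
    curve_eps: float = 5e-3  # N; sets the unloaded resistance curve_c/curve_eps

    def __post_init__(self) -> None:
        coords = np.asarray(self.foot_coords_mm, dtype=float)
        if coords.shape != (6, 2):
            raise ValueError("foot_coords_mm must be 6 coordinate pairs")
        if self.divider_ohm <= 0:
            raise ValueError("divider reference resistance must be positive")
        object.__setattr__(self, "foot_coords_mm", coords)

    def coords12(self) -> np.ndarray:
        """(12, 2) coordinates for channels L1..L6, R1..R6 in a shared frame.

        The left foot is the mirror image of the right, shifted medially.
        """
        right = self.foot_coords_mm.copy()
        right[:, 0] += self.foot_offset_mm
        left = self.foot_coords_mm.copy()
        left[:, 0] = -left[:, 0] - self.foot_offset_mm
        return np.vstack([left, right])


@dataclass(frozen=True)
class GaitParams:
    """Per-activity parameterization of the signal generator.

    ``cadence`` is in steps/s; one full per-foot gait cycle lasts
    ``1 / cadence`` seconds.  ``stance_fraction`` is the fraction of the
    cycle a foot is loaded; with the feet half a cycle out of phase the
    nominal dual-support fraction of walking is ``2 * stance_fraction - 1``
    (and 0 whenever stance_fraction < 0.5, i.e. running).  Roll amplitudes
    are peak-to-peak degrees.
    """

    activity: str
    cadence: float = 0.0              # steps/s (0 for static postures)
    stance_fraction: float = 0.6      # in (0, 1)
    dual_support_fraction: float = 0.2
    thigh_roll_amp: float = 0.0       # deg, peak-to-peak
    shank_roll_amp: float = 0.0       # deg, peak-to-peak
    pitch_activity_level: float = 0.0  # deg, peak-to-peak pitch oscillation
    yaw_stability: float = 1.0        # 1 = stable; >1 = larger slow yaw wander
    speed_note: float = 0.0           # km/h, documentation only
    pressure_peak: float = 400.0      # kPa at the most loaded sensor
    noise_sd_pressure: float = 5.0    # kPa, additive Gaussian, clipped at 0
    noise_sd_angle: float = 1.5       # deg, additive Gaussian
    transition_duration: float = 2.0  # s, sit<->stand ramp
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ValueError(f"unknown activity {self.activity!r}")
        if self.activity in DYNAMIC_ACTIVITIES and self.cadence <= 0:
            raise ValueError("cadence must be positive for dynamic activities")
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must lie in (0, 1)")
        if not 0.0 <= self.dual_support_fraction < 0.5:
            raise ValueError("dual_support_fraction must lie in [0, 0.5)")
        if self.activity == RUNNING and self.dual_support_fraction != 0.0:
            raise ValueError("running has no dual-support period")
        for amp in (self.thigh_roll_amp, self.shank_roll_amp,
                    self.pitch_activity_level, self.pressure_peak):
            if amp < 0:
                raise ValueError("amplitudes must be nonnegative")

    @staticmethod
    def for_activity(activity: str, **overrides) -> "GaitParams":
        """Default parameterization of each of the 8 activities.

        Dynamic-gait cadences, roll amplitudes and pitch activity follow the
        summary of the studied activity set (walking ~1.0 steps/s at ~5 km/h,
        running >2 steps/s at ~10 km/h with no dual support, stair ascent
        1.2-1.5 steps/s with high pitch activity and reduced thigh roll,
        stair descent ~0.75 steps/s with the lowest pitch activity).
        """
        table = {
            STANDING: dict(),
            SITTING: dict(),
            SIT_TO_STAND: dict(),
            STAND_TO_SIT: dict(),
            WALKING: dict(cadence=1.0, stance_fraction=0.60,
                          dual_support_fraction=0.20, thigh_roll_amp=100.0,
                          shank_roll_amp=100.0, pitch_activity_level=10.0,
                          speed_note=5.0, pressure_peak=400.0),
            RUNNING: dict(cadence=2.2, stance_fraction=0.38,
                          dual_support_fraction=0.0, thigh_roll_amp=100.0,
                          shank_roll_amp=100.0, pitch_activity_level=12.0,
                          speed_note=10.0, pressure_peak=600.0),
            STAIR_ASCENT: dict(cadence=1.35, stance_fraction=0.62,
                               dual_support_fraction=0.24, thigh_roll_amp=60.0,
                               shank_roll_amp=70.0, pitch_activity_level=25.0,
                               yaw_stability=3.0, speed_note=2.0,
                               pressure_peak=420.0),
            STAIR_DESCENT: dict(cadence=0.75, stance_fraction=0.62,
                                dual_support_fraction=0.24, thigh_roll_amp=30.0,
                                shank_roll_amp=70.0, pitch_activity_level=5.0,
                                speed_note=2.0, pressure_peak=420.0),
        }
        if activity not in table:
            raise ValueError(f"unknown activity {activity!r}")
        kwargs = dict(table[activity])
        kwargs.update(overrides)
        return GaitParams(activity=activity, **kwargs)

    def jittered(self, rng: np.random.Generator, rel: float = 0.1) -> "GaitParams":
        """Multiplicative jitter of cadence/amplitudes, emulating a subject."""
        def j(v: float) -> float:
            return float(v * (1.0 + rng.uniform(-rel, rel))) if v > 0 else v

        return replace(
            self,
            cadence=j(self.cadence),
            thigh_roll_amp=j(self.thigh_roll_amp),
            shank_roll_amp=j(self.shank_roll_amp),
            pitch_activity_level=j(self.pitch_activity_level),
            pressure_peak=j(self.pressure_peak),
        )


@dataclass
class Recording:
    """One synchronized multimodal session.

    pressure : (12, T) kPa, channels L1..L6, R1..R6
    euler    : (4, 3, T) degrees, nodes l_thigh, r_thigh, l_shank, r_shank,
               angles roll, pitch, yaw
    labels   : (T,) per-frame activity labels
    """

    pressure: np.ndarray
    euler: np.ndarray
    labels: np.ndarray
    sample_rate: float = SAMPLE_RATE
    subject_id: str = "sim"

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.euler = np.asarray(self.euler, dtype=float)
        self.labels = np.asarray(self.labels)
        t = self.pressure.shape[-1]
        if self.pressure.shape != (12, t):
            raise ValueError("pressure must be (12, T)")
        if self.euler.shape != (4, 3, t):
            raise ValueError("euler must be (4, 3, T)")
        if self.labels.shape != (t,):
            raise ValueError("labels must have length T")
        if np.any(self.pressure < 0):
            raise ValueError("pressure must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.pressure.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.sample_rate

    @property
    def euler_flat(self) -> np.ndarray:
        """(12, T) angle block, node-major then roll/pitch/yaw."""
        return self.euler.reshape(12, -1)

    # -- serialization -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.n_frames) / self.sample_rate
        data = {"time_s": t}
        for i, ch in enumerate(PRESSURE_CHANNELS):
            data[f"p_{ch}"] = self.pressure[i]
        flat = self.euler_flat
        for i, (node, ang) in enumerate(
            (n, a) for n in IMU_NODES for a in ANGLE_NAMES
        ):
            data[f"ang_{node}_{ang}"] = flat[i]
        data["label"] = self.labels
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        """Write frame-per-row CSV plus a JSON sidecar with the metadata."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.6g")
        meta = {"sample_rate": self.sample_rate, "subject_id": self.subject_id}
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Recording":
        path = Path(path)
        df = pd.read_csv(path)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        pressure = df[[f"p_{ch}" for ch in PRESSURE_CHANNELS]].to_numpy().T
        ang_cols = [f"ang_{n}_{a}" for n in IMU_NODES for a in ANGLE_NAMES]
        euler = df[ang_cols].to_numpy().T.reshape(4, 3, -1)
        return cls(
            pressure=pressure,
            euler=euler,
            labels=df["label"].to_numpy(),
            sample_rate=float(meta.get("sample_rate", SAMPLE_RATE)),
            subject_id=str(meta.get("subject_id", "unknown")),
        )

    @staticmethod
    def concatenate(parts: list["Recording"]) -> "Recording":
        if not parts:
            raise ValueError("nothing to concatenate")
        sr = parts[0].sample_rate
        if any(p.sample_rate != sr for p in parts):
            raise ValueError("sample rates differ")
        return Recording(
            pressure=np.concatenate([p.pressure for p in parts], axis=1),
            euler=np.concatenate([p.euler for p in parts], axis=2),
            labels=np.concatenate([p.labels for p in parts]),
            sample_rate=sr,
            subject_id=parts[0].subject_id,
        )
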