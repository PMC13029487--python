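"""Stage-1 router: static vs dynamic gait via a dual-threshold rule.

A window is routed by "time-domain energy + frequency-domain significance":
if the detrended pressure energy is below T_E the window is static and the
spectral test is skipped entirely (the compute-saving path); otherwise the
window is dynamic only when the spectral significance exceeds T_Ratio.

Significance is the in-band spectral prominence of the left-minus-right
foot-total pressure signal.  Locomotion alternates the feet, so its
differential pressure is strongly periodic at the gait-cycle rate; posture
transfers (sit-to-stand) load and unload both feet together, leaving the
differential without periodic structure.  A transfer wave is spectrally
concentrated in the *summed* pressure too (a single smooth pulse), which is
why the differential -- not the summed -- signal carries the static/dynamic
distinction at this window length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import GAIT_BAND, band_spectral_features, spectrum
from .preprocessing import GaitWindow

__all__ = ["DetectorThresholds", "window_energy", "classify_state",
           "RouteDecision", "STATIC", "DYNAMIC"]

STATIC = "static"
DYNAMIC = "dynamic"


@dataclass(frozen=True)
class DetectorThresholds:
    """Defaults calibrated once on the simulator's default conditions.

    ``t_energy`` is in kPa^2 (summed per-channel detrended mean-square);
    static postures at the default noise floor sit more than an order of
    magnitude below the default while locomotion sits far above.
    ``t_ratio`` is unitless (>= 1 under the prominence definition); the
    differential-pressure prominence of simulated locomotion stays above
    ~8.5 while static and transfer windows stay below ~5.5, so the default
    splits the gap.
    """

    t_energy: float = 2000.0
    t_ratio: float = 6.5

    def __post_init__(self) -> None:
        if self.t_energy < 0:
            raise ValueError("t_energy must be nonnegative")
        if self.t_ratio < 1.0:
            raise ValueError("t_ratio must be >= 1 under the prominence "
                             "definition")


@dataclass(frozen=True)
class RouteDecision:
    state: str
    energy: float
    prominence: float | None  # None when the spectral test was skipped
    spectral_computed: bool


def window_energy(pressure: np.ndarray) -> float:
    """Detrended time-domain energy of a 12-channel pressure window.

    Sum over channels of the mean squared deviation from each channel's
    window mean; invariant to constant offsets, so quiet standing under
    constant load registers as (near) zero energy.
    """
    p = np.asarray(pressure, dtype=float)
    return float(np.sum(np.var(p, axis=1)))


def classify_state(
    window: GaitWindow | np.ndarray,
    thresholds: DetectorThresholds = DetectorThresholds(),
    band: tuple[float, float] = GAIT_BAND,
) -> RouteDecision:
    """Route one window to the static or dynamic branch."""
    pressure = window.pressure if isinstance(window, GaitWindow) else window
    energy = window_energy(pressure)
    if energy < thresholds.t_energy:
        return RouteDecision(STATIC, energy, None, spectral_computed=False)
    p = np.asarray(pressure, dtype=float)
    diff = p[:6].sum(axis=0) - p[6:].sum(axis=0)
    _, _, prominence = band_spectral_features(spectrum(diff - diff.mean()),
                                              band)
    state = DYNAMIC if prominence > thresholds.t_ratio else STATIC
    return RouteDecision(state, energy, prominence, spectral_computed=True)
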